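"""Predict 1D, DQ-SQ and PDSD peak positions from bond graphs and shifts.

The double-quantum coordinate rule is the core of the DQ-SQ interpretation:
a bonded pair (i, j) produces cross peaks on the single-quantum (F2) axis at
each partner's shift, sharing the double-quantum (F1) coordinate

    delta_DQ = delta_i + delta_j.

Bonded, chemically (near-)equivalent carbons collapse to a single
"autocorrelation" peak at F2 = delta and F1 = 2*delta — e.g. the mutually
bonded Phe ring carbons, whose envelope near 130 ppm autocorrelates at
ca. 260 ppm in the DQ dimension.  PDSD cross peaks appear at (delta_i,
delta_j) and its mirror for every pair within the spin-diffusion radius,
which grows with mixing time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .residue_model import ResidueTopology, bonded_pairs, proximity_pairs

__all__ = [
    "Peak2D",
    "PeakList",
    "predict_dqsq",
    "predict_pdsd",
    "predict_cp1d",
    "mixing_time_to_radius",
    "apply_referencing_offset",
    "DEFAULT_EQUIVALENCE_WINDOW",
    "DEFAULT_QUATERNARY_ATTENUATION",
    "DEFAULT_MIXING_SCHEDULE",
]

#: |delta_i - delta_j| below which a bonded pair collapses to one
#: autocorrelation peak (ppm); the Phe ring envelope motivates ~2 ppm.
DEFAULT_EQUIVALENCE_WINDOW = 2.0

#: Intensity multiplier for correlations involving a non-protonated carbon,
#: which cross-polarize poorly and are often too weak to observe.
DEFAULT_QUATERNARY_ATTENUATION = 0.2

#: PDSD mixing-time (ms) -> bond-radius breakpoints: up to each time, that
#: radius. 20 ms resolves one-bond proximities, 100 ms two-bond (e.g. the
#: aromatic Cdelta-Czeta pair), longer mixing three-bond.
DEFAULT_MIXING_SCHEDULE = ((20.0, 1), (100.0, 2))
_MAX_RADIUS = 3

EXPERIMENTS = ("CP1D", "DQSQ", "PDSD")


@dataclass(frozen=True)
class Peak2D:
    """One peak; ``f1`` is the indirect coordinate (DQ sum for DQ-SQ, SQ for
    PDSD) and is None for 1D peaks."""

    f2: float
    f1: float | None = None
    intensity: float = 1.0
    linewidth: float | None = None
    residue: str | None = None
    atom_i: str | None = None
    atom_j: str | None = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")
        if self.linewidth is not None and self.linewidth <= 0:
            raise ValueError("linewidth must be positive when set")


@dataclass
class PeakList:
    experiment: str
    peaks: list[Peak2D] = field(default_factory=list)
    mixing_time: float | None = None
    referencing_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment tag {self.experiment!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def coordinates(self) -> list[tuple[float, float | None]]:
        return [(p.f2, p.f1) for p in self.peaks]


def _pair_intensity(
    topology: ResidueTopology,
    atoms: Sequence[str],
    base: float,
    quaternary_attenuation: float,
) -> float:
    if any(a in topology.quaternary for a in atoms):
        return base * quaternary_attenuation
    return base


def _check_shifts(shifts: Mapping[str, float], topology: ResidueTopology) -> None:
    unknown = set(shifts) - set(topology.atoms)
    if unknown:
        raise ValueError(
            f"shifts reference atoms not in {topology.code} topology: {sorted(unknown)}"
        )


def predict_dqsq(
    shifts: Mapping[str, float],
    topology: ResidueTopology,
    equivalence_window: float = DEFAULT_EQUIVALENCE_WINDOW,
    base_intensity: float = 1.0,
    quaternary_attenuation: float = DEFAULT_QUATERNARY_ATTENUATION,
    linewidth: float | None = None,
) -> PeakList:
    """DQ-SQ peaks for one residue spin system.

    Atoms absent from ``shifts`` are treated as unshifted and produce no
    peaks.  Carbons without C-C bonds (e.g. Arg CZ) never appear: double
    quantum coherence requires a bonded 13C partner.
    """
    _check_shifts(shifts, topology)
    peaks: list[Peak2D] = []
    for bond in sorted(bonded_pairs(topology), key=sorted):
        i, j = sorted(bond)
        if i not in shifts or j not in shifts:
            continue
        di, dj = shifts[i], shifts[j]
        dq = di + dj
        inten = _pair_intensity(topology, (i, j), base_intensity, quaternary_attenuation)
        if abs(di - dj) <= equivalence_window:
            peaks.append(Peak2D(f2=(di + dj) / 2.0, f1=dq, intensity=inten,
                                linewidth=linewidth, residue=topology.code,
                                atom_i=i, atom_j=j))
        else:
            for f2, (ai, aj) in ((di, (i, j)), (dj, (j, i))):
                peaks.append(Peak2D(f2=f2, f1=dq, intensity=inten,
                                    linewidth=linewidth, residue=topology.code,
                                    atom_i=ai, atom_j=aj))
    return PeakList(experiment="DQSQ", peaks=peaks)


def predict_pdsd(
    shifts: Mapping[str, float],
    topology: ResidueTopology,
    radius: int,
    base_intensity: float = 1.0,
    quaternary_attenuation: float = DEFAULT_QUATERNARY_ATTENUATION,
    linewidth: float | None = None,
    mixing_time: float | None = None,
) -> PeakList:
    """PDSD peaks: off-diagonal pairs within ``radius`` bonds plus the full
    diagonal (every shifted carbon, isolated ones included)."""
    _check_shifts(shifts, topology)
    peaks: list[Peak2D] = []
    for pair in sorted(proximity_pairs(topology, radius), key=sorted):
        i, j = sorted(pair)
        if i not in shifts or j not in shifts:
            continue
        inten = _pair_intensity(topology, (i, j), base_intensity, quaternary_attenuation)
        for (f2a, f1a), (ai, aj) in (
            ((shifts[i], shifts[j]), (i, j)),
            ((shifts[j], shifts[i]), (j, i)),
        ):
            peaks.append(Peak2D(f2=f2a, f1=f1a, intensity=inten,
                                linewidth=linewidth, residue=topology.code,
                                atom_i=ai, atom_j=aj))
    for atom in topology.atoms:
        if atom in shifts:
            inten = _pair_intensity(topology, (atom,), base_intensity,
                                    quaternary_attenuation)
            peaks.append(Peak2D(f2=shifts[atom], f1=shifts[atom], intensity=inten,
                                linewidth=linewidth, residue=topology.code,
                                atom_i=atom, atom_j=atom))
    return PeakList(experiment="PDSD", peaks=peaks, mixing_time=mixing_time)


def predict_cp1d(
    shifts: Mapping[str, float],
    topology: ResidueTopology,
    base_intensity: float = 1.0,
    quaternary_attenuation: float = DEFAULT_QUATERNARY_ATTENUATION,
    linewidth: float | None = None,
) -> PeakList:
    """1D CP peaks: one per shifted carbon (quaternaries attenuated)."""
    _check_shifts(shifts, topology)
    peaks = [
        Peak2D(
            f2=shifts[a], f1=None,
            intensity=_pair_intensity(topology, (a,), base_intensity,
                                      quaternary_attenuation),
            linewidth=linewidth, residue=topology.code, atom_i=a,
        )
        for a in topology.atoms if a in shifts
    ]
    return PeakList(experiment="CP1D", peaks=peaks)


def mixing_time_to_radius(
    mixing_time: float,
    schedule: Sequence[tuple[float, int]] = DEFAULT_MIXING_SCHEDULE,
) -> int:
    """Map a PDSD mixing time (ms) to a bond-count transfer radius.

    Stepwise non-decreasing; the default schedule sends <=20 ms to one bond
    and <=100 ms to two bonds, longer mixing to three.
    """
    if mixing_time <= 0:
        raise ValueError(f"mixing time must be positive, got {mixing_time}")
    for breakpoint_ms, radius in schedule:
        if mixing_time <= breakpoint_ms:
            return radius
    return max(r for _, r in schedule) + 1 if schedule else _MAX_RADIUS


def apply_referencing_offset(peaklist: PeakList, offset: float) -> PeakList:
    """Shift every SQ coordinate by ``offset`` ppm (DQ coordinates by twice
    that, since the DQ axis is a sum of two SQ shifts)."""
    f1_factor = 2.0 if peaklist.experiment == "DQSQ" else 1.0
    shifted = [
        replace(
            p,
            f2=p.f2 + offset,
            f1=None if p.f1 is None else p.f1 + f1_factor * offset,
        )
        for p in peaklist.peaks
    ]
    return PeakList(
        experiment=peaklist.experiment,
        peaks=shifted,
        mixing_time=peaklist.mixing_time,
        referencing_offset=peaklist.referencing_offset + offset,
    )
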