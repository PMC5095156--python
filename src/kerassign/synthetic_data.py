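"""Synthetic peak lists, 1D profiles and rasterized 2D spectra.

The generator emulates the statistical structure of 2D correlation data from
uniformly 13C-labelled keratin: each residue type draws a secondary-structure
class, takes the per-class reference shifts, perturbs them with Gaussian
shift noise, and emits 1D/DQ-SQ/PDSD peak lists whose intensities follow
mole % weighted by isotope labelling efficiency (lower for non-essential
amino acids, which are diluted by de novo biosynthesis from unlabelled
carbohydrate) and by a quaternary-carbon attenuation.  An optional lipid
contaminant contributes the methylene autocorrelation seen in practice near
30 ppm.  Peak lists can be rasterized to grids of 2D Gaussians and picked
back, so the whole analysis chain is testable without any measured data.

All randomness flows through the mandatory config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy import ndimage

from .amide_decomposition import Profile1D
from .peak_prediction import (
    Peak2D,
    PeakList,
    mixing_time_to_radius,
    predict_cp1d,
    predict_dqsq,
    predict_pdsd,
)
from .residue_model import (
    CompositionTable,
    ReferenceShiftTable,
    ResidueTopology,
    STRUCTURE_CLASSES,
    csi_reference_table,
    load_composition,
    load_topologies,
)

__all__ = [
    "SyntheticConfig",
    "GridSpec",
    "SpectrumGrid",
    "GroundTruth",
    "sample_shifts",
    "generate_peaklists",
    "render_spectrum",
    "pick_peaks",
    "synthesize_amide_profile",
]

#: assumed labelling efficiency of non-essential amino acids (essentials get 1)
DEFAULT_NONESSENTIAL_EFFICIENCY = 0.6

#: global default secondary-structure mix: helical IF rod domains dominate,
#: with substantial sheet/coil head, tail and matrix content
DEFAULT_CLASS_MIX = {"H": 0.4, "S": 0.3, "C": 0.3}

LIPID_CODE = "LIPID"
LIPID_SHIFT = 30.0  # ppm, equivalent methylene pair


class SyntheticConfig(BaseModel):
    """Full generative recipe for one synthetic data set."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    seed: int
    composition: CompositionTable = Field(default_factory=load_composition)
    class_mix: dict[str, float] | dict[str, dict[str, float]] = Field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    shift_noise_sd: float = Field(default=0.2, ge=0.0)
    linewidth: float = Field(default=0.5, gt=0.0)
    labelling_efficiency: dict[str, float] = Field(default_factory=dict)
    quaternary_attenuation: float = Field(default=0.2, ge=0.0, le=1.0)
    include_lipid: bool = False
    lipid_intensity: float = Field(default=5.0, ge=0.0)
    pdsd_mixing_ms: float = Field(default=20.0, gt=0.0)
    equivalence_window: float = Field(default=2.0, ge=0.0)

    @field_validator("class_mix")
    @classmethod
    def _mix_sums_to_one(cls, v):
        def check(mix: Mapping[str, float], label: str) -> None:
            if any(f < 0 or f > 1 for f in mix.values()):
                raise ValueError(f"class fractions out of [0,1] for {label}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"class fractions must sum to 1 for {label}")

        if v and isinstance(next(iter(v.values())), dict):
            for res, mix in v.items():
                check(mix, res)
        else:
            check(v, "global mix")
        return v

    def mix_for(self, residue: str) -> dict[str, float]:
        if self.class_mix and isinstance(next(iter(self.class_mix.values())), dict):
            return self.class_mix.get(residue, dict(DEFAULT_CLASS_MIX))
        return dict(self.class_mix)  # type: ignore[arg-type]

    def efficiency_for(self, topology: ResidueTopology) -> float:
        if topology.code in self.labelling_efficiency:
            return self.labelling_efficiency[topology.code]
        return 1.0 if topology.essential else DEFAULT_NONESSENTIAL_EFFICIENCY


@dataclass
class GroundTruth:
    """Hidden generating labels for scoring a recovery run."""

    classes: dict[str, str]
    shifts: dict[str, dict[str, float]]
    intensities: dict[str, float]


def sample_shifts(
    config: SyntheticConfig,
    refs: ReferenceShiftTable | None = None,
    topologies: Mapping[str, ResidueTopology] | None = None,
) -> GroundTruth:
    """Draw one class and one noisy shift set per composition residue.

    Deterministic given the config seed; with ``shift_noise_sd == 0`` the
    shifts equal the reference values exactly.
    """
    refs = refs if refs is not None else csi_reference_table()
    topologies = topologies or load_topologies()
    rng = np.random.default_rng(config.seed)
    classes: dict[str, str] = {}
    shifts: dict[str, dict[str, float]] = {}
    intensities: dict[str, float] = {}
    for code, pct in sorted(config.composition.expanded().items()):
        if code not in topologies:
            raise KeyError(f"no topology for composition residue {code!r}")
        topo = topologies[code]
        mix = config.mix_for(code)
        cls = rng.choice(STRUCTURE_CLASSES, p=[mix.get(c, 0.0) for c in STRUCTURE_CLASSES])
        atom_shifts = {}
        for atom in topo.atoms:
            if not refs.has(code, atom, cls):
                raise KeyError(f"reference table lacks {code} {atom} (class {cls})")
            mean, _sd = refs.lookup(code, atom, cls)
            atom_shifts[atom] = float(mean + rng.normal(0.0, config.shift_noise_sd))
        classes[code] = str(cls)
        shifts[code] = atom_shifts
        intensities[code] = pct * config.efficiency_for(topo)
    return GroundTruth(classes=classes, shifts=shifts, intensities=intensities)


def _lipid_topology() -> ResidueTopology:
    return ResidueTopology(
        code=LIPID_CODE,
        atoms=("C1", "C2"),
        bonds=frozenset({frozenset(("C1", "C2"))}),
        equivalent_groups=(frozenset(("C1", "C2")),),
        essential=False,
    )


def generate_peaklists(
    config: SyntheticConfig,
    refs: ReferenceShiftTable | None = None,
    topologies: Mapping[str, ResidueTopology] | None = None,
) -> tuple[dict[str, PeakList], GroundTruth]:
    """Generate annotated {CP1D, DQSQ, PDSD} peak lists for one config.

    Peak intensities are proportional to mole % x labelling efficiency, with
    the configured attenuation on correlations involving quaternary carbons.
    Every peak carries its generating (residue, atom pair) annotation.
    """
    topologies = topologies or load_topologies()
    truth = sample_shifts(config, refs, topologies)
    radius = mixing_time_to_radius(config.pdsd_mixing_ms)
    lists = {
        "CP1D": PeakList(experiment="CP1D"),
        "DQSQ": PeakList(experiment="DQSQ"),
        "PDSD": PeakList(experiment="PDSD", mixing_time=config.pdsd_mixing_ms),
    }
    species: list[tuple[ResidueTopology, dict[str, float], float]] = [
        (topologies[code], truth.shifts[code], truth.intensities[code])
        for code in sorted(truth.shifts)
    ]
    if config.include_lipid:
        lip = _lipid_topology()
        lip_shifts = {"C1": LIPID_SHIFT, "C2": LIPID_SHIFT}
        species.append((lip, lip_shifts, config.lipid_intensity))
        truth.shifts[LIPID_CODE] = lip_shifts
        truth.intensities[LIPID_CODE] = config.lipid_intensity
    for topo, atom_shifts, inten in species:
        common = dict(
            base_intensity=inten,
            quaternary_attenuation=config.quaternary_attenuation,
            linewidth=config.linewidth,
        )
        lists["CP1D"].peaks.extend(predict_cp1d(atom_shifts, topo, **common).peaks)
        lists["DQSQ"].peaks.extend(
            predict_dqsq(atom_shifts, topo,
                         equivalence_window=config.equivalence_window, **common).peaks
        )
        lists["PDSD"].peaks.extend(
            predict_pdsd(atom_shifts, topo, radius=radius, **common).peaks
        )
    return lists, truth


@dataclass(frozen=True)
class GridSpec:
    """Raster extents and resolution (ppm). F1 covers the DQ range for DQ-SQ."""

    f2_min: float = 0.0
    f2_max: float = 200.0
    f1_min: float = 0.0
    f1_max: float = 400.0
    step: float = 0.1

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        # high-to-low, the NMR display convention
        f2 = np.arange(self.f2_max, self.f2_min - self.step / 2, -self.step)
        f1 = np.arange(self.f1_max, self.f1_min - self.step / 2, -self.step)
        return f1, f2


@dataclass
class SpectrumGrid:
    f1: np.ndarray  # descending, length n1
    f2: np.ndarray  # descending, length n2
    intensity: np.ndarray  # shape (n1, n2)
    experiment: str = "DQSQ"
    provenance: dict = field(default_factory=dict)
    clipped: list[Peak2D] = field(default_factory=list)


def render_spectrum(
    peaklist: PeakList,
    grid: GridSpec | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    default_linewidth: float = 1.0,
) -> SpectrumGrid:
    """Rasterize a 2D peak list as a sum of 2D Gaussians.

    Each peak contributes a Gaussian of FWHM equal to its linewidth (falling
    back to ``default_linewidth``) with unit peak height times its intensity.
    Peaks outside the grid are skipped and reported in ``clipped``.
    """
    grid = grid or GridSpec()
    f1_ax, f2_ax = grid.axes()
    inten = np.zeros((f1_ax.size, f2_ax.size))
    fwhm_to_sigma = 2.0 * np.sqrt(2.0 * np.log(2.0))
    clipped = []
    for p in peaklist.peaks:
        if p.f1 is None:
            raise ValueError("render_spectrum needs 2D peaks (f1 set)")
        if not (grid.f2_min <= p.f2 <= grid.f2_max and grid.f1_min <= p.f1 <= grid.f1_max):
            clipped.append(p)
            continue
        lw = p.linewidth or default_linewidth
        sigma = lw / fwhm_to_sigma
        # local window: +/- 5 sigma around the peak on each axis
        i1 = np.searchsorted(-f1_ax, -(p.f1 + 5 * sigma))
        j1 = np.searchsorted(-f1_ax, -(p.f1 - 5 * sigma))
        i2 = np.searchsorted(-f2_ax, -(p.f2 + 5 * sigma))
        j2 = np.searchsorted(-f2_ax, -(p.f2 - 5 * sigma))
        w1 = f1_ax[i1:j1 + 1]
        w2 = f2_ax[i2:j2 + 1]
        if w1.size == 0 or w2.size == 0:
            continue
        g1 = np.exp(-0.5 * ((w1 - p.f1) / sigma) ** 2)
        g2 = np.exp(-0.5 * ((w2 - p.f2) / sigma) ** 2)
        inten[i1:j1 + 1, i2:j2 + 1] += p.intensity * np.outer(g1, g2)
    if np.any(inten < 0):  # pragma: no cover - inputs are non-negative
        raise ValueError("negative intensity before noise")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inten = inten + rng.normal(0.0, noise_sd, size=inten.shape)
    return SpectrumGrid(
        f1=f1_ax, f2=f2_ax, intensity=inten, experiment=peaklist.experiment,
        provenance={"noise_sd": noise_sd, "seed": seed, "step": grid.step},
        clipped=clipped,
    )


def _parabolic_offset(y_m1: float, y_0: float, y_p1: float) -> float:
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom >= 0:
        return 0.0
    return 0.5 * (y_m1 - y_p1) / denom


def pick_peaks(grid: SpectrumGrid, threshold: float = 0.05) -> PeakList:
    """Local maxima above ``threshold`` x grid max, sub-pixel refined by
    3-point parabolic interpolation per axis."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    z = grid.intensity
    if z.size == 0 or np.max(z) <= 0:
        return PeakList(experiment=grid.experiment)
    local_max = z == ndimage.maximum_filter(z, size=3, mode="nearest")
    mask = local_max & (z >= threshold * np.max(z))
    step1 = float(grid.f1[0] - grid.f1[1]) if grid.f1.size > 1 else 0.0
    step2 = float(grid.f2[0] - grid.f2[1]) if grid.f2.size > 1 else 0.0
    peaks = []
    for i, j in zip(*np.nonzero(mask)):
        d1 = d2 = 0.0
        if 0 < i < z.shape[0] - 1:
            d1 = _parabolic_offset(z[i - 1, j], z[i, j], z[i + 1, j])
        if 0 < j < z.shape[1] - 1:
            d2 = _parabolic_offset(z[i, j - 1], z[i, j], z[i, j + 1])
        peaks.append(
            Peak2D(
                f2=float(grid.f2[j] - d2 * step2),
                f1=float(grid.f1[i] - d1 * step1),
                intensity=float(z[i, j]),
            )
        )
    peaks.sort(key=lambda p: -p.intensity)
    return PeakList(experiment=grid.experiment, peaks=peaks)


def synthesize_amide_profile(
    centers: tuple[float, float] = (172.5, 175.0),
    fwhm: tuple[float, float] = (2.0, 2.0),
    fractions: tuple[float, float] = (0.5, 0.5),
    noise_sd_frac: float = 0.01,
    region: tuple[float, float] = (165.0, 185.0),
    step: float = 0.05,
    seed: int | None = None,
) -> Profile1D:
    """Synthetic amide-region profile: two Gaussians with the given area
    fractions plus additive noise of sd ``noise_sd_frac`` x clean maximum."""
    lo, hi = sorted(region)
    ppm = np.arange(hi, lo - step / 2, -step)
    fwhm_to_sigma = 2.0 * np.sqrt(2.0 * np.log(2.0))
    clean = np.zeros_like(ppm)
    for c, w, frac in zip(centers, fwhm, fractions):
        amp = frac / w  # equal-area normalization: area ~ amp * fwhm
        clean += amp * np.exp(-0.5 * ((ppm - c) / (w / fwhm_to_sigma)) ** 2)
    noisy = clean
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        noisy = clean + rng.normal(0.0, noise_sd_frac * np.max(clean), size=ppm.shape)
    return Profile1D(ppm=ppm, intensity=noisy, region=(lo, hi))
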