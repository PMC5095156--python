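"""Match observed peak lists to predicted residue spin systems.

Residue-type assignment works at the level of spin systems: each amino acid
type's bond graph predicts a pattern of DQ-SQ (and PDSD) peaks, and observed
peaks are matched to those patterns by optimal one-to-one assignment under a
per-axis ppm tolerance.  Residues are processed in descending abundance
(mole %), so a peak matchable to several residue types is claimed by the
most abundant one — an abundance prior standing in for the manual judgement
that overlapped signals belong to the majority species.  The result is
assembled into an assignment table ordered by abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .peak_prediction import (
    DEFAULT_EQUIVALENCE_WINDOW,
    Peak2D,
    PeakList,
    predict_dqsq,
)
from .residue_model import (
    AMBIGUOUS_GROUPS,
    CompositionTable,
    ReferenceShiftTable,
    ResidueTopology,
    STRUCTURE_CLASSES,
)

__all__ = [
    "MatchResult",
    "SpinSystemMatch",
    "AssignmentRow",
    "AssignmentTable",
    "match_peaklist",
    "score_spin_system",
    "assign_spin_systems",
    "assemble_table",
    "DEFAULT_TOLERANCE",
    "DEFAULT_ABUNDANCE_FLOOR",
]

#: per-axis matching tolerance (ppm), a typical moderate-field ssNMR linewidth
DEFAULT_TOLERANCE = 0.5

#: mole % below which a residue type is reported 'unobserved' (His, Met scale)
DEFAULT_ABUNDANCE_FLOOR = 2.0

_BIG = 1e12


@dataclass
class MatchResult:
    """One-to-one matching between an observed and a predicted peak list."""

    pairs: list[tuple[Peak2D, Peak2D, float]]  # (observed, predicted, sq. dist)
    unmatched_observed: list[Peak2D]
    unmatched_predicted: list[Peak2D]

    @property
    def score(self) -> float:
        """Total squared ppm distance over matched pairs (0 iff exact)."""
        return float(sum(d for _, _, d in self.pairs))

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _sorted_peaks(peaks: Iterable[Peak2D]) -> list[Peak2D]:
    # deterministic processing order: lower f2, then lower f1
    return sorted(peaks, key=lambda p: (p.f2, -np.inf if p.f1 is None else p.f1))


def match_peaklist(
    observed: PeakList,
    predicted: PeakList,
    tolerance: float = DEFAULT_TOLERANCE,
    f1_tolerance: float | None = None,
) -> MatchResult:
    """Optimal one-to-one matching minimizing total squared ppm distance.

    A pairing is admissible only if each axis differs by at most its
    tolerance: ``tolerance`` on F2, ``f1_tolerance`` on F1 (defaulting to
    the same value).  In DQ-SQ spectra the DQ coordinate is a sum of two
    shifts and so carries both partners' deviations — callers matching DQ
    data pass a wider ``f1_tolerance`` (the assignment pipeline uses twice
    the SQ tolerance).  Both lists must carry the same experiment tag.
    """
    if observed.experiment != predicted.experiment:
        raise ValueError(
            f"experiment mismatch: {observed.experiment} vs {predicted.experiment}"
        )
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if f1_tolerance is None:
        f1_tolerance = tolerance
    obs = _sorted_peaks(observed.peaks)
    pred = _sorted_peaks(predicted.peaks)
    if not obs or not pred:
        return MatchResult([], list(obs), list(pred))

    cost = np.full((len(obs), len(pred)), _BIG)
    for i, po in enumerate(obs):
        for j, pp in enumerate(pred):
            d2 = po.f2 - pp.f2
            d1 = 0.0
            if po.f1 is not None or pp.f1 is not None:
                if po.f1 is None or pp.f1 is None:
                    continue  # dimensionality mismatch: inadmissible
                d1 = po.f1 - pp.f1
            if abs(d2) <= tolerance and abs(d1) <= f1_tolerance:
                cost[i, j] = d2 * d2 + d1 * d1
    rows, cols = linear_sum_assignment(cost)
    pairs, mo, mp = [], set(), set()
    for i, j in zip(rows, cols):
        if cost[i, j] < _BIG:
            pairs.append((obs[i], pred[j], float(cost[i, j])))
            mo.add(i)
            mp.add(j)
    return MatchResult(
        pairs=pairs,
        unmatched_observed=[p for i, p in enumerate(obs) if i not in mo],
        unmatched_predicted=[p for j, p in enumerate(pred) if j not in mp],
    )


@dataclass
class SpinSystemMatch:
    """One residue type's match against an observed peak list."""

    residue: str
    atom_shifts: dict[str, float]
    n_matched: int
    n_predicted: int
    score: float
    resolved: bool = False
    class_hint: str | None = None  # reference-class hypothesis that matched best
    ambiguous_peaks: int = 0

    def __post_init__(self) -> None:
        if self.n_matched > self.n_predicted:
            raise ValueError("n_matched cannot exceed n_predicted")


def _consensus_shifts(pairs) -> dict[str, float]:
    """Per-atom consensus from matched DQ-SQ peaks.

    Each matched peak contributes its F2 coordinate to the F2-side atom and,
    via the DQ sum rule, ``f1 - f2`` to the partner atom — the same way a
    partner shift is read off the DQ coordinate of a cross peak.  Collapsed
    autocorrelation peaks contribute F2 to both equivalent atoms.
    """
    acc: dict[str, list[float]] = {}
    for obs, pred, _d in pairs:
        if pred.f1 is not None and pred.atom_j is not None and pred.atom_j != pred.atom_i:
            if abs(2.0 * pred.f2 - pred.f1) < 1e-9:
                # collapsed autocorrelation: F2 is the shared shift
                acc.setdefault(pred.atom_i, []).append(obs.f2)
                acc.setdefault(pred.atom_j, []).append(obs.f2)
            else:
                acc.setdefault(pred.atom_i, []).append(obs.f2)
                if obs.f1 is not None:
                    acc.setdefault(pred.atom_j, []).append(obs.f1 - obs.f2)
        elif pred.atom_i is not None:
            acc.setdefault(pred.atom_i, []).append(obs.f2)
    return {a: float(np.mean(v)) for a, v in sorted(acc.items())}


def score_spin_system(
    observed: PeakList,
    residue: str,
    candidate_shifts: Mapping[str, float],
    topology: ResidueTopology,
    tolerance: float = DEFAULT_TOLERANCE,
    equivalence_window: float = DEFAULT_EQUIVALENCE_WINDOW,
    competing_predictions: Sequence[PeakList] = (),
) -> SpinSystemMatch:
    """Match one residue's predicted DQ-SQ pattern against observed peaks.

    ``competing_predictions`` (other residues' predicted lists) determine the
    ``resolved`` flag: the spin system is resolved when at least one of its
    matched peaks has no competing predicted peak within tolerance.
    """
    if residue != topology.code:
        raise KeyError(f"topology is for {topology.code}, not {residue}")
    predicted = predict_dqsq(candidate_shifts, topology,
                             equivalence_window=equivalence_window)
    f1_tol = 2.0 * tolerance if observed.experiment == "DQSQ" else tolerance
    result = match_peaklist(observed, predicted, tolerance, f1_tolerance=f1_tol)
    resolved = False
    for obs, _pred, _d in result.pairs:
        clash = False
        for other in competing_predictions:
            for op in other.peaks:
                if (abs(op.f2 - obs.f2) <= tolerance
                        and obs.f1 is not None and op.f1 is not None
                        and abs(op.f1 - obs.f1) <= f1_tol):
                    clash = True
                    break
            if clash:
                break
        if not clash:
            resolved = True
            break
    return SpinSystemMatch(
        residue=residue,
        atom_shifts=_consensus_shifts(result.pairs),
        n_matched=result.n_matched,
        n_predicted=len(predicted),
        score=result.score,
        resolved=resolved,
    )


def assign_spin_systems(
    observed: PeakList,
    refs: ReferenceShiftTable,
    topologies: Mapping[str, ResidueTopology],
    composition: CompositionTable,
    tolerance: float = DEFAULT_TOLERANCE,
    equivalence_window: float = DEFAULT_EQUIVALENCE_WINDOW,
) -> list[SpinSystemMatch]:
    """Assign every composition residue type against the observed peak list.

    For each residue (most abundant first, alphabetical tie-break) every
    structure-class reference hypothesis is tried; the hypothesis matching
    the most peaks (lowest score on ties) wins.  Matching is non-exclusive —
    overlapped signals genuinely superimpose, and one observed peak may
    support several residue types — but any matched peak that also falls
    within tolerance of another residue's winning prediction is counted as
    ambiguous and, by the abundance prior, leaves the residue 'resolved'
    only if at least one unambiguous peak remains.
    """
    expanded = composition.expanded()
    f1_tol = 2.0 * tolerance if observed.experiment == "DQSQ" else tolerance
    order = sorted(expanded.items(), key=lambda kv: (-kv[1], kv[0]))
    prelim: list[tuple[str, MatchResult, str, PeakList]] = []
    for code, _pct in order:
        if code not in topologies:
            continue
        topo = topologies[code]
        best = None
        for cls in STRUCTURE_CLASSES:
            shifts = {
                a: refs.lookup(code, a, cls)[0]
                for a in topo.atoms
                if refs.has(code, a, cls)
            }
            if not shifts:
                continue
            predicted = predict_dqsq(shifts, topo, equivalence_window=equivalence_window)
            result = match_peaklist(observed, predicted, tolerance, f1_tolerance=f1_tol)
            key = (-result.n_matched, result.score)
            if best is None or key < best[0]:
                best = (key, cls, result, predicted)
        if best is None:
            continue
        _key, cls, result, predicted = best
        prelim.append((code, result, cls, predicted))

    # resolved / ambiguity flags against every other residue's winning prediction
    matches = []
    for code, result, cls, predicted in prelim:
        others = [p for c, _r, _cl, p in prelim if c != code]
        resolved = False
        ambiguous = 0
        for obs, _pred, _d in result.pairs:
            clash = any(
                abs(op.f2 - obs.f2) <= tolerance
                and op.f1 is not None and obs.f1 is not None
                and abs(op.f1 - obs.f1) <= f1_tol
                for other in others
                for op in other.peaks
            )
            if clash:
                ambiguous += 1
            else:
                resolved = True
        matches.append(
            SpinSystemMatch(
                residue=code,
                atom_shifts=_consensus_shifts(result.pairs),
                n_matched=result.n_matched,
                n_predicted=len(predicted),
                score=result.score,
                resolved=resolved,
                class_hint=cls,
                ambiguous_peaks=ambiguous,
            )
        )
    return matches


@dataclass
class AssignmentRow:
    residue: str  # may be a grouped code like 'E/Q'
    atom_shifts: dict[str, float] = field(default_factory=dict)
    index: float | None = None
    structure_class: str | None = None
    mole_percent: float = 0.0
    certainty: str = "tentative"  # high | tentative | unobserved

    def with_structure(self, index, structure_class) -> "AssignmentRow":
        return dc_replace(self, index=index, structure_class=structure_class)


_DISPLAY_ATOMS = (
    ("CO", ("CO",)),
    ("CA", ("CA",)),
    ("CB", ("CB",)),
    ("CG", ("CG", "CG1")),
    ("CG2", ("CG2",)),
    ("CD", ("CD", "CD1", "CD2")),
    ("CE", ("CE", "CE1")),
    ("CZ", ("CZ",)),
)


@dataclass
class AssignmentTable:
    """Table-style summary: one row per residue type, ordered by mole %."""

    rows: list[AssignmentRow]

    def __post_init__(self) -> None:
        self.rows = sorted(self.rows, key=lambda r: (-r.mole_percent, r.residue))

    def row(self, residue: str) -> AssignmentRow:
        for r in self.rows:
            if r.residue == residue:
                return r
        raise KeyError(residue)

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec: dict = {"residue": r.residue}
            for col, sources in _DISPLAY_ATOMS:
                vals = [r.atom_shifts[a] for a in sources if a in r.atom_shifts]
                rec[col] = float(np.mean(vals)) if vals else np.nan
            rec["dCA_minus_dCB"] = r.index if r.index is not None else np.nan
            rec["class"] = r.structure_class or ""
            rec["mole_percent"] = r.mole_percent
            rec["certainty"] = r.certainty
            records.append(rec)
        cols = ["residue"] + [c for c, _ in _DISPLAY_ATOMS] + [
            "dCA_minus_dCB", "class", "mole_percent", "certainty",
        ]
        return pd.DataFrame.from_records(records, columns=cols)


def assemble_table(
    matches: Iterable[SpinSystemMatch],
    composition: CompositionTable,
    abundance_floor: float = DEFAULT_ABUNDANCE_FLOOR,
) -> AssignmentTable:
    """Assemble matches into an abundance-ordered assignment table.

    Grouped composition entries (E/Q, D/N) merge their members' matches.
    Residues below ``abundance_floor`` mole % are flagged 'unobserved';
    matched residues are 'high' only when their spin system is resolved.
    """
    by_residue: dict[str, SpinSystemMatch] = {}
    for m in matches:
        if m.residue in by_residue:
            raise ValueError(f"multiple matches for residue {m.residue}")
        by_residue[m.residue] = m
    rows = []
    for code, pct in composition.mole_percent.items():
        members = AMBIGUOUS_GROUPS.get(code, (code,))
        member_matches = [by_residue[m] for m in members if m in by_residue]
        shifts: dict[str, float] = {}
        n_matched = 0
        resolved = False
        for m in member_matches:
            n_matched += m.n_matched
            resolved = resolved or m.resolved
            for a, v in m.atom_shifts.items():
                shifts.setdefault(a, v)
        if pct < abundance_floor and n_matched == 0:
            certainty = "unobserved"
        elif n_matched == 0:
            certainty = "unobserved"
        elif resolved and len(members) == 1 and pct >= abundance_floor:
            certainty = "high"
        else:
            certainty = "tentative"
        rows.append(
            AssignmentRow(
                residue=code,
                atom_shifts=shifts,
                mole_percent=pct,
                certainty=certainty,
            )
        )
    return AssignmentTable(rows=rows)
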