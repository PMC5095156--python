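"""Secondary-structure inference from the dCA - dCB chemical-shift index.

Helix and sheet/coil environments push the Calpha and Cbeta shifts in
opposite directions, so their difference

    index = delta(Calpha) - delta(Cbeta)

is a structure indicator that is invariant to the global referencing
convention — any constant offset added to all shifts cancels.  A residue is
classified by comparing its observed index against the per-class reference
index (reference CA minus reference CB for helix, sheet and coil) and taking
the nearest class.  Glycine, lacking Cbeta, is never classified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .residue_model import ReferenceShiftTable, STRUCTURE_CLASSES

__all__ = ["StructureIndexResult", "compute_index", "classify", "classify_table"]

UNDEFINED = "undefined"

#: deterministic precedence used when two classes are exactly equidistant
_TIE_ORDER = {"H": 0, "S": 1, "C": 2}


@dataclass(frozen=True)
class StructureIndexResult:
    residue: str
    dCA: float | None
    dCB: float | None
    index: float | None
    structure_class: str
    margin: float | None
    tie: bool = False


def compute_index(dCA: float | None, dCB: float | None) -> float | None:
    """Signed chemical-shift index dCA - dCB; None when either shift is
    missing (the Gly case), signalling an undefined index rather than
    raising."""
    if dCA is None or dCB is None:
        return None
    if not (math.isfinite(dCA) and math.isfinite(dCB)):
        raise ValueError("chemical shifts must be finite")
    return dCA - dCB


def classify(
    residue: str,
    index: float | None,
    refs: ReferenceShiftTable,
) -> tuple[str, float | None, bool]:
    """Nearest-reference classification of one residue's index.

    Returns ``(class, margin, tie)`` where margin is the distance gap between
    the best and second-best class references.  Exact ties resolve by the
    fixed precedence helix > sheet > coil and are flagged.
    """
    if index is None:
        return UNDEFINED, None, False
    try:
        distances = {
            cls: abs(index - refs.class_index(residue, cls))
            for cls in STRUCTURE_CLASSES
        }
    except KeyError as exc:
        raise KeyError(
            f"reference table lacks CA/CB entries needed to classify {residue}: {exc}"
        ) from exc
    ordered = sorted(distances.items(), key=lambda kv: (kv[1], _TIE_ORDER[kv[0]]))
    best, second = ordered[0], ordered[1]
    margin = second[1] - best[1]
    return best[0], margin, math.isclose(best[1], second[1], abs_tol=1e-12)


def index_result(
    residue: str,
    dCA: float | None,
    dCB: float | None,
    refs: ReferenceShiftTable,
) -> StructureIndexResult:
    """Convenience: compute the index and classify in one step."""
    idx = compute_index(dCA, dCB)
    cls, margin, tie = classify(residue, idx, refs)
    return StructureIndexResult(
        residue=residue, dCA=dCA, dCB=dCB, index=idx,
        structure_class=cls, margin=margin, tie=tie,
    )


def classify_table(assignments, refs: ReferenceShiftTable):
    """Populate the structure-class column of an assignment table.

    Every residue with both CA and CB shifts gains a class; Gly and residues
    without both backbone shifts become 'undefined'.  Returns a new table.
    """
    from .assignment import AssignmentTable  # local import to avoid a cycle

    rows = []
    for row in assignments.rows:
        dCA, dCB = row.atom_shifts.get("CA"), row.atom_shifts.get("CB")
        try:
            res = index_result(row.residue, dCA, dCB, refs)
            rows.append(row.with_structure(res.index, res.structure_class))
        except KeyError:
            # grouped rows (E/Q, D/N) and residues without class references
            # keep their index but stay unclassified
            rows.append(row.with_structure(compute_index(dCA, dCB), UNDEFINED))
    return AssignmentTable(rows=rows)
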