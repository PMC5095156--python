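"""Amino acid carbon bond graphs and reference chemical shifts.

The residue-type spin systems observed in 2D DQ-SQ and PDSD correlation
experiments on uniformly 13C-labelled protein are determined entirely by the
carbon-carbon bond graph of each amino acid type.  This module packages those
graphs (20 standard residues, collapsed aromatic-equivalence convention), the
observed fur-keratin shift fixture, the per-structure-class reference shift
table used for classification and simulation, and the measured amino acid
composition.

Atom labels are ASCII (CO, CA, CB, CG, CG2, CD, CE, CZ, ...); a mapping to
Greek display names (C=O, Calpha, ...) is provided for reports.  Carbons bonded
only through heteroatoms (Arg CZ guanidinium, Met CE thioether, His CE1) are
isolated nodes of the carbon graph: they produce no one-bond DQ-SQ peak but
still appear in 1D spectra and on the PDSD diagonal.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ResidueTopology",
    "ReferenceShiftTable",
    "CompositionTable",
    "load_topologies",
    "bonded_pairs",
    "proximity_pairs",
    "load_observed_shifts",
    "fur_reference_table",
    "csi_reference_table",
    "load_composition",
    "GREEK_NAMES",
    "AMBIGUOUS_GROUPS",
]

STRUCTURE_CLASSES = ("H", "S", "C")
CLASS_INDEPENDENT = "*"

#: ASCII atom label -> conventional display name.
GREEK_NAMES = {
    "CO": "C=O", "CA": "Cα", "CB": "Cβ", "CG": "Cγ", "CG1": "Cγ1",
    "CG2": "Cγ2", "CD": "Cδ", "CD1": "Cδ1", "CD2": "Cδ2", "CE": "Cε",
    "CE1": "Cε1", "CE2": "Cε2", "CE3": "Cε3", "CZ": "Cζ", "CZ2": "Cζ2",
    "CZ3": "Cζ3", "CH2": "Cη2",
}

#: Composition-table group codes that hydrolysis cannot distinguish.
AMBIGUOUS_GROUPS = {"E/Q": ("E", "Q"), "D/N": ("D", "N")}


def _data_path(name: str) -> Path:
    return Path(resources.files("kerassign").joinpath("data", name))


def _read_csv(name_or_path) -> pd.DataFrame:
    return pd.read_csv(name_or_path, comment="#", skip_blank_lines=True)


@dataclass(frozen=True)
class ResidueTopology:
    """Carbon bond graph of one amino acid type."""

    code: str
    atoms: tuple[str, ...]
    bonds: frozenset[frozenset[str]]
    equivalent_groups: tuple[frozenset[str], ...] = ()
    #: collapsed convention only: representative atom -> the near-equivalent
    #: ring positions it stands for (e.g. CD -> (CD1, CD2) in Phe/Tyr)
    collapsed_members: tuple[tuple[str, tuple[str, ...]], ...] = ()
    quaternary: frozenset[str] = frozenset()
    essential: bool = False

    def __post_init__(self) -> None:
        atom_set = set(self.atoms)
        for bond in self.bonds:
            if len(bond) != 2:
                raise ValueError(f"{self.code}: self-edge or malformed bond {set(bond)}")
            if not bond <= atom_set:
                raise ValueError(f"{self.code}: bond references unknown atom {set(bond)}")
        for group in self.equivalent_groups:
            if not group <= atom_set:
                raise ValueError(f"{self.code}: equivalence group atom not in atoms")
        # the bonded part of the graph must be a single connected component;
        # hetero-bonded carbons (Arg CZ, Met CE, His CE1) may sit isolated
        bonded = {a for b in self.bonds for a in b}
        if bonded:
            seen = {next(iter(sorted(bonded)))}
            frontier = deque(seen)
            adj = self._adjacency()
            while frontier:
                for nb in adj[frontier.popleft()]:
                    if nb not in seen:
                        seen.add(nb)
                        frontier.append(nb)
            if seen != bonded:
                raise ValueError(f"{self.code}: bonded carbon graph is disconnected")

    def _adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {a: set() for a in self.atoms}
        for bond in self.bonds:
            i, j = sorted(bond)
            adj[i].add(j)
            adj[j].add(i)
        return adj

    @property
    def isolated_atoms(self) -> frozenset[str]:
        """Carbons with no C-C bond (bonded only through heteroatoms)."""
        bonded = {a for b in self.bonds for a in b}
        return frozenset(set(self.atoms) - bonded)


def bonded_pairs(topology: ResidueTopology) -> set[frozenset[str]]:
    """Unordered one-bond carbon pairs: the spin pairs a DQ-SQ experiment sees."""
    return set(topology.bonds)


def proximity_pairs(topology: ResidueTopology, radius: int) -> set[frozenset[str]]:
    """All unordered atom pairs within ``radius`` bonds (graph distance <= k).

    Models the growth of the spin-diffusion transfer radius with PDSD mixing
    time; ``radius=1`` is exactly the bond set.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    adj = topology._adjacency()
    pairs: set[frozenset[str]] = set()
    for start in topology.atoms:
        dist = {start: 0}
        frontier = deque([start])
        while frontier:
            node = frontier.popleft()
            if dist[node] == radius:
                continue
            for nb in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    frontier.append(nb)
        for other, d in dist.items():
            if other != start and d <= radius:
                pairs.add(frozenset((start, other)))
    return pairs


_EXPAND = {"CD": ("CD1", "CD2"), "CE": ("CE1", "CE2")}


def _expand_aromatic(code, atoms, bonds, quaternary):
    """Split collapsed Phe/Tyr ring representatives into their two members,
    restoring the six-membered ring closure."""
    new_atoms = []
    for a in atoms:
        new_atoms.extend(_EXPAND.get(a, (a,)))
    new_bonds = {
        frozenset(p) for p in [
            ("CO", "CA"), ("CA", "CB"), ("CB", "CG"),
            ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
        ]
    }
    groups = (frozenset(("CD1", "CD2")), frozenset(("CE1", "CE2")))
    return tuple(new_atoms), frozenset(new_bonds), groups, frozenset(quaternary)


def load_topologies(expanded: bool = False) -> dict[str, ResidueTopology]:
    """Load the packaged bond graphs for the 20 standard amino acids.

    With ``expanded=True`` the near-equivalent Phe/Tyr ring positions
    (CD1/CD2, CE1/CE2) are kept as distinct atoms; by default they are
    collapsed to single representatives, matching the one-shift-per-position
    reporting convention of the observed data.
    """
    try:
        atoms_df = _read_csv(_data_path("topology_atoms.csv"))
        bonds_df = _read_csv(_data_path("topology_bonds.csv"))
        res_df = _read_csv(_data_path("residues.csv"))
    except Exception as exc:  # pragma: no cover - packaging failure
        raise RuntimeError(f"malformed packaged topology data: {exc}") from exc
    essential = dict(zip(res_df["residue"], res_df["essential"].astype(bool)))
    topologies: dict[str, ResidueTopology] = {}
    for code, sub in atoms_df.groupby("residue", sort=False):
        atoms = tuple(sub["atom"])
        quaternary = frozenset(sub.loc[sub["quaternary"] == 1, "atom"])
        members = tuple(
            (str(r.atom), tuple(str(r.equiv_members).split("/")))
            for r in sub.itertuples()
            if isinstance(r.equiv_members, str) and r.equiv_members.strip()
        )
        bonds = frozenset(
            frozenset((r.atom_i, r.atom_j))
            for r in bonds_df[bonds_df["residue"] == code].itertuples()
        )
        groups: tuple[frozenset[str], ...] = ()
        if expanded and code in ("F", "Y"):
            atoms, bonds, groups, quaternary = _expand_aromatic(
                code, atoms, bonds, quaternary
            )
            members = ()
        topologies[code] = ResidueTopology(
            code=code, atoms=atoms, bonds=bonds, equivalent_groups=groups,
            collapsed_members=members, quaternary=quaternary,
            essential=essential[code],
        )
    if len(topologies) != 20:
        raise RuntimeError(
            f"packaged topology data defines {len(topologies)} residues, expected 20"
        )
    return topologies


@dataclass
class ReferenceShiftTable:
    """Mean shift (ppm, TSP scale) per (residue, atom, structure class).

    Class '*' marks class-independent entries; :meth:`lookup` falls back to
    them when no class-specific entry exists.
    """

    entries: dict[tuple[str, str, str], tuple[float, float]]
    provenance: dict[tuple[str, str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (res, atom, cls), (shift, _sd) in self.entries.items():
            if not 0.0 <= shift <= 220.0:
                raise ValueError(
                    f"reference shift out of 13C range: {res} {atom} {cls} = {shift}"
                )

    def lookup(self, residue: str, atom: str, structure_class: str = CLASS_INDEPENDENT):
        """Return (mean, sd) for the entry, falling back to class-independent."""
        key = (residue, atom, structure_class)
        if key in self.entries:
            return self.entries[key]
        key = (residue, atom, CLASS_INDEPENDENT)
        if key in self.entries:
            return self.entries[key]
        raise KeyError(
            f"no reference shift for residue {residue} atom {atom} class {structure_class}"
        )

    def has(self, residue: str, atom: str, structure_class: str = CLASS_INDEPENDENT) -> bool:
        try:
            self.lookup(residue, atom, structure_class)
            return True
        except KeyError:
            return False

    def atoms_for(self, residue: str) -> set[str]:
        return {atom for (res, atom, _cls) in self.entries if res == residue}

    def class_index(self, residue: str, structure_class: str) -> float:
        """Reference dCA - dCB for one structure class."""
        ca, _ = self.lookup(residue, "CA", structure_class)
        cb, _ = self.lookup(residue, "CB", structure_class)
        return ca - cb

    @classmethod
    def from_csv(cls, path) -> "ReferenceShiftTable":
        df = _read_csv(path).rename(columns={"class": "structure_class"})
        entries, prov = {}, {}
        for row in df.itertuples():
            key = (row.residue, row.atom, str(row.structure_class))
            entries[key] = (float(row.shift_ppm), float(row.sd_ppm))
            prov[key] = str(row.provenance)
        return cls(entries=entries, provenance=prov)


def load_observed_shifts(provenance: str | None = "table1") -> pd.DataFrame:
    """Observed fur-keratin shift fixture as a DataFrame.

    ``provenance`` filters to one source ('table1' or 'fig1_text');
    ``None`` returns every row.
    """
    df = _read_csv(_data_path("observed_shifts_fur.csv"))
    if provenance is not None:
        df = df[df["provenance"] == provenance].reset_index(drop=True)
    return df


def fur_reference_table(provenance: str = "table1") -> ReferenceShiftTable:
    """Class-independent reference table built from the observed fur shifts."""
    df = load_observed_shifts(provenance)
    entries, prov = {}, {}
    for row in df.itertuples():
        key = (row.residue, row.atom, CLASS_INDEPENDENT)
        entries[key] = (float(row.shift_ppm), 0.5)
        prov[key] = f"{row.provenance}:{row.certainty}"
    return ReferenceShiftTable(entries=entries, provenance=prov)


def csi_reference_table(path=None) -> ReferenceShiftTable:
    """Per-class CA/CB/CO reference table plus class-independent side chains.

    This is the default generative/classification table: CA and CB carry the
    helix/sheet/coil dependence of the chemical shift index, CO carries the
    two-component amide split, side chains are class-independent.
    """
    return ReferenceShiftTable.from_csv(path or _data_path("reference_shifts.csv"))


@dataclass
class CompositionTable:
    """Amino acid composition (mole %) with optional labelling efficiencies.

    Keys may be grouped codes ('E/Q', 'D/N') for pairs indistinguishable
    after hydrolysis; :meth:`expanded` splits them evenly over their members.
    """

    mole_percent: dict[str, float]
    labelling_efficiency: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, pct in self.mole_percent.items():
            if pct < 0:
                raise ValueError(f"negative mole % for {code}")
        total = sum(self.mole_percent.values())
        if total > 100.0 + 1e-9:
            raise ValueError(f"mole % sums to {total:.2f} > 100")
        for code, eff in self.labelling_efficiency.items():
            if not 0.0 <= eff <= 1.0:
                raise ValueError(f"labelling efficiency out of [0,1] for {code}")

    def expanded(self) -> dict[str, float]:
        """Per-single-residue mole %, splitting grouped codes evenly."""
        out: dict[str, float] = {}
        for code, pct in self.mole_percent.items():
            members = AMBIGUOUS_GROUPS.get(code, (code,))
            for m in members:
                out[m] = out.get(m, 0.0) + pct / len(members)
        return out

    @classmethod
    def from_csv(cls, path) -> "CompositionTable":
        df = _read_csv(path)
        eff = {}
        if "labelling_efficiency" in df.columns:
            eff = {
                r.residue: float(r.labelling_efficiency)
                for r in df.itertuples()
                if pd.notna(r.labelling_efficiency)
            }
        return cls(
            mole_percent={r.residue: float(r.mole_percent) for r in df.itertuples()},
            labelling_efficiency=eff,
        )


def load_composition() -> CompositionTable:
    """Measured fur amino acid composition (mole %)."""
    return CompositionTable.from_csv(_data_path("composition_fur.csv"))
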