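"""Readers and writers for peak lists, profiles and assignment tables.

Two peak-list dialects are supported: the package's own tabular format
(comma-separated, header ``experiment,f1_ppm,f2_ppm,intensity,
linewidth_ppm,residue,atom_i,atom_j``) and a Sparky-style assignment-label
format (``label w1 w2 height`` whitespace-separated, e.g.
``Y_CE-CZ 271.0 116.0 1.0`` with w1 the indirect F1 coordinate).  Lines
starting with ``#`` are comments; every writer embeds its generating
parameters as ``#`` header lines for provenance.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Mapping

import pandas as pd

from .amide_decomposition import Profile1D
from .peak_prediction import Peak2D, PeakList

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "write_sparky",
    "read_profile",
    "write_profile",
    "write_table",
    "PeakListFormatError",
]

_CSV_COLUMNS = [
    "experiment", "f1_ppm", "f2_ppm", "intensity", "linewidth_ppm",
    "residue", "atom_i", "atom_j",
]


class PeakListFormatError(ValueError):
    pass


def _provenance_header(params: Mapping | None) -> str:
    if not params:
        return ""
    lines = [f"# {k} = {v}" for k, v in params.items()]
    return "\n".join(lines) + "\n"


def write_peaklist(peaklist: PeakList, path, params: Mapping | None = None) -> None:
    """Write a peak list in the tabular csv dialect with provenance header."""
    path = Path(path)
    rows = []
    for p in peaklist.peaks:
        rows.append({
            "experiment": peaklist.experiment,
            "f1_ppm": "" if p.f1 is None else p.f1,
            "f2_ppm": p.f2,
            "intensity": p.intensity,
            "linewidth_ppm": "" if p.linewidth is None else p.linewidth,
            "residue": p.residue or "",
            "atom_i": p.atom_i or "",
            "atom_j": p.atom_j or "",
        })
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    header = _provenance_header(params)
    if peaklist.mixing_time is not None:
        header += f"# mixing_time_ms = {peaklist.mixing_time}\n"
    header += f"# referencing_offset_ppm = {peaklist.referencing_offset}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def write_sparky(peaklist: PeakList, path, params: Mapping | None = None) -> None:
    """Write a 2D peak list in the Sparky-style ``label w1 w2 height`` dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(params))
        for p in peaklist.peaks:
            if p.f1 is None:
                raise PeakListFormatError("sparky dialect requires 2D peaks")
            if p.residue and p.atom_i:
                label = f"{p.residue}_{p.atom_i}" + (f"-{p.atom_j}" if p.atom_j else "")
            else:
                label = "?"
            fh.write(f"{label} {p.f1:.3f} {p.f2:.3f} {p.intensity:.6g}\n")


def _parse_sparky_label(label: str):
    residue = atom_i = atom_j = None
    if label != "?" and "_" in label:
        residue, _, atoms = label.partition("_")
        atom_i, _, atom_j = atoms.partition("-")
        atom_i = atom_i or None
        atom_j = atom_j or None
    return residue, atom_i, atom_j


def _read_sparky(lines, experiment: str) -> PeakList:
    peaks, bad = [], []
    for lineno, line in lines:
        parts = line.split()
        if len(parts) < 3:
            bad.append(lineno)
            continue
        try:
            w1, w2 = float(parts[1]), float(parts[2])
            height = float(parts[3]) if len(parts) > 3 else 1.0
        except ValueError:
            bad.append(lineno)
            continue
        if height < 0:
            warnings.warn(f"line {lineno}: negative intensity, row rejected")
            continue
        residue, atom_i, atom_j = _parse_sparky_label(parts[0])
        peaks.append(Peak2D(f2=w2, f1=w1, intensity=height,
                            residue=residue, atom_i=atom_i, atom_j=atom_j))
    if bad:
        raise PeakListFormatError(f"malformed sparky rows at lines {bad}")
    return PeakList(experiment=experiment, peaks=peaks)


def read_peaklist(path, dialect: str | None = None, experiment: str = "DQSQ") -> PeakList:
    """Read a peak list, auto-detecting the dialect from the header.

    Rows with negative intensity are rejected with a diagnostic warning;
    structurally malformed rows raise :class:`PeakListFormatError` listing
    their line numbers.
    """
    path = Path(path)
    raw = [
        (i + 1, ln.strip())
        for i, ln in enumerate(path.read_text().splitlines())
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not raw:
        raise PeakListFormatError(f"{path}: empty peak list file")
    if dialect is None:
        dialect = "csv" if raw[0][1].lower().startswith("experiment") else "sparky"
    if dialect == "sparky":
        return _read_sparky(raw, experiment)
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    missing = {"experiment", "f2_ppm", "intensity"} - set(df.columns)
    if missing:
        raise PeakListFormatError(f"{path}: missing columns {sorted(missing)}")
    exps = df["experiment"].unique()
    if len(exps) != 1:
        raise PeakListFormatError(f"{path}: mixed experiment tags {list(exps)}")
    peaks = []
    bad = []
    for i, row in df.iterrows():
        try:
            inten = float(row["intensity"])
            if inten < 0:
                warnings.warn(f"row {i}: negative intensity, row rejected")
                continue
            f1 = row.get("f1_ppm")
            lw = row.get("linewidth_ppm")
            peaks.append(Peak2D(
                f2=float(row["f2_ppm"]),
                f1=None if pd.isna(f1) or f1 == "" else float(f1),
                intensity=inten,
                linewidth=None if pd.isna(lw) or lw == "" else float(lw),
                residue=None if pd.isna(row.get("residue")) else str(row.get("residue")) or None,
                atom_i=None if pd.isna(row.get("atom_i")) else str(row.get("atom_i")) or None,
                atom_j=None if pd.isna(row.get("atom_j")) else str(row.get("atom_j")) or None,
            ))
        except (TypeError, ValueError):
            bad.append(int(i) + 2)  # +2: header line and 1-basing
    if bad:
        raise PeakListFormatError(f"{path}: malformed rows at lines {bad}")
    return PeakList(experiment=str(exps[0]), peaks=peaks)


def write_profile(profile: Profile1D, path, params: Mapping | None = None) -> None:
    """Two-column (ppm, intensity) text profile with provenance header."""
    with open(path, "w") as fh:
        fh.write(_provenance_header(params))
        fh.write("ppm,intensity\n")
        for x, y in zip(profile.ppm, profile.intensity):
            fh.write(f"{x:.5f},{y:.8g}\n")


def read_profile(path, region=None) -> Profile1D:
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    if df.empty:
        raise PeakListFormatError(f"{path}: empty profile file")
    kwargs = {} if region is None else {"region": tuple(region)}
    return Profile1D(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), **kwargs)


def write_table(df: pd.DataFrame, path, params: Mapping | None = None) -> None:
    """Write any tabular result (e.g. an assignment table) with provenance."""
    with open(path, "w") as fh:
        fh.write(_provenance_header(params))
        df.to_csv(fh, index=False)
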