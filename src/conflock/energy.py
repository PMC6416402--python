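"""Per-residue-pair interaction-energy traces and summary tables.

Traces arrive as GROMACS ``gmx energy`` XVG output, one file per residue
pair per short-range component (Coulombic ``coul_sr`` or Lennard-Jones
``lj_sr``), time in ps and energy in kJ/mol.  Summaries reduce a pair's two
component traces to time-averaged electrostatic / van-der-Waals / total
energies, the quantities tabulated for an interface.

The reference per-pair summary tables for the bovine Cu,Zn-SOD dimer
interface (4 hydrogen-bond pairs, 25 hydrophobic pairs, and their two
conformational-lock groups) ship as packaged CSVs; see
:func:`load_reference_tables` and :func:`load_reference_groups`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structure import ResidueId

__all__ = [
    "EnergyComponent",
    "EnergyTrace",
    "PairEnergySummary",
    "EnergyTableSummary",
    "XVGParseError",
    "read_xvg",
    "write_xvg",
    "average_energy",
    "summarize_pair",
    "aggregate_table",
    "dominant_component",
    "load_reference_tables",
    "load_reference_groups",
    "summaries_from_csv",
    "summaries_to_csv",
]

CSV_COLUMNS = ["pair", "kind", "electrostatic_kJ_mol", "vdw_kJ_mol", "total_kJ_mol"]


class EnergyComponent(str, Enum):
    COUL_SR = "coul_sr"
    LJ_SR = "lj_sr"
    TOTAL = "total"


class XVGParseError(ValueError):
    pass


def _parse_pair(pair) -> tuple[ResidueId, ResidueId]:
    if isinstance(pair, str):
        a, b = pair.split("-")
        return (ResidueId.from_label(a), ResidueId.from_label(b))
    a, b = pair
    return (a, b)


@dataclass
class EnergyTrace:
    """Time series of one energy component for one residue pair."""

    pair: tuple[ResidueId, ResidueId]
    component: EnergyComponent
    times: np.ndarray   # ps, strictly increasing
    values: np.ndarray  # kJ/mol
    title: str = ""

    def __post_init__(self) -> None:
        self.pair = _parse_pair(self.pair)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.component = EnergyComponent(self.component)
        if self.times.shape != self.values.shape or self.times.size < 2:
            raise ValueError("times and values must match and have length >= 2")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def pair_label(self) -> str:
        return f"{self.pair[0].label}-{self.pair[1].label}"

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class PairEnergySummary:
    """One table row: time-averaged component energies for a residue pair."""

    pair: str
    kind: str  # "hydrogen_bond" | "hydrophobic"
    electrostatic: float
    vdw: float
    total: float

    def as_dict(self) -> dict:
        return {
            "pair": self.pair, "kind": self.kind,
            "electrostatic_kJ_mol": self.electrostatic,
            "vdw_kJ_mol": self.vdw, "total_kJ_mol": self.total,
        }


@dataclass
class EnergyTableSummary:
    rows: list[PairEnergySummary]
    total_electrostatic: float
    total_vdw: float
    total_total: float


def read_xvg(path: str | Path, pair: str | tuple | None = None,
             component: EnergyComponent | str = EnergyComponent.TOTAL) -> EnergyTrace:
    """Read a two-column GROMACS XVG file into an :class:`EnergyTrace`.

    ``#`` comment and ``@`` directive lines are skipped; the plot title from
    an ``@ title`` directive, when present, is kept.  When ``pair`` is not
    given it is parsed from the title or the file stem
    (``Ile149A-Gly49B_coul_sr.xvg`` style).
    """
    path = Path(path)
    times, values = [], []
    title = ""
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("@"):
                if s.startswith("@    title") or s.startswith("@ title"):
                    title = s.split('"')[1] if '"' in s else ""
                continue
            parts = s.split()
            if len(parts) < 2:
                raise XVGParseError(f"{path}:{lineno}: expected two columns, got {s!r}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise XVGParseError(f"{path}:{lineno}: non-numeric payload {s!r}") from exc
    if len(times) < 2:
        raise XVGParseError(f"{path}: fewer than 2 data rows")
    if pair is None:
        stem = path.stem
        for comp in EnergyComponent:
            suffix = f"_{comp.value}"
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                component = comp
                break
        pair = title.split()[0] if title and "-" in title.split()[0] else stem
    return EnergyTrace(pair=pair, component=component,
                       times=np.asarray(times), values=np.asarray(values), title=title)


def write_xy(times, values, path: str | Path, title: str = "",
             xlabel: str = "Time (ps)", ylabel: str = "Energy (kJ/mol)") -> None:
    """Write a plain two-column XVG file (no residue-pair semantics)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# generated by conflock\n")
        fh.write(f'@    title "{title}"\n')
        fh.write(f'@    xaxis  label "{xlabel}"\n')
        fh.write(f'@    yaxis  label "{ylabel}"\n')
        fh.write('@TYPE xy\n')
        for t, v in zip(times, values):
            fh.write(f"{t:.6g} {v:.9g}\n")


def read_xy(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a plain two-column XVG payload, skipping ``#``/``@`` lines."""
    times, values = [], []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            parts = s.split()
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except (IndexError, ValueError) as exc:
                raise XVGParseError(f"{path}:{lineno}: bad payload {s!r}") from exc
    return np.asarray(times), np.asarray(values)


def write_xvg(trace: EnergyTrace, path: str | Path,
              xlabel: str = "Time (ps)", ylabel: str = "Energy (kJ/mol)") -> None:
    write_xy(trace.times, trace.values, path,
             title=f"{trace.pair_label} {trace.component.value}",
             xlabel=xlabel, ylabel=ylabel)


def average_energy(trace: EnergyTrace, window: tuple[float, float] | None = None) -> float:
    """Arithmetic mean of the trace values within a time window (default all)."""
    if window is None:
        return float(np.mean(trace.values))
    lo, hi = window
    mask = (trace.times >= lo) & (trace.times <= hi)
    if not mask.any():
        raise ValueError(f"window {window} does not overlap trace support "
                         f"[{trace.times[0]}, {trace.times[-1]}]")
    return float(np.mean(trace.values[mask]))


def _nearest_join(coul: EnergyTrace, lj: EnergyTrace) -> tuple[np.ndarray, np.ndarray]:
    """Align lj onto coul's grid by nearest time; tolerance = dt/2."""
    tol = 0.5 * min(coul.dt, lj.dt)
    idx = np.searchsorted(lj.times, coul.times)
    idx = np.clip(idx, 0, lj.times.size - 1)
    left = np.clip(idx - 1, 0, lj.times.size - 1)
    use_left = np.abs(lj.times[left] - coul.times) < np.abs(lj.times[idx] - coul.times)
    idx = np.where(use_left, left, idx)
    ok = np.abs(lj.times[idx] - coul.times) <= tol
    return coul.values[ok], lj.values[idx][ok]


def summarize_pair(coul_trace: EnergyTrace, lj_trace: EnergyTrace, kind: str,
                   window: tuple[float, float] | None = None) -> PairEnergySummary:
    """Reduce a pair's two component traces to a table row.

    Electrostatic = mean(Coul-SR), vdW = mean(LJ-SR), total = their sum.
    Mismatched time grids are joined by nearest time within half the smaller
    sampling interval.
    """
    if coul_trace.pair_label != lj_trace.pair_label:
        raise ValueError(f"pair mismatch: {coul_trace.pair_label} vs {lj_trace.pair_label}")
    if window is not None:
        coul_trace = _clip(coul_trace, window)
        lj_trace = _clip(lj_trace, window)
    if coul_trace.times.shape == lj_trace.times.shape and np.allclose(
            coul_trace.times, lj_trace.times):
        elec = float(np.mean(coul_trace.values))
        vdw = float(np.mean(lj_trace.values))
    else:
        cv, lv = _nearest_join(coul_trace, lj_trace)
        if cv.size == 0:
            raise ValueError("time grids share no points within tolerance")
        elec, vdw = float(np.mean(cv)), float(np.mean(lv))
    return PairEnergySummary(pair=coul_trace.pair_label, kind=kind,
                             electrostatic=elec, vdw=vdw, total=elec + vdw)


def _clip(trace: EnergyTrace, window: tuple[float, float]) -> EnergyTrace:
    lo, hi = window
    mask = (trace.times >= lo) & (trace.times <= hi)
    if mask.sum() < 2:
        raise ValueError(f"window {window} leaves fewer than 2 samples")
    return replace(trace, times=trace.times[mask], values=trace.values[mask])


def aggregate_table(rows: Sequence[PairEnergySummary]) -> EnergyTableSummary:
    """Column sums over table rows (zero totals for an empty table)."""
    return EnergyTableSummary(
        rows=list(rows),
        total_electrostatic=float(sum(r.electrostatic for r in rows)),
        total_vdw=float(sum(r.vdw for r in rows)),
        total_total=float(sum(r.total for r in rows)),
    )


def dominant_component(summary: PairEnergySummary) -> tuple[str, bool]:
    """Which component dominates a pair, by magnitude.

    Returns ``(component, tied)`` where component is ``"electrostatic"`` or
    ``"vdw"``; exact magnitude ties resolve to vdw with the tie flag set.
    """
    e, v = abs(summary.electrostatic), abs(summary.vdw)
    if e > v:
        return ("electrostatic", False)
    return ("vdw", e == v)


def summaries_from_csv(path_or_buf) -> list[PairEnergySummary]:
    df = pd.read_csv(path_or_buf)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary CSV missing columns: {sorted(missing)}")
    return [
        PairEnergySummary(pair=r.pair, kind=r.kind,
                          electrostatic=float(r.electrostatic_kJ_mol),
                          vdw=float(r.vdw_kJ_mol), total=float(r.total_kJ_mol))
        for r in df.itertuples()
    ]


def summaries_to_csv(rows: Sequence[PairEnergySummary], path: str | Path) -> None:
    pd.DataFrame([r.as_dict() for r in rows], columns=CSV_COLUMNS).to_csv(path, index=False)


def _data_path(name: str):
    return resources.files("conflock.data").joinpath(name)


def load_reference_tables() -> tuple[list[PairEnergySummary], list[PairEnergySummary]]:
    """The packaged SOD interface summary tables.

    Returns ``(hbond_rows, hydrophobic_rows)``: the 4 hydrogen-bond residue
    pairs and the 25 hydrophobic residue pairs with their published average
    interaction energies (kJ/mol).
    """
    with resources.as_file(_data_path("table1.csv")) as p:
        t1 = summaries_from_csv(p)
    with resources.as_file(_data_path("table2.csv")) as p:
        t2 = summaries_from_csv(p)
    return t1, t2


def load_reference_groups() -> dict[str, int]:
    """Published conformational-lock group membership: pair label -> 1 or 2."""
    with resources.as_file(_data_path("table3_groups.csv")) as p:
        df = pd.read_csv(p)
    return dict(zip(df["pair"], df["group"].astype(int)))
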