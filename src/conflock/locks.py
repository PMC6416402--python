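"""Rupture-time detection and conformational-lock grouping.

A residue pair "ruptures" when its smoothed total interaction energy decays
from its bound-state baseline to a small fraction of it and stays there.  A
conformational lock is a set of pairs whose ruptures cluster in time: the
pairs of one lock break together as one step of dimer dissociation.  The
grouping is 1-D largest-gap splitting of the sorted rupture times, applied
recursively while the largest inter-event gap exceeds ``min_gap_ps``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .energy import EnergyTrace, PairEnergySummary, average_energy

__all__ = [
    "RuptureConfig",
    "RuptureEvent",
    "LockGroup",
    "LockReport",
    "UndefinedRuptureError",
    "detect_rupture",
    "group_locks",
    "lock_energy",
    "compare_tracesets",
    "total_trace",
]


class UndefinedRuptureError(ValueError):
    """The trace never shows a bound baseline above the noise floor."""


@dataclass
class RuptureConfig:
    """Detection parameters (ps / kJ-mol units).

    ``alpha`` is the decay fraction: rupture is called when the smoothed
    energy magnitude first drops below ``alpha * |baseline|`` and stays
    below it for ``sustain_ps``.
    """

    smooth_window_ps: float = 10.0
    baseline_window_ps: float = 50.0
    alpha: float = 0.1
    sustain_ps: float = 20.0
    min_baseline: float = 0.1    # kJ/mol; below this the pair never bound
    zero_floor: float = 0.5      # kJ/mol; |E| below this counts as zero

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class RuptureEvent:
    pair: str
    rupture_time: float | None
    baseline_energy: float
    zero_time: float | None = None


@dataclass
class LockGroup:
    group_id: int
    members: list[str]
    member_kinds: dict[str, str]
    n_hbond: int
    n_hydrophobic: int
    total_energy: float
    rupture_window: tuple[float, float]
    mean_rupture_time: float


@dataclass
class LockReport:
    groups: list[LockGroup]
    unassigned: list[str]
    parameters: dict

    def all_pairs(self) -> list[str]:
        return [m for g in self.groups for m in g.members] + list(self.unassigned)

    def to_json(self, path: str | Path | None = None, **meta) -> str:
        payload = {
            "groups": [
                {
                    "group_id": g.group_id,
                    "members": g.members,
                    "n_hbond": g.n_hbond,
                    "n_hydrophobic": g.n_hydrophobic,
                    "total_energy_kJ_mol": round(g.total_energy, 4),
                    "rupture_window_ps": [round(x, 2) for x in g.rupture_window],
                    "mean_rupture_time_ps": round(g.mean_rupture_time, 2),
                }
                for g in self.groups
            ],
            "unassigned": self.unassigned,
            "parameters": self.parameters,
            **meta,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def total_trace(coul: EnergyTrace, lj: EnergyTrace) -> EnergyTrace:
    """Per-time-point sum of the two component traces (shared grid required)."""
    if coul.times.shape != lj.times.shape or not np.allclose(coul.times, lj.times):
        raise ValueError("component traces must share one time grid")
    return EnergyTrace(pair=coul.pair, component="total",
                       times=coul.times, values=coul.values + lj.values)


def _moving_average(values: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return values
    kernel = np.ones(n) / n
    # centered; edges use a shrinking window via normalization
    smoothed = np.convolve(values, kernel, mode="same")
    norm = np.convolve(np.ones_like(values), kernel, mode="same")
    return smoothed / norm


def detect_rupture(trace: EnergyTrace, config: RuptureConfig | None = None) -> RuptureEvent:
    """Find the rupture time of one total-energy trace.

    Baseline = mean over the initial ``baseline_window_ps``; rupture = first
    time the centered-moving-average energy magnitude falls below
    ``alpha * |baseline|`` and remains below for ``sustain_ps``;
    ``rupture_time`` is None when the pair never ruptures.  ``zero_time`` is
    the first time after which the magnitude stays below ``zero_floor``.
    """
    cfg = config or RuptureConfig()
    t, v = trace.times, trace.values
    dt = trace.dt
    need = cfg.baseline_window_ps + cfg.sustain_ps
    if t[-1] - t[0] < need:
        raise ValueError(f"trace span {t[-1] - t[0]:.1f} ps shorter than "
                         f"baseline + sustain windows ({need:.1f} ps)")
    win = max(1, int(round(cfg.smooth_window_ps / dt)))
    smooth = _moving_average(v, win)
    baseline = float(np.mean(v[t <= t[0] + cfg.baseline_window_ps]))
    if abs(baseline) < cfg.min_baseline:
        raise UndefinedRuptureError(
            f"{trace.pair_label}: baseline {baseline:.3g} kJ/mol below noise "
            f"floor {cfg.min_baseline}; pair never bound")
    below = np.abs(smooth) < cfg.alpha * abs(baseline)
    sustain_n = max(1, int(round(cfg.sustain_ps / dt)))
    rupture_time = _first_sustained(t, below, sustain_n)
    zero_time = _first_sustained(t, np.abs(smooth) < cfg.zero_floor, sustain_n,
                                 to_end=True)
    return RuptureEvent(pair=trace.pair_label, rupture_time=rupture_time,
                        baseline_energy=baseline, zero_time=zero_time)


def _first_sustained(t: np.ndarray, mask: np.ndarray, n: int,
                     to_end: bool = False) -> float | None:
    if to_end:
        # last index after which mask holds everywhere
        if not mask[-1]:
            return None
        idx = np.where(~mask)[0]
        start = 0 if idx.size == 0 else idx[-1] + 1
        return float(t[start])
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= n:
            return float(t[i - n + 1])
    return None


def _largest_gap_split(times: np.ndarray, min_gap: float, max_groups: int) -> list[np.ndarray]:
    """Recursive largest-gap splitting of sorted times (earlier gap wins ties)."""
    order = np.argsort(times, kind="stable")
    groups = [order]
    while len(groups) < max_groups:
        best = None  # (gap, group_index, split_pos)
        for gi, g in enumerate(groups):
            if g.size < 2:
                continue
            gaps = np.diff(times[g])
            pos = int(np.argmax(gaps))  # argmax -> earliest on ties
            gap = float(gaps[pos])
            if gap > min_gap and (best is None or gap > best[0]):
                best = (gap, gi, pos)
        if best is None:
            break
        _, gi, pos = best
        g = groups.pop(gi)
        groups[gi:gi] = [g[: pos + 1], g[pos + 1:]]
    groups.sort(key=lambda g: float(np.mean(times[g])))
    return groups


def group_locks(events: Sequence[RuptureEvent],
                summaries: Sequence[PairEnergySummary],
                min_gap_ps: float = 50.0, max_groups: int = 4,
                config: RuptureConfig | None = None) -> LockReport:
    """Partition ruptured pairs into conformational-lock groups.

    Pairs without a detected rupture go to ``unassigned``.  Groups are
    numbered 1..G in order of mean rupture time; each group's total energy is
    the sum of its members' summary totals.
    """
    by_pair = {s.pair: s for s in summaries}
    missing = [e.pair for e in events if e.pair not in by_pair]
    if missing:
        raise KeyError(f"no energy summary for pairs: {missing}")
    defined = [e for e in events if e.rupture_time is not None]
    unassigned = [e.pair for e in events if e.rupture_time is None]
    params = {"min_gap_ps": min_gap_ps, "max_groups": max_groups,
              **({} if config is None else config.as_dict())}
    if not defined:
        return LockReport(groups=[], unassigned=unassigned, parameters=params)
    times = np.asarray([e.rupture_time for e in defined])
    parts = _largest_gap_split(times, min_gap_ps, max_groups)
    groups = []
    for gid, part in enumerate(parts, start=1):
        members = [defined[i].pair for i in part]
        kinds = {p: by_pair[p].kind for p in members}
        groups.append(LockGroup(
            group_id=gid,
            members=members,
            member_kinds=kinds,
            n_hbond=sum(1 for p in members if kinds[p] == "hydrogen_bond"),
            n_hydrophobic=sum(1 for p in members if kinds[p] == "hydrophobic"),
            total_energy=float(sum(by_pair[p].total for p in members)),
            rupture_window=(float(times[part].min()), float(times[part].max())),
            mean_rupture_time=float(times[part].mean()),
        ))
    return LockReport(groups=groups, unassigned=unassigned, parameters=params)


def lock_energy(members: Iterable[str], summaries: Sequence[PairEnergySummary]) -> float:
    """Sum of member pairs' total energies (kJ/mol); 0 for an empty group."""
    by_pair = {s.pair: s for s in summaries}
    total = 0.0
    for p in members:
        if p not in by_pair:
            raise KeyError(f"pair {p} missing from summaries")
        total += by_pair[p].total
    return total


def compare_tracesets(reference: Mapping[str, EnergyTrace],
                      variant: Mapping[str, EnergyTrace],
                      config: RuptureConfig | None = None) -> pd.DataFrame:
    """Per-pair rupture/baseline deltas between two total-trace sets.

    Operates on the pairs common to both sets; deltas are variant minus
    reference.  Useful for wild-type vs perturbed (e.g. mutant-like) runs.
    """
    common = sorted(set(reference) & set(variant))
    rows = []
    for p in common:
        ref_ev = detect_rupture(reference[p], config)
        var_ev = detect_rupture(variant[p], config)
        d_rupture = (None if ref_ev.rupture_time is None or var_ev.rupture_time is None
                     else var_ev.rupture_time - ref_ev.rupture_time)
        rows.append({
            "pair": p,
            "baseline_ref": ref_ev.baseline_energy,
            "baseline_var": var_ev.baseline_energy,
            "delta_baseline": var_ev.baseline_energy - ref_ev.baseline_energy,
            "rupture_ref": ref_ev.rupture_time,
            "rupture_var": var_ev.rupture_time,
            "delta_rupture": d_rupture,
        })
    return pd.DataFrame(rows, columns=[
        "pair", "baseline_ref", "baseline_var", "delta_baseline",
        "rupture_ref", "rupture_var", "delta_rupture"])
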