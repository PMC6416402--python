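"""Synthetic inputs for the whole pipeline: no MD engine required.

Two generator tiers:

* **Parametric** (:func:`generate_traceset`): per-pair total-energy traces
  built as depth x sigmoid decay centred on the pair's lock epoch, plus
  Ornstein-Uhlenbeck noise that decays with the bond.  Exact ground truth is
  recorded, which makes this the primary statistical test surface.
* **Mechanistic** (:func:`simulate_pull`): a 1-D overdamped Langevin model of
  a constant-velocity pull.  The pulled coordinate x (chain-chain separation
  increase, nm) feels the steering spring F = -k[x_pull(t) - x_pull(0) - vt]
  and a set of breakable bonds with potential
  U_i(x) = depth_i (1 - (x/b_i)^2) for 0 <= x < b_i (zero after the bond
  irreversibly breaks at extension b_i).  The effective bond stiffness is
  therefore 2|depth_i|/b_i^2 and the quasi-static rupture force of a single
  bond is 2|depth_i|/b_i, which gives a closed-form oracle.

Default pull parameters follow the production conditions of the analysed
system: spring constant k = 250 kJ mol^-1 nm^-2, velocity v = 0.01 nm/ps.
Default bond parameters come from the packaged interface tables: bond depth
= the pair's average total energy, break extension 0.13 nm for group-1 and
0.30 nm for group-2 pairs (the observed stretch at the two rupture epochs).

The module also builds a **synthetic** stand-in structure for the dimer
interface (:func:`synthetic_interface_structure`) that realizes the
published contact census geometrically, and a toy multi-frame dissociation
trajectory (:func:`synthetic_dissociation_trajectory`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .energy import (EnergyComponent, EnergyTrace, PairEnergySummary,
                     load_reference_groups, load_reference_tables, write_xvg)
from .poltorak import KineticCurve
from .structure import AtomRecord, StructureModel, element_mass

__all__ = [
    "PullParams",
    "BondSpec",
    "TraceSet",
    "PullResult",
    "OUParams",
    "StabilityError",
    "spring_force",
    "default_bond_specs",
    "generate_traceset",
    "simulate_pull",
    "generate_kinetic_curve",
    "synthetic_interface_structure",
    "synthetic_dissociation_trajectory",
    "COM_START_NM",
    "COM_END_NM",
]

KB = 0.0083144626  # kJ mol^-1 K^-1
COM_START_NM = 2.82
COM_END_NM = 6.83
# logistic scale so that `width` is the 10-90% transition width
_SIGMOID_WIDTH_FACTOR = 2.0 * math.log(9.0)


class StabilityError(RuntimeError):
    pass


@dataclass
class PullParams:
    """Constant-velocity pulling parameters (GROMACS units)."""

    k: float = 250.0       # spring constant, kJ mol^-1 nm^-2
    v: float = 0.01        # pull velocity, nm/ps
    x0: float = 0.0        # initial pulled-coordinate position, nm
    duration: float = 600.0  # ps
    dt: float = 0.1        # ps

    def __post_init__(self) -> None:
        if self.k <= 0 or self.v < 0 or self.dt <= 0 or self.duration < self.dt:
            raise ValueError("require k > 0, v >= 0, dt > 0, duration >= dt")


@dataclass
class BondSpec:
    """One breakable interface bond, parameterized from a summary-table row."""

    pair: str
    depth: float                      # kJ/mol, negative
    component_split: tuple[float, float]  # (coul fraction, lj fraction)
    group: int                        # 1 (breaks first) or 2
    break_extension: float            # nm
    stiffness: float | None = None    # kJ mol^-1 nm^-2; default 2|depth|/b^2
    kind: str = "hydrophobic"

    def __post_init__(self) -> None:
        if self.depth >= 0:
            raise ValueError(f"{self.pair}: bond depth must be negative")
        if abs(sum(self.component_split) - 1.0) > 1e-6:
            raise ValueError(f"{self.pair}: component fractions must sum to 1")
        if self.break_extension <= 0:
            raise ValueError(f"{self.pair}: break_extension must be positive")
        if self.stiffness is None:
            self.stiffness = 2.0 * abs(self.depth) / self.break_extension ** 2


@dataclass
class OUParams:
    """Ornstein-Uhlenbeck noise: correlation time (ps) and SD as a fraction
    of each pair's depth."""

    tau: float = 1.0
    sd_frac: float = 0.2


@dataclass
class TraceSet:
    """A bundle of per-pair component traces plus force and separation."""

    times: np.ndarray               # ps
    traces: list[EnergyTrace]       # 2 components x n pairs, shared grid
    force: np.ndarray               # steering force, kJ mol^-1 nm^-1
    com_separation: np.ndarray      # nm
    truth: dict

    def total_traces(self) -> dict[str, EnergyTrace]:
        by_pair: dict[str, dict[EnergyComponent, EnergyTrace]] = {}
        for tr in self.traces:
            by_pair.setdefault(tr.pair_label, {})[tr.component] = tr
        out = {}
        for label, comps in by_pair.items():
            total = comps[EnergyComponent.COUL_SR].values + comps[EnergyComponent.LJ_SR].values
            out[label] = EnergyTrace(pair=label, component="total",
                                     times=self.times, values=total)
        return out

    def component_traces(self, label: str) -> tuple[EnergyTrace, EnergyTrace]:
        comps = {tr.component: tr for tr in self.traces if tr.pair_label == label}
        return comps[EnergyComponent.COUL_SR], comps[EnergyComponent.LJ_SR]

    def write(self, outdir: str | Path) -> None:
        """Write XVG traces, pullf.xvg, com.xvg and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tr in self.traces:
            write_xvg(tr, outdir / f"{tr.pair_label}_{tr.component.value}.xvg")
        from .energy import write_xy
        write_xy(self.times, self.force, outdir / "pullf.xvg",
                 title="pull force", ylabel="Force (kJ/mol/nm)")
        write_xy(self.times, self.com_separation, outdir / "com.xvg",
                 title="COM separation", ylabel="Distance (nm)")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read_xvg_dir(cls, path: str | Path) -> "TraceSet":
        from .energy import read_xvg, read_xy
        path = Path(path)
        traces, force, com, times = [], None, None, None
        for f in sorted(path.glob("*.xvg")):
            if f.name == "pullf.xvg":
                force = read_xy(f)[1]
            elif f.name == "com.xvg":
                com = read_xy(f)[1]
            else:
                traces.append(read_xvg(f))
        if not traces:
            raise FileNotFoundError(f"no pair trace XVG files in {path}")
        times = traces[0].times
        truth_file = path / "truth.json"
        truth = json.loads(truth_file.read_text()) if truth_file.exists() else {}
        if force is None:
            force = np.zeros_like(times)
        if com is None:
            com = np.full_like(times, COM_START_NM)
        return cls(times=times, traces=traces, force=force,
                   com_separation=com, truth=truth)


@dataclass
class PullResult:
    traceset: TraceSet
    rupture_force: float            # kJ mol^-1 nm^-1
    break_times: dict[str, float]   # ps per pair (inf if never broke)


def spring_force(params: PullParams, x: float, t: float) -> float:
    """Steering-spring force F = -k [x_pull(t) - x_pull(0) - v t].

    Positive when the pulled coordinate lags behind the moving reference
    x0 + v t; zero exactly at the moving rest point.
    """
    return -params.k * (x - params.x0 - params.v * t)


def default_bond_specs(break_ext_group1: float = 0.13,
                       break_ext_group2: float = 0.30) -> list[BondSpec]:
    """Bond specs for all 29 interface pairs from the packaged tables.

    Depth = table total energy; coul/lj split from the table's component
    columns; lock group from the packaged group table; break extensions
    default to the observed pull stretch at each group's rupture epoch.
    """
    t1, t2 = load_reference_tables()
    groups = load_reference_groups()
    specs = []
    for row in t1 + t2:
        g = groups[row.pair]
        # fractions against elec+vdw, not the printed total, so they sum to 1
        # despite table rounding
        comp_sum = row.electrostatic + row.vdw
        specs.append(BondSpec(
            pair=row.pair, depth=row.total,
            component_split=(row.electrostatic / comp_sum, row.vdw / comp_sum),
            group=g,
            break_extension=break_ext_group1 if g == 1 else break_ext_group2,
            kind=row.kind))
    return specs


def _sigmoid_decay(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """1 -> 0 logistic decay; `width` is the 10-90% transition width."""
    scale = width / _SIGMOID_WIDTH_FACTOR
    return 1.0 / (1.0 + np.exp(np.clip((t - center) / scale, -500, 500)))


def _ou_noise(rng: np.random.Generator, n_series: int, n_t: int,
              dt: float, tau: float) -> np.ndarray:
    """Unit-variance OU noise, exact AR(1) discretization, shape (n_series, n_t)."""
    rho = math.exp(-dt / tau)
    innov_sd = math.sqrt(1.0 - rho * rho)
    x = np.empty((n_series, n_t))
    x[:, 0] = rng.standard_normal(n_series)
    eps = rng.standard_normal((n_series, n_t - 1)) * innov_sd
    for i in range(1, n_t):
        x[:, i] = x[:, i - 1] * rho + eps[:, i - 1]
    return x


def generate_traceset(bonds: Sequence[BondSpec] | None = None,
                      epochs: tuple[float, float] = (240.0, 400.0),
                      noise: OUParams | None = None,
                      seed: int = 0,
                      duration: float = 600.0,
                      dt: float = 0.1,
                      decay_width: float = 10.0,
                      epoch_jitter_sd: float = 5.0,
                      pull: PullParams | None = None) -> TraceSet:
    """Parametric SMD-like trace set with exact ground truth.

    Each pair's total energy is ``depth * sigmoid_decay(t; epoch_g + jitter,
    width)`` plus OU noise scaled by ``sd_frac * |depth|`` and multiplied by
    the same decay envelope (so every trace is zero after its rupture).  The
    chain-chain COM separation rises monotonically from 2.82 nm to 6.83 nm.
    Identical seeds give bit-identical output.
    """
    if bonds is None:
        bonds = default_bond_specs()
    noise = noise or OUParams()
    pull = pull or PullParams(duration=duration, dt=dt)
    if epochs[0] > epochs[1]:
        raise ValueError("epochs must be ordered")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    n_t = t.size

    centers = {}
    for b in bonds:
        epoch = epochs[b.group - 1]
        centers[b.pair] = epoch + rng.normal(0.0, epoch_jitter_sd)
    ou = (_ou_noise(rng, len(bonds), n_t, dt, noise.tau)
          if noise.sd_frac > 0 else np.zeros((len(bonds), n_t)))

    traces: list[EnergyTrace] = []
    truth_pairs = {}
    for i, b in enumerate(bonds):
        env = _sigmoid_decay(t, centers[b.pair], decay_width)
        total = b.depth * env + noise.sd_frac * abs(b.depth) * ou[i] * env
        fc, fl = b.component_split
        traces.append(EnergyTrace(pair=b.pair, component=EnergyComponent.COUL_SR,
                                  times=t, values=fc * total))
        traces.append(EnergyTrace(pair=b.pair, component=EnergyComponent.LJ_SR,
                                  times=t, values=fl * total))
        truth_pairs[b.pair] = {
            "group": b.group, "depth": b.depth, "kind": b.kind,
            "rupture_center_ps": centers[b.pair],
            "mean_coul": fc * b.depth, "mean_lj": fl * b.depth,
        }

    # COM separation: smooth monotone rise hitting the endpoints exactly.
    com = COM_START_NM + (COM_END_NM - COM_START_NM) * 0.5 * (1 - np.cos(np.pi * t / t[-1]))
    # Phenomenological steering force: each intact bond resists with its
    # quasi-static rupture force scaled by how far it has been stretched.
    force = np.zeros(n_t)
    for i, b in enumerate(bonds):
        env = _sigmoid_decay(t, centers[b.pair], decay_width)
        ramp = np.clip(pull.v * t / b.break_extension, 0.0, 1.0)
        force += (b.stiffness * b.break_extension) * env * ramp
    force += 0.02 * force.max() * _ou_noise(rng, 1, n_t, dt, 5.0)[0]

    truth = {
        "seed": int(seed), "epochs_ps": list(epochs),
        "noise": asdict(noise), "decay_width_ps": decay_width,
        "epoch_jitter_sd_ps": epoch_jitter_sd,
        "pull": asdict(pull), "pairs": truth_pairs,
        "com_start_nm": COM_START_NM, "com_end_nm": COM_END_NM,
    }
    return TraceSet(times=t, traces=traces, force=force,
                    com_separation=com, truth=truth)


def simulate_pull(bonds: Sequence[BondSpec], params: PullParams | None = None,
                  friction: float = 2000.0, temperature: float = 300.0,
                  seed: int = 0, sample_every: int = 1,
                  force_smooth_ps: float = 5.0) -> PullResult:
    """Mechanistic 1-D constant-velocity pull with breakable bonds.

    Overdamped Langevin integration (Euler-Maruyama) of the pulled
    coordinate under the steering spring plus the intact bonds' harmonic
    forces; each bond breaks irreversibly when the extension exceeds its
    ``break_extension``.  Per-pair energies are emitted every
    ``sample_every`` steps; the rupture force is the maximum smoothed
    steering force recorded before the final bond break (over the whole
    trace if nothing breaks).

    ``friction`` is the drag coefficient (kJ mol^-1 ps nm^-2) and sets both
    the relaxation time and, with temperature, the thermal noise amplitude.
    """
    params = params or PullParams()
    if friction <= 0 or temperature < 0:
        raise ValueError("friction must be positive and temperature >= 0")
    kappa_sum = sum(b.stiffness for b in bonds)
    if params.dt * (params.k + kappa_sum) / friction > 0.5:
        raise StabilityError(
            f"dt={params.dt} ps too large for stiffness k+sum(kappa)="
            f"{params.k + kappa_sum:.0f} at friction {friction}: "
            "the per-step force change exceeds the stable range; reduce dt")
    rng = np.random.default_rng(seed)
    n_steps = int(round(params.duration / params.dt))
    depths = np.array([b.depth for b in bonds]) if bonds else np.empty(0)
    kappas = np.array([b.stiffness for b in bonds]) if bonds else np.empty(0)
    bexts = np.array([b.break_extension for b in bonds]) if bonds else np.empty(0)
    intact = np.ones(len(bonds), dtype=bool)
    break_times = {b.pair: math.inf for b in bonds}

    noise_amp = math.sqrt(2.0 * KB * temperature * params.dt / friction)
    x = params.x0
    n_samples = n_steps // sample_every + 1
    t_out = np.empty(n_samples)
    x_out = np.empty(n_samples)
    f_out = np.empty(n_samples)
    e_out = np.empty((len(bonds), n_samples))
    last_break_step = -1

    def record(si: int, t: float) -> None:
        t_out[si] = t
        x_out[si] = x
        f_out[si] = spring_force(params, x, t)
        if len(bonds):
            xe = np.clip(x - params.x0, 0.0, bexts)
            e = depths * (1.0 - (xe / bexts) ** 2)
            e[~intact] = 0.0
            e_out[:, si] = e

    record(0, 0.0)
    si = 1
    xi = rng.standard_normal(n_steps)
    for step in range(1, n_steps + 1):
        t = step * params.dt
        f_spring = spring_force(params, x, t - params.dt)
        ext = x - params.x0
        f_bonds = float(np.sum(np.where(intact, -kappas * np.clip(ext, 0.0, None), 0.0))) \
            if len(bonds) else 0.0
        x += params.dt / friction * (f_spring + f_bonds) + noise_amp * xi[step - 1]
        if len(bonds):
            newly = intact & (x - params.x0 >= bexts)
            if newly.any():
                for i in np.flatnonzero(newly):
                    break_times[bonds[i].pair] = t
                intact &= ~newly
                last_break_step = step
        if step % sample_every == 0 and si < n_samples:
            record(si, t)
            si += 1
    t_out, x_out, f_out = t_out[:si], x_out[:si], f_out[:si]
    e_out = e_out[:, :si]

    win = max(1, int(round(force_smooth_ps / (params.dt * sample_every))))
    kernel = np.ones(win) / win
    f_smooth = np.convolve(f_out, kernel, mode="same") / np.convolve(
        np.ones_like(f_out), kernel, mode="same")
    if last_break_step > 0:
        upto = np.searchsorted(t_out, last_break_step * params.dt, side="right")
        rupture_force = float(f_smooth[:upto].max())
    else:
        rupture_force = float(np.abs(f_smooth).max())

    traces = []
    truth_pairs = {}
    for i, b in enumerate(bonds):
        fc, fl = b.component_split
        traces.append(EnergyTrace(pair=b.pair, component=EnergyComponent.COUL_SR,
                                  times=t_out, values=fc * e_out[i]))
        traces.append(EnergyTrace(pair=b.pair, component=EnergyComponent.LJ_SR,
                                  times=t_out, values=fl * e_out[i]))
        truth_pairs[b.pair] = {"group": b.group, "depth": b.depth,
                               "break_time_ps": break_times[b.pair],
                               "quasi_static_rupture_force": b.stiffness * b.break_extension}
    truth = {"seed": int(seed), "pull": asdict(params), "friction": friction,
             "temperature_K": temperature, "pairs": truth_pairs,
             "rupture_force": rupture_force}
    ts = TraceSet(times=t_out, traces=traces if bonds else [],
                  force=f_out, com_separation=COM_START_NM + np.clip(x_out - params.x0, 0, None),
                  truth=truth)
    return PullResult(traceset=ts, rupture_force=rupture_force, break_times=break_times)


def generate_kinetic_curve(n_steps: int = 2,
                           step_fractions: Sequence[float] | None = None,
                           rate: float = 0.5,
                           noise_sd: float = 0.0,
                           seed: int = 0,
                           duration: float = 100.0,
                           n_points: int = 241) -> tuple[KineticCurve, dict]:
    """Staircase residual-activity decay with exponential transitions.

    ``step_fractions`` (summing to 1) are the activity losses of successive
    steps; a single step yields the pure single-exponential
    ``A(t) = exp(-rate t)``.  Returns the curve and a ground-truth dict with
    the construction parameters and the implied kinetic ratio
    ``R = 1 / step_fractions[0]``.
    """
    if step_fractions is None:
        step_fractions = [1.0 / n_steps] * n_steps
    step_fractions = list(map(float, step_fractions))
    if len(step_fractions) != n_steps:
        raise ValueError("need one fraction per step")
    if abs(sum(step_fractions) - 1.0) > 1e-9:
        raise ValueError("step fractions must sum to 1")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    if n_steps == 1:
        a = np.exp(-rate * t)
        step_times = [0.0]
    else:
        step_times = [duration * (2 * i - 1) / (2 * n_steps) for i in range(1, n_steps + 1)]
        a = np.ones_like(t)
        for f, t_i in zip(step_fractions, step_times):
            trans = np.where(t > t_i, 1.0 - np.exp(-rate * (t - t_i)), 0.0)
            a = a - f * trans
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=a.size)
    a = np.clip(a, -0.049, 1.049)
    truth = {"R": 1.0 / step_fractions[0], "n_steps": n_steps,
             "step_fractions": step_fractions, "step_times": step_times,
             "rate": rate, "noise_sd": noise_sd, "seed": int(seed)}
    return KineticCurve(times=t, residual_activity=a), truth


# ---------------------------------------------------------------------------
# Synthetic structures
# ---------------------------------------------------------------------------

_HB_DIST = 2.9     # A, donor-acceptor
_PHOB_DIST = 3.5   # A, apolar atom pair
_SALT_DIST = 7.0   # A, beyond the 6 A (0.6 nm) salt-bridge cutoff
_SITE_SPACING = 12.0  # A between contact sites
_SUB_OFFSETS = (-6.0, 0.0, 6.0)  # A, the 3 atom contacts of a hydrophobic pair


def synthetic_interface_structure() -> StructureModel:
    """SYNTHETIC stand-in structure for the Cu,Zn-SOD dimer interface.

    This is *not* the crystal structure: it is a constructed two-chain atom
    arrangement whose inter-chain geometry realizes the published interface
    census — the 4 hydrogen-bond residue pairs of the reference table, the
    25 hydrophobic residue pairs as 3 apolar atom contacts each (75 atom
    contacts), an inter-chain Asp11/Lys9 charged pair placed beyond the
    0.6 nm salt-bridge cutoff, and flagged Cu/Zn HETATM sites.  Each contact
    occupies its own well-separated site so detection recovers the census
    exactly; atoms carry real element masses but residues are reduced to
    their interacting atoms (hydrophobic atoms are named C01, C02, ... since
    one residue may take part in more contacts than it has apolar atoms).
    """
    t1, t2 = load_reference_tables()
    atoms_by_res: dict[tuple[str, int, str], list[tuple[str, str, np.ndarray]]] = {}
    c_counter: dict[tuple, int] = {}

    def add(label: str, name: str, element: str, xyz) -> None:
        from .structure import ResidueId
        rid = ResidueId.from_label(label)
        key = (rid.chain_id, rid.residue_seq, rid.residue_name)
        atoms_by_res.setdefault(key, []).append((name, element, np.asarray(xyz, float)))

    def next_c(label: str) -> str:
        c_counter[label] = c_counter.get(label, 0) + 1
        return f"C{c_counter[label]:02d}"

    site = 0
    # hydrogen bonds: alternate donor side so no residue reuses N or O
    for idx, row in enumerate(t1):
        a_lab, b_lab = row.pair.split("-")
        cx = site * _SITE_SPACING
        site += 1
        a_name, b_name = ("N", "O") if idx % 2 == 0 else ("O", "N")
        add(a_lab, a_name, a_name[0], (cx - _HB_DIST / 2, 0.0, 0.0))
        add(b_lab, b_name, b_name[0], (cx + _HB_DIST / 2, 0.0, 0.0))
    # hydrophobic pairs: 3 separated atom contacts each
    for row in t2:
        a_lab, b_lab = row.pair.split("-")
        cx = site * _SITE_SPACING
        site += 1
        for dy in _SUB_OFFSETS:
            add(a_lab, next_c(a_lab), "C", (cx - _PHOB_DIST / 2, dy, 0.0))
            add(b_lab, next_c(b_lab), "C", (cx + _PHOB_DIST / 2, dy, 0.0))
    # the one inter-chain charged pair, placed beyond the salt-bridge cutoff
    for a_lab, b_lab in (("Asp11A", "Lys9B"), ("Asp11B", "Lys9A")):
        cx = site * _SITE_SPACING
        site += 1
        add(a_lab, "OD1", "O", (cx - _SALT_DIST / 2, -0.6, 0.0))
        add(a_lab, "OD2", "O", (cx - _SALT_DIST / 2, 0.6, 0.0))
        add(a_lab, "CG", "C", (cx - _SALT_DIST / 2 - 1.4, 0.0, 0.0))
        add(b_lab, "NZ", "N", (cx + _SALT_DIST / 2, 0.0, 0.0))

    records: list[AtomRecord] = []
    serial = 1
    for chain in ("A", "B"):
        keys = sorted(k for k in atoms_by_res if k[0] == chain)
        for key in keys:
            for name, element, xyz in atoms_by_res[key]:
                records.append(AtomRecord(
                    serial=serial, name=name, element=element,
                    residue_name=key[2], chain_id=chain, residue_seq=key[1],
                    coords=xyz, mass=element_mass(element)))
                serial += 1
        # flagged metal cofactor sites, excluded from interface analysis
        y_off = -40.0 if chain == "A" else 40.0
        for met, seq in (("CU", 900), ("ZN", 901)):
            records.append(AtomRecord(
                serial=serial, name=met, element=met, residue_name=met,
                chain_id=chain, residue_seq=seq,
                coords=np.array([0.0, y_off, 20.0]), mass=element_mass(met),
                is_hetatm=True))
            serial += 1
    return StructureModel(records, pdb_id="SYN1")


def synthetic_dissociation_trajectory(n_frames: int = 21,
                                      com_start: float = COM_START_NM,
                                      com_end: float = COM_END_NM) -> StructureModel:
    """SYNTHETIC toy dissociation trajectory (multi-frame structure).

    Chain B is a rigid copy of a small chain A template translated along x so
    that the chain-chain COM distance rises linearly from ``com_start`` to
    ``com_end`` nm across frames.
    """
    template = [
        ("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.4, 0.3, 0.2)),
        ("C", "C", (2.6, -0.4, -0.3)), ("O", "O", (2.7, -1.6, -0.4)),
        ("CB", "C", (1.5, 1.6, 1.0)),
    ]
    atoms: list[AtomRecord] = []
    serial = 1
    for chain in ("A", "B"):
        for name, el, xyz in template:
            atoms.append(AtomRecord(serial=serial, name=name, element=el,
                                    residue_name="ALA", chain_id=chain, residue_seq=1,
                                    coords=np.asarray(xyz, float), mass=element_mass(el)))
            serial += 1
    n_at = len(template)
    base = np.asarray([a.coords for a in atoms])
    frames = []
    for f in range(n_frames):
        d_nm = com_start + (com_end - com_start) * (f / (n_frames - 1) if n_frames > 1 else 0.0)
        frame = base.copy()
        frame[n_at:, 0] += d_nm * 10.0  # nm -> A translation of chain B
        frames.append(frame)
    return StructureModel(atoms, np.stack(frames), pdb_id="SYNT")
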