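# Methods

This note records the models implemented in `conflock`, the defaults that
matter, and the design decisions taken where the underlying procedure was
genuinely open.

## The system and the question

Cu,Zn-superoxide dismutase is a homodimer whose interface is held by a
handful of backbone hydrogen bonds (Ile149–Gly49 and Ile149–Gly112 across
both chain orders) and a larger shell of hydrophobic residue-pair contacts
clustered around Gly49, Gly112 and Ile149.  When the B chain is pulled off
the A chain at constant velocity with a harmonic spring, the per-pair
short-range interaction energies do not decay independently: they collapse
in two waves, an early group near 240 ps and a late group near 400 ps of
the pull, with everything at zero by roughly 520 ps.  Each wave is a
*conformational lock*: a set of contacts broken together as one step of
dissociation.  The package's job is to make that analysis reproducible —
classify the contacts, aggregate the energies, date the ruptures, group the
pairs, and connect the lock count to solution kinetics.

## Reference tables

`conflock/data/table1.csv` (4 hydrogen-bond rows) and `table2.csv`
(25 hydrophobic rows) hold the per-pair average electrostatic (Coul-SR),
van-der-Waals (LJ-SR) and total energies in kJ/mol for the SOD interface;
`table3_groups.csv` holds the two-lock membership (8 + 21 pairs).  Row
identity `elec + vdw = total` holds within 0.015 kJ/mol (printed rounding).
Column sums give −49.57 / −8.12 / −57.69 kJ/mol for the hydrogen-bond table
and a total of −87.65 kJ/mol for the hydrophobic table; the two lock groups
sum to −30.10 and −115.23 kJ/mol.  One internal inconsistency of the source
tables is preserved rather than edited: the hydrophobic table's printed vdW
column total (−74.10) differs from the sum of its printed entries (−74.13)
by 0.03 kJ/mol, so the vdW column is only asserted at the
`n_rows × 0.005 kJ/mol` rounding tolerance.

## Structure model and geometry

Coordinates are stored in Å (PDB native); every distance the API returns is
converted to nm at the boundary.  Multi-model PDB files are the only
trajectory format — each MODEL block is one frame with identical atom
ordering.  Alternate locations keep the highest-occupancy conformer (first
on ties).  Element masses come from a built-in standard-atomic-weight
table; unknown elements fall back to carbon with a warning.  RMSD uses
Kabsch superposition via `scipy.spatial.transform.Rotation.align_vectors`;
a degenerate selection (< 3 atoms or collinear) falls back to unfitted RMSD
with a warning.  The default RMSD selection is Cα, configurable through the
atom predicate since the exact backbone-carbon selection of the source
analysis is not fixed.

## Contact classification

Criteria follow published LigPlot/HBPLUS conventions and are fully
configurable:

* hydrogen bond — donor–acceptor N/O distance ≤ 3.35 Å; when explicit
  hydrogens are present the additional H···A ≤ 2.70 Å and D–H···A ≥ 90°
  criteria apply.  Crystal structures without hydrogens use distance-only
  detection with donor/acceptor typing from a built-in per-residue table
  (backbone N donates, backbone O accepts, plus the usual side-chain sets).
* hydrophobic contact — apolar atom (C/S, excluding carbons in polar
  context such as the backbone carbonyl and side-chain carboxyl/amide/
  guanidinium carbons) to apolar atom across chains within 3.90 Å.  Counts
  are reported both per atom pair and collapsed to unordered residue pairs,
  since "hydrophobic bond" counts in the literature are ambiguous between
  the two.
* salt bridge — anionic group centroid (Asp/Glu) to cationic group
  centroid (Lys/Arg/His) within 0.6 nm; that cutoff value is exactly the
  criterion by which the SOD inter-chain Asp11–Lys9 pair is excluded.

The census is a pure function of structure plus criteria, invariant under
rigid transforms and chain-argument order, and is checked in the tests
against a brute-force all-pairs distance scan.

### The synthetic stand-in structure

The real crystal structure cannot be redistributed with the package, so
`synthetic_interface_structure()` builds a clearly-labelled synthetic
two-chain arrangement that realizes the published census geometrically:
each of the 4 hydrogen bonds, 25 hydrophobic residue pairs (3 atom contacts
each → 75) and the beyond-cutoff Asp11/Lys9 pair occupies its own
well-separated site, and Cu/Zn sites are present as flagged HETATM records.
Running the census on it is therefore a *construction + recovery* exercise:
it validates the detector logic and the counting conventions, not the
crystallographic geometry.  Residues are reduced to their interacting atoms
(hydrophobic atoms are named `C01`, `C02`, … because a residue may take
part in more contacts than it has apolar atoms).

## Energy traces and summaries

Traces are two-column GROMACS XVG (time ps, energy kJ/mol), one file per
pair per component, `#`/`@` lines skipped.  A pair summary is
electrostatic = mean(Coul-SR), vdW = mean(LJ-SR), total = their sum;
mismatched grids are joined by nearest time within half the smaller
sampling interval.  The averaging window defaults to the full trace — the
source tables do not state whether their averages are full-window or
bound-phase, so a `window` argument supports both readings; the row-sum
identities hold either way.  Replicate sets can be summarized per pair as
mean ± SD; the packaged tables are single-replicate.

## Rupture detection and lock grouping

Total energy (Coul + LJ per time point) is smoothed with a 10 ps centered
moving average.  The baseline is the mean over the first 50 ps; a pair with
|baseline| < 0.1 kJ/mol never bound (undefined-rupture error).  Rupture is
the first time the smoothed magnitude falls below α·|baseline| (α = 0.1)
and stays below for 20 ps; the zero time is the first time after rupture
beyond which the magnitude stays below the noise floor.

Grouping formalizes what is usually done by eye on the energy curves:
sort the detected rupture times and split at the largest inter-event gap
whenever it exceeds `min_gap_ps` (default 50 ps), recursively up to
`max_groups` (default 4), earliest split winning ties.  This is
deterministic, order-free and shift-invariant, and reproduces a 240/400 ps
two-lock split.  A documented quirk of the source analysis is preserved:
the narrative text dates one hydrogen bond (Ile149B–Gly112A) near 270 ps
but the published membership table places it in the late group; the
packaged group table follows the membership table.

## Poltorak lock counting

`n = (0.13 + δ)/(0.13 − 0.05 δ)` on `0 ≤ δ < 2.6` (pole at 2.6), `δ = R − 1`.
The operational definition of `R` is not recoverable from the modern
sources (it descends from earlier kinetic work), so the package adopts and
documents a convention: **R = total activity loss / first-resolved-step
loss** from a plateau decomposition of the smoothed curve.  Plateaus are
regions where the local slope stays below 10% of the maximum decay slope
for at least 5% of the time span; levels are read at the flattest point of
each plateau; steps smaller than 5% of the dynamic range are discarded.
Under this convention a single-exponential decay has no intermediate
plateau and gives exactly R = 1 → δ = 0 → n = 1, the simple two-state
dissociation limit — the boundary behaviour that any sensible reading of
the formula must satisfy.  (A change-point fit with a BIC-selected penalty
was considered and rejected: it happily segments a smooth exponential into
several pieces and so fails that limit.)  Uncertainty comes from residual
resampling (199 bootstrap replicates by default), propagated through the
chain to a CI on `n`; `n` is reported both as the real-valued formula
output and as an integer ceiling.

## Synthetic generators

The generators define the study conditions; their defaults are fixed, not
tuning knobs.

**Parametric trace sets** (`generate_traceset`): each pair's total energy
is `depth × logistic decay` centred on its group epoch (240 or 400 ps,
per-pair jitter SD 5 ps, 10–90% transition width 10 ps) plus
Ornstein–Uhlenbeck noise (correlation time 1 ps, SD 20% of depth)
multiplied by the same envelope, so traces are zero after rupture and the
whole set is silent by ~520 ps.  Depths and Coul/LJ splits come from the
packaged tables; the component split is normalized against elec + vdw so
the two components sum exactly to the total.  Time grid 0–600 ps at 0.1 ps.
The chain–chain COM separation rises monotonically 2.82 → 6.83 nm.  The
steering-force channel is a phenomenological shape (each intact bond
contributes its quasi-static rupture force scaled by stretch) intended for
format plumbing, not quantitative use.  Output is bit-identical under a
fixed seed, and the emitted `truth.json` records every draw.

**Mechanistic pull simulator** (`simulate_pull`): one overdamped Langevin
degree of freedom `x` (pull-coordinate displacement, nm) under the
steering spring `F = −k[x − x0 − vt]` (defaults k = 250 kJ mol⁻¹ nm⁻²,
v = 0.01 nm/ps) and breakable bonds with potential
`U_i(x) = depth_i (1 − (x/b_i)²)` for `0 ≤ x < b_i`, zero after the
irreversible break at extension `b_i`.  The implied stiffness is
`κ_i = 2|depth_i|/b_i²` and the quasi-static rupture force `2|depth_i|/b_i`
is the closed-form oracle used in the tests.  Default break extensions are
0.13 nm for group-1 and 0.30 nm for group-2 bonds — the observed pull
stretch at the two rupture epochs — so group 1 breaks first.  Friction
defaults to 2000 kJ mol⁻¹ ps nm⁻² at T = 300 K; with these values the
drag term `γvk/(k+κ)` plus thermally activated early rupture at low
velocity make the mean rupture force increase with pull velocity, and the
bound-phase force fluctuation SD `k·sqrt(k_B T/(k+κ))` grows with the
spring constant — the two qualitative behaviours expected of constant-
velocity force spectroscopy.  Euler–Maruyama integration with a hard
stability guard (`dt·(k+Σκ)/γ ≤ 0.5` or a StabilityError advising a
smaller dt).  The model is 1-D, overdamped, solvent-free and has no
rotational degrees of freedom: it reproduces rupture phenomenology, not
molecular detail.  Reported rupture force is the maximum 5 ps-smoothed
steering force before the final break.

**Kinetic curves** (`generate_kinetic_curve`): staircase decay with
exponential transitions at evenly spaced times; one step degenerates to the
pure exponential `exp(−rate·t)`.  Ground truth `R = 1/f₁` is attached.

### What passing tests do and do not show

The parametric generator emulates the *statistical* structure of decaying
pair energies (two epochs, OU noise, exact means), so lock-recovery results
demonstrate that the detector and grouper work at realistic noise — they do
not validate force-field energetics.  The census on the synthetic structure
validates contact-classification logic, not crystallographic reality.  The
Langevin model is tested for monotone trends only; observables read off
published figures (rupture-force magnitudes, RMSD plateaus, exact 270/520
ps timings) depend on full MD trajectories and are out of reach at a desk.

## Problem sizes and numerical choices

Defaults were chosen so the whole suite and the reproduction script run
comfortably on one CPU: 29-pair trace sets at 6001 time points; 50 seeded
tracesets for recovery statistics; 20 seeds per point on the
velocity/spring-constant grids with a 2-bond representative set (one bond
per lock group) and dt = 0.05 ps; 100 noisy replicates × 99 bootstrap
resamples for the Poltorak coverage check.  Ties: equal largest gaps split
at the earliest position; equal-magnitude dominant components resolve to
vdW with a tie flag; altloc ties keep the first conformer.

## Known limitations

* The hydrogen-bond detector without explicit hydrogens is purely
  distance-typed; sulfur donors/acceptors and water bridges are ignored.
* π-stacking and cation-π interactions are not classified.
* Lock grouping assumes rupture times are cluster-separable in 1-D; locks
  overlapping in time would need the trace-correlation structure instead.
* The Poltorak `R` convention is a documented choice; comparisons with
  historical `n` values estimated under other conventions should be made
  with care.
* `estimate_R` needs resolvable plateaus: steps faster than the sampling
  interval or smaller than 5% of the dynamic range merge into their
  neighbours.
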