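# conflock

Conformational-lock analysis of homodimeric enzyme interfaces from
steered-pulling simulations.

Oligomeric enzymes such as Cu,Zn-superoxide dismutase (SOD) owe much of
their stability and catalytic efficiency to the subunit interface.  The
*conformational lock* picture describes that interface as a small number of
interaction groups that must each be broken as one step during thermal
dissociation.  Two observables speak to the same question:

* **structure + pulling energetics** — which inter-chain residue pairs
  interact, how strong each contact is (short-range Coulombic and
  Lennard-Jones energies from an MD energy decomposition), and *when* each
  pair's interaction energy collapses as the dimer is pulled apart at
  constant velocity under a harmonic spring,
  `F = -k [x_pull(t) - x_pull(0) - v t]`;
* **residual-activity kinetics** — the shape of the activity-versus-time
  decay during thermal dissociation, summarized by a ratio `R`, from which
  the minimal number of distinct active dimer forms follows from the
  empirical Poltorak relations
  `n = (0.13 + δ) / (0.13 - 0.05 δ)` with `δ = R - 1` (valid for
  `0 ≤ δ < 2.6`).

`conflock` implements the full desk-side pipeline around these ideas:

| module | what it does |
| --- | --- |
| `conflock.structure` | minimal PDB model (multi-model files as toy trajectories), centre-of-mass distances, Kabsch-fitted RMSD |
| `conflock.contacts` | DIMPLOT-style interface census: hydrogen bonds, hydrophobic contacts, salt bridges, all cutoffs configurable |
| `conflock.energy` | GROMACS XVG trace ingestion, per-pair electrostatic/vdW/total averages, table aggregation; the reference SOD interface tables ship as packaged CSVs |
| `conflock.locks` | rupture-time detection on total-energy traces and largest-gap grouping of pairs into conformational locks |
| `conflock.poltorak` | `R → δ → n` lock counting from residual-activity curves, with bootstrap uncertainty |
| `conflock.synthetic` | everything needed without an MD engine: parametric trace sets with exact ground truth, a 1-D Langevin constant-velocity pull simulator with breakable bonds, kinetic-curve generation, and a synthetic stand-in interface structure |
| `conflock.pipeline` / `conflock.cli` | one-command orchestration (`conflock run --config pipeline.yaml`) with reproducible, hash-stamped outputs |

## Worked example

```python
import conflock as cf
from conflock.locks import detect_rupture, group_locks

# interface census on the packaged synthetic stand-in structure
s = cf.synthetic_interface_structure()
print(cf.interface_census(s, "A", "B").summary())

# generate a steered-pull trace set and recover the lock groups
ts = cf.generate_traceset(seed=1)
t1, t2 = cf.load_reference_tables()
events = [detect_rupture(tr) for tr in ts.total_traces().values()]
report = group_locks(events, t1 + t2)
for g in report.groups:
    print(f"group {g.group_id}: {len(g.members)} pairs ({g.n_hbond} H-bond, "
          f"{g.n_hydrophobic} hydrophobic), total {g.total_energy:.2f} kJ/mol, "
          f"mean rupture {g.mean_rupture_time:.1f} ps")

# lock counting from a two-step residual-activity curve
curve, truth = cf.generate_kinetic_curve(n_steps=2, seed=1)
est = cf.lock_count(curve)
print(f"R = {est.R:.3f} +/- {est.R_se:.3f}, delta = {est.delta:.3f}, "
      f"n = {est.n:.2f} (ceil {est.n_rounded})")
```

prints

```
{'n_hbond_pairs': 4, 'n_hydrophobic_atom_contacts': 75, 'n_hydrophobic_residue_pairs': 25, 'n_salt_bridges': 0}
group 1: 8 pairs (1 H-bond, 7 hydrophobic), total -30.10 kJ/mol, mean rupture 246.7 ps
group 2: 21 pairs (3 H-bond, 18 hydrophobic), total -115.24 kJ/mol, mean rupture 405.9 ps
R = 2.000 +/- 0.025, delta = 1.000, n = 14.12 (ceil 15)
```

The census finds the 4 inter-chain hydrogen-bond residue pairs and the 25
hydrophobic residue pairs (75 atom contacts) of the SOD A/B interface, with
the lone Asp11–Lys9 charged pair correctly excluded (beyond the 0.6 nm
salt-bridge cutoff).  The lock detector recovers the two conformational
locks — one rupturing near 240 ps with a total bound-state energy of
−30.10 kJ/mol, the other near 400 ps at −115.23 kJ/mol — and the Poltorak
chain turns a two-equal-step activity decay into `R = 2`, i.e. about 14
distinguishable active dimer forms as a lower bound.

The same analysis runs from the shell:

```bash
conflock synth traceset --seed 1 -o data/
conflock locks data/ -o report/
conflock poltorak curve.csv
conflock run --config pipeline.yaml
```

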