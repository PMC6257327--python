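# dimerpbsa

Time-resolved end-point binding free-energy decomposition for two-chain
peptide dimer trajectories.

`dimerpbsa` implements a single-trajectory MM-PBSA/GBSA style analysis for
a peptide dimer: per-frame molecular-mechanics and implicit-solvent
energies for the complex and both monomers, the binding-energy
decomposition `dE_bind = dE_MM + dE_sol`, a Schlitter configurational
entropy correction, stage segmentation of the binding time series,
hydrogen-bond and contact-map analysis, RMSD dissimilarity matrices, a
dimer-conformation classifier, and replica selection across a temperature
ladder. A deterministic synthetic-system generator plants known signals
(stage boundaries, a best replica, hydrogen-bond occupancies) so that
every analysis component can be validated by recovery experiments.

See [docs/methods.md](docs/methods.md) for the physical model, numerical
choices and the scope of the synthetic generator.

## The decomposition

For each frame, the effective free energy of complex `C` and monomers
`A`, `B` is `G = E_MM + G_sol`, with `E_MM = E_int + E_ele + E_vdw` and
`G_sol = G_polar + G_nonpolar` (finite-difference Poisson or generalized
Born, plus a SASA-proportional nonpolar term). In the single-trajectory
protocol the monomer coordinates come from the complex trajectory, so
`dE_int ≡ 0` exactly and

```
dE_bind = G_C − G_A − G_B = dE_MM + dE_sol
```

holds per frame to 1e-8 kcal/mol by construction. For example, species
means of −904.7, −445.8 and −443.0 kcal/mol give a binding energy of
−15.9 kcal/mol, equivalently recovered from the MM/solvation split
−277.8 + 261.9 = −15.9; entropy terms −1.716, −0.842, −0.844 kcal/mol
give a correction −TΔS = −0.03 kcal/mol:

```python
>>> from dimerpbsa.binding import combine_free_energies, combine_mm_solvation, entropy_correction
>>> round(combine_free_energies(-904.7, -445.8, -443.0), 6)
-15.9
>>> round(combine_mm_solvation(-277.8, 261.9), 6)
-15.9
>>> round(entropy_correction(-1.716, -0.842, -0.844), 6)
-0.03
```

## Worked example

Build a six-residue synthetic dimer, generate a 500-frame staged
trajectory (the chains approach through planted contact events), compute
the per-frame energy matrix with the GB engine, and recover the planted
stage boundaries from the anti-correlated `dE_MM`/`dE_sol` series:

```python
from dimerpbsa.binding import (energy_matrix, entropy_correction,
                               schlitter_entropy, trajectory_summary)
from dimerpbsa.model_io import select_chain
from dimerpbsa.solvation import SolvationConfig
from dimerpbsa.synthetic import StagePlan, build_toy_dimer, generate_staged_trajectory
from dimerpbsa.timeseries import moving_average, normalize_series, segment_stages

topo, ff = build_toy_dimer(6, seed=3)
plan = StagePlan.default(n_frames=500, seed=7)
traj = generate_staged_trajectory(topo, plan)

matrix = energy_matrix(traj, ff, SolvationConfig(n_sphere_points=240))
summary = trajectory_summary(matrix)
print("dG_bind = %.2f +/- %.2f kcal/mol"
      % (summary.mean["dG_bind"], summary.sd["dG_bind"]))
print("dE_MM   = %.2f, dG_sol = %.2f kcal/mol"
      % (summary.mean["dE_MM"], summary.mean["dG_sol"]))

ent = {t: schlitter_entropy(traj, select_chain(topo, t))
       for t in ("complex", "A", "B")}
print("-T dS   = %.2f kcal/mol" % entropy_correction(
    ent["complex"].minus_t_s, ent["A"].minus_t_s, ent["B"].minus_t_s))

sm = lambda col: moving_average(normalize_series(matrix[col].to_numpy()), 41)
sb = segment_stages(sm("dE_MM"), sm("dE_sol"), window=15)
print("planted stage boundaries:", plan.boundaries)
print("recovered boundaries:    ", sb.boundaries)
```

Output (deterministic for these seeds):

```
dG_bind = 5.04 +/- 2.89 kcal/mol
dE_MM   = -43.86, dG_sol = 48.90 kcal/mol
-T dS   = -1.44 kcal/mol
planted stage boundaries: (73, 179, 307, 478)
recovered boundaries:     (81, 169, 319, 467)
```

All four planted boundaries are recovered within 12 frames (less than
half the 41-frame smoothing window). The positive mean `dG_bind` is
expected: most of the staged trajectory is spent at large separation,
where the desolvation penalty of the toy model dominates.

Hydrogen-bond occupancies planted into a second trajectory are recovered
exactly, because the generator schedules bonds as exact frame subsets:

```python
from dimerpbsa.structure import hbond_occupancy, hbond_presence_matrix
from dimerpbsa.synthetic import PlantedBond

bonds = (
    PlantedBond(donor_chain="A", donor_residue=2, acceptor_chain="B",
                acceptor_residue=2, occupancy=0.62),
    PlantedBond(donor_chain="A", donor_residue=4, acceptor_chain="B",
                acceptor_residue=4, occupancy=0.35),
)
plan2 = StagePlan.default(n_frames=500, seed=7, contact_schedule=bonds)
traj2 = generate_staged_trajectory(topo, plan2)
print(hbond_occupancy(hbond_presence_matrix(traj2)).head(3).to_string(index=False))
```

```
               bond category  occupancy_percent
A:ASP2:N->B:ASP2:OD    inter               62.0
 A:ALA4:N->B:ALA4:O    inter               35.0
```

## Command line

```bash
# generate a synthetic input set (PDB topology, trajectory, parameters)
dimerpbsa synth --n-residues 6 --frames 200 --seed 5 --out inputs/

# run the full analysis pipeline from a YAML config (or --topology/--trajectory/--params)
dimerpbsa run-all --config config.yaml

# segment stages from an existing energy matrix
dimerpbsa stages --matrix out/energy_matrix.csv --out out/

# pick the most favorable replica from per-replica energy matrices
dimerpbsa replica-select r0.csv r1.csv r2.csv --tail-ns 1.0
```

`run-all` writes an artifact bundle (energy matrix, summary, entropy,
stage table, hydrogen-bond presence/density/occupancy, per-chain RMSD
matrices, contact map, per-frame conformation classification and a
manifest with versions, seed and configuration) and is byte-for-byte
deterministic for a fixed configuration.

## Defaults mirror the study conditions

The synthetic generator defaults reproduce the conditions the pipeline is
designed for: a 19 ns production window sampled every 4 ps (4750 frames —
`sample_frames` computes this count), four association stages at
fractional positions 0.147/0.358/0.616/0.958 of the trajectory, and a
26-replica temperature ladder spanning 280–405 K in which the 305 K
replica is the persistently bound one.

## Reproduction

```bash
# unit, property, oracle and acceptance tests (~1 min)
pytest -q tests/

# end-to-end battery; writes every headline quantity as JSON (~40 s)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

With `--seed 1` the battery reports, among other quantities:
`pb_born_ion_rel_error_pct = 1.65` (0.25 Å grid vs the analytic Born
energy), `schlitter_1dof_rel_error = 0.0`, `kabsch_rigid_copy_rmsd_max ≈
1.1e-14`, `stage_recovery_runs_passed = 100` of 100 noisy runs,
`replica_recovered = 1` (index 5 of 26, the 305 K replica) and
`hbond_occupancy_max_abs_error_pct = 0.0` for planted occupancies of
34.4/23.5/23.4/22.1/17.0 %. All values are computed at run time; nothing
is read from fixtures.

## Layout

```
src/dimerpbsa/      package (model_io, mm_energy, solvation, binding,
                    structure, timeseries, synthetic, pipeline, cli)
tests/              pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py   end-to-end battery
docs/methods.md     model, numerics, generator scope and limitations
```
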