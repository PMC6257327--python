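# Methods

This note records the physical model, the numerical choices, and the scope
of the synthetic data generator behind `dimerpbsa`. Everything here is
implemented in `src/dimerpbsa/`; nothing is fitted to external data at run
time.

## 1. Model and decomposition

The package analyzes a two-chain peptide dimer (chains `A` and `B`, complex
`C`) with a single-trajectory implicit-solvent end-point protocol. For each
frame the effective free energy of a species `X` is

```
G_X = E_MM(X) + G_sol(X)
E_MM = E_int + E_ele + E_vdw          (internal = bond + angle + dihedral)
G_sol = G_polar + G_nonpolar
```

and the binding energy is the species difference

```
dE_bind = G_C − G_A − G_B = dE_MM + dE_sol
```

Because both monomer terms are evaluated on coordinates extracted from the
complex trajectory (single-trajectory protocol), every internal coordinate
of `A` and `B` is identical in the complex and monomer evaluations, so
`dE_int ≡ 0` exactly; `dE_MM` reduces to the inter-chain electrostatic and
van der Waals interaction. The per-frame energy matrix carries 18 energy
columns (six terms × three species plus the differences) plus `time_ps`,
and the identities

```
dE_bind = dE_MM + dE_sol
dE_bind = (E_MM_C + E_sol_C) − (E_MM_A + E_sol_A) − (E_MM_B + E_sol_B)
```

hold to 1e-8 kcal/mol per frame by construction; the test suite asserts
them on every generated trajectory.

A configurational-entropy correction `−TΔS = −T S_C + T S_A + T S_B` is
estimated with the Schlitter upper-bound formula (section 4).

## 2. Molecular-mechanics terms

Standard fixed-charge force-field functional forms:

- bonds `k (d − b0)²` and angles `k (θ − θ0)²` (no factor ½; `k` absorbs it),
- periodic dihedrals `k (1 + cos(n φ − δ))`,
- Coulomb `K_E q_i q_j / r` with `K_E = 332.0637` kcal·Å/mol·e²,
- Lennard-Jones 12-6 in `rmin/2, ε` parameterization with Lorentz–Berthelot
  style combination (`rmin = rmin_half_i + rmin_half_j`, `ε = √(ε_i ε_j)`).

Nonbonded exclusions follow the usual topology rules: pairs separated by
one or two bonds are excluded, 1-4 pairs are scaled by `1/1.2`
(electrostatics) and `1/2.0` (Lennard-Jones). Bond-path distances are
computed by breadth-first search on the bond graph. Pairs closer than
0.1 Å raise an error rather than returning a huge energy.

## 3. Implicit solvation

`G_polar` is available from two engines sharing one configuration object:

- **Finite-difference Poisson solver (`engine="pb"`).** Successive
  over-relaxation on a uniform grid, two-dielectric model (interior 1,
  water 80), molecular volume defined by atomic radii plus `probe_radius`,
  charges spread to the eight surrounding grid points (trilinear).
  The reaction-field energy is the grid-charge interaction energy minus
  the same quantity computed in a homogeneous reference dielectric, which
  cancels the grid self-energy. Accuracy is controlled by `grid_spacing`:
  for a Born ion (q = 1 e, R = 2 Å) the relative error is 6.5 % at 1.0 Å,
  4.2 % at 0.5 Å and 1.7 % at 0.25 Å spacing, and the test suite pins the
  0.25 Å result to within 2 % of the analytic Born energy.
- **Generalized Born (`engine="gb"`).** Still-style pairwise formula with
  effective radii from the Coulomb-field approximation (pairwise
  descreening integrals). Exact for an isolated ion; agrees with the PB
  engine within 2 % on the Born ion; reproduces the screened-Coulomb limit
  for well-separated charges to 1e-9 relative.

The GB engine is the pipeline default: it is orders of magnitude faster
and smooth in the coordinates, which matters for per-frame time series.

`G_nonpolar = β + γ·SASA` with `γ = 0.00542 kcal/mol/Å²` and
`β = 0.92 kcal/mol` per species. The solvent-accessible surface area uses
the Shrake–Rupley method on a deterministic golden-spiral point set
(default 960 points/atom; tests and examples use 240 for speed). Note the
per-species constant β contributes `−β` to `dE_sol` (three species, C−A−B);
asymptotic-separation tests therefore set `β = 0`.

## 4. Schlitter entropy

The absolute configurational entropy upper bound

```
S = ½ k_B ln det(1 + k_B T e² / ħ² · M^{1/2} σ M^{1/2})
```

is evaluated from the mass-weighted covariance matrix σ of the Cartesian
coordinates (optionally after least-squares superposition onto the first
frame to remove rigid-body motion, `fit=True` by default). The determinant
is computed through the symmetric eigendecomposition with eigenvalues
clipped at zero, which makes the estimate exact for analytic 1-DOF
Gaussians (verified to 1e-6 relative) and exactly zero for static or
purely rigid-body trajectories. A warning is raised when
`n_frames − 1 < 3 n_atoms`, where the covariance is rank-deficient and the
bound is systematically low.

## 5. Structure analysis

- **RMSD.** Kabsch superposition via quaternion alignment. The residual is
  evaluated on the explicitly rotated coordinates, not the closed-form
  trace expression, which loses ~7 digits to cancellation for
  near-identical structures; rigid copies give RMSD at machine precision.
- **Hydrogen bonds.** Geometric criterion: donor–acceptor distance
  ≤ 3.5 Å and donor–hydrogen–acceptor angle ≥ 120°, with covalently
  bonded or 1-3 connected pairs skipped. Bonds are labeled
  `chain:RESn:atom->chain:RESn:atom` and categorized `inter`, `intra_A`,
  `intra_B`. Occupancy is the percentage of frames in which a bond is
  present; a windowed density partitions counts over time.
- **Contact maps.** Residue–residue side-chain minimum-distance contacts
  at a 6.5 Å default cutoff, per frame or trajectory-averaged fractions.
- **Conformation classifier.** Each chain's CA trace is tested for a
  hairpin (a local direction reversal flanked by two extended strands).
  Two hairpins are labeled by which strands face each other (N or C,
  decided by inter-chain strand contacts) and relative orientation
  (parallel/antiparallel): `CC-antiparallel`, `NC-parallel`, etc. One
  hairpin whose partner chain wraps it (termini subtend ≥ 120° at the
  hairpin centroid) gives `nested-*` or `antinested-*` labels. Everything
  else is `unclassified`. Requires ≥ 6 residues per chain.

## 6. Time-series analysis

Binding-energy trajectories are mean-centered (`normalize_series`) and
smoothed with a centered boxcar (`moving_average`, shrinking windows at the
edges). `segment_stages` marks stage boundaries at frames where the
smoothed `dE_MM` has a local minimum and the smoothed `dE_sol` has a
matching local maximum within the search window — the anti-correlation of
molecular-mechanics attraction and desolvation penalty is the signature of
a contact event. Candidate extrema must exceed a prominence floor
(`min_prominence="auto"` = 5 × a robust noise scale estimated from the
median absolute first difference, corrected for smoothing); this filters
noise-induced extrema without any per-dataset tuning. `select_replica`
ranks replicas by the tail-window mean of the inter-monomer interaction
(`ΔE_ele + ΔE_vdw + ΔG_sol`).

## 7. Synthetic data generator: scope and limitations

`build_toy_dimer(n)` constructs two identical n-residue chains in a
united-atom representation (6 atoms per residue: N, H, CA, side-chain tip,
C, O), with one anionic (OD) and one cationic (NZ) side chain per chain so
that chains are neutral but have a specific electrostatic contact. Force
constants, equilibrium values and charges are fixed by the builder;
equilibrium geometry parameters are read off the reference structure, so
the internal energy of the reference coordinates is exactly zero.

`generate_staged_trajectory` moves chain B along the separation axis
through a piecewise-constant separation profile with multiplicative
Gaussian wells that dip to contact distance at planted stage boundaries,
plus isotropic coordinate noise. `PlantedBond` schedules place exact
donor–acceptor geometries (2.9 Å, linear) in a chosen subset of frames —
occupancies are planted as exact frame counts, so recovery is expected to
be exact, not statistical. `generate_replica_set` produces one trajectory
per temperature with noise amplitude ∝ √T and only the designated replica
in persistent contact.

One interaction to be aware of: planted-bond frames hold the acceptor
2.9 Å from the donor nitrogen, which puts the donor hydrogen deep inside
the descreening volume of a fat united-atom acceptor tip (2.5 Å radius).
The GB solver treats a non-positive inverse effective radius as an error
(it signals unphysical burial), so energy evaluation on trajectories with
planted contact schedules can raise; planted bonds are intended for the
structure-analysis recovery experiments (detection, presence, occupancy),
not for energetics. Energetics examples and the pipeline use trajectories
without contact schedules.

Limitations, by design: the generator produces caricatures, not physics.
There is no thermostat or integrator — frames are independent draws around
a deterministic profile; the united-atom model has no transferable force
field; solvation parameters are illustrative. The generator exists to
plant known signals (stage boundaries, a best replica, hydrogen-bond
occupancies, binding-energy anti-correlation) that the analysis code must
recover, and every default (19 ns window, 4 ps interval, 4750 frames,
stage boundary fractions 0.147/0.358/0.616/0.958, 26 replicas spanning
280–405 K with the best at 305 K) mirrors the study conditions the
pipeline is meant to process.

## 8. Numerical conventions

Energies kcal/mol, distances Å, times ps (stage tables report ns),
temperatures K, entropies kcal/mol/K (reported alongside `−TS` in
kcal/mol). All random number use goes through `numpy.random.default_rng`
with explicit seeds; every generator and pipeline output is bit-for-bit
reproducible given the same seed and configuration.
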