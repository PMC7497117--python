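# Methods

Model definitions, parameter provenance, numerical choices, and the limits
of the bundled fixtures. Units: nm, ps, kJ/mol, K, amu;
k_B = 0.0083144621 kJ mol⁻¹ K⁻¹; PDB coordinates (Å) are divided by 10 on
read.

## Dual-resolution representation

A protein–ligand complex is split at residue granularity. The `n_at`
residues closest to the ligand — ranked by the distance between each
residue's mass-weighted centre of mass and the closest ligand atom, ties
broken by residue index — remain atomistic; all others are coarse-grained to
a single bead placed on their Cα. Residues in direct contact with the
ligand (minimum heavy-atom distance ≤ 0.45 nm, configurable) are expected to
head that ranking; if a requested selection would exclude a contact residue
the mapping is rejected rather than silently accepted.

## Elastic network

The coarse-grained region is a Cα elastic network with energy

    E = Σ_{i<j} k_ij (r_ij − r_ij⁰)² θ(r_c − r_ij⁰)

— note: no ½ prefactor, so a bond's harmonic stiffness is 2k_ij. Two spring
species: a stiff backbone constant k_b = 5×10⁴ kJ mol⁻¹ nm⁻² between beads
of consecutive residues (bonded regardless of separation) and a weaker
k_nb = 160 kJ mol⁻¹ nm⁻² between all other pairs whose native distance lies
below the cutoff r_c = 1.2 nm. Native distances come from the reference
conformation, so energy and forces vanish there.

Fluctuations follow from the analytic Hessian at the native state: each bond
contributes 2k·ûûᵀ blocks along its unit vector (transverse curvature
vanishes at the minimum). The thermal covariance is k_BT·H⁺, with the
pseudo-inverse excluding modes whose eigenvalue is below 10⁻⁸ times the
largest; a well-posed non-collinear network has exactly six such rigid-body
modes, and more than six raises an error (disconnected or collinear
networks). A literally collinear bead chain has *more* than six soft modes
under a central-force network — the transverse directions are free — so
collinear inputs are reported as ill-conditioned rather than given a
three-mode special case. Per-bead RMSF is the square root of the trace of
the bead's 3×3 covariance block; bead masses never enter equilibrium
fluctuations.

`fit_knb` minimizes the RMSE between predicted and reference Cα RMSF over
k_nb with a golden-section search on log k_nb in [10⁻¹, 10⁶] (relative
tolerance 10⁻³), holding k_b and r_c fixed. The Hessian is assembled once as
a backbone part plus a unit-strength non-bonded part and rescaled per
evaluation.

## Excluded-volume coupling

Coarse-grained beads repel their surroundings through a purely repulsive
Weeks–Chandler–Andersen potential (Lennard-Jones truncated at its minimum
2^{1/6}σ and shifted up by ε). Per-bead σ_i = R_{g,i}·c with the residue's
all-atom radius of gyration and a single shared scale factor c = 0.658;
ε = 0.34 kJ/mol. Degenerate single-atom residues (R_g = 0) are floored at
σ = 0.05 nm with a warning. `calibrate_c` finds c against any monotone
scalar observable by bisection (relative tolerance 10⁻⁴); a stochastic
objective must fix its own seed so repeated evaluations agree.

## Alchemical potentials

**Soft-core Lennard-Jones** (Beutler form):
U = λ·4ε[(σ⁶/A)² − σ⁶/A] with A = ασ⁶(1−λ)^p + r⁶, α = 0.5, p = 1.0.
Finite at r = 0 for λ < 1, identically zero at λ = 0, and exactly plain
Lennard-Jones at λ = 1. The λ-derivative and radial force are analytic.

**Reaction-field Coulomb**: U = f·q_iq_j(1/r + k_rf r² − c_rf) for
r ≤ r_cut, zero beyond, with k_rf = (ε_rf−1)/((2ε_rf+1)r_cut³), ε_rf = 80,
r_cut = 1.2 nm, and c_rf chosen so U vanishes continuously at the cutoff;
f = 138.935458 kJ mol⁻¹ nm e⁻². Charges scale linearly in λ (no Coulomb
soft core is needed while the Lennard-Jones cores are intact).

**Boresch restraints**: one distance r(P1–L1), two angles
θ_A(P2‑P1‑L1), θ_B(P1‑L1‑L2), three dihedrals φ_A(P3‑P2‑P1‑L1),
φ_B(P2‑P1‑L1‑L2), φ_C(P1‑L1‑L2‑L3) over three protein and three ligand
anchor atoms, each harmonically restrained to its reference value with
energy λ·Σ½k(x−x₀)²; dihedral deviations are wrapped to (−π, π]. Default
force constants: k_r = 4184 kJ mol⁻¹ nm⁻², angles/dihedrals
41.84 kJ mol⁻¹ rad⁻². Forces are analytic (angle and dihedral gradients
verified against finite differences). Removal of the restraints to the
standard state V° = 1.661 nm³ (1 M) has the stiff-spring closed form

    ΔG_r,off = −k_BT ln[ 8π² V° / (r₀² sinθ_A⁰ sinθ_B⁰)
                          · √(Π k) / (2π k_BT)³ ]

valid when the restrained fluctuations are small; the acceptance suite
compares it with direct quadrature of the restrained partition function.

## Sampling and estimation

Langevin dynamics with the BAOAB splitting: half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity update, half-drift, half-kick. Defaults:
T = 298 K, friction γ = 15 ps⁻¹, time step 1 fs. Velocities are initialised
from Maxwell–Boltzmann; with γ = 0 the scheme reduces to velocity Verlet and
conserves energy to O(dt²). The integrator is shape-agnostic, so many
independent λ-windows can be propagated in one vectorized trajectory.
Identical parameters and seed give identical trajectories; configurations
are checked for finiteness at every sampling point and divergence is
reported with its step index.

Each TI leg integrates ⟨∂U/∂λ⟩ over λ with the trapezoidal rule. λ-grids
are evenly spaced including both endpoints (defaults: 11 restraint / 15
Coulomb / 5 Lennard-Jones windows on the complex leg, 5/16 on the ligand
leg); a schedule missing an endpoint is rejected unless partial integration
is explicitly requested. Per-window uncertainties are 95 % confidence
half-widths from four contiguous block means and the Student-t distribution
(trailing remainder dropped); the integral uncertainty is the
|weight|-weighted linear sum of window errors.

## Thermodynamic cycle

    ΔG_bind = ΔG_compl + ΔG_lig + ΔG_r,off

with ΔG_compl = ΔG_restr,on + ΔG_Coul,c + ΔG_LJ,c (restraints switched on,
then protein–ligand Coulomb and Lennard-Jones interactions switched off in
the complex) and ΔG_lig = ΔG_Coul,l + ΔG_LJ,l (ligand re-grown into
solvent). Component uncertainties combine by **linear addition** — a
deliberately conservative convention that matches the published benchmark
totals (9.1 + 8.0 = 17.1); quadrature summation is available as an option.
The analytic restraint-removal term always carries zero uncertainty. Both
the decoupling route (per-component legs) and the annihilation route
(pre-summed complex and ligand legs) are supported by the ledger.

## Resolution quality

The total ΔG_bind is nearly flat in the number of atomistic residues, but
its complex-leg components are not. The quadratic deviation of each
resolution from the fully atomistic reference,

    δ² = (ΔG_Coul − ΔG_Coul,at)² + (ΔG_LJ − ΔG_LJ,at)² + (ΔG_Restr − ΔG_Restr,at)²,

is unweighted (uncertainties ignored) and uses the complex-leg components
only, since the ligand and restraint-removal legs do not depend on protein
resolution. On the bundled lysozyme benchmark the scan gives δ² = 448.62 at
3 atomistic residues, a minimum of 11.74 at 6, and larger values again above
8 — the statistic exposes an optimal intermediate resolution.

## Bundled benchmark

`duores.benchmarks` carries the published free-energy components for hen
egg-white lysozyme bound to tri-N-acetylchitotriose (complex-leg components
for 3–10 atomistic residues and the fully atomistic reference, the ligand
leg, ΔG_r,off = −31.3 kJ/mol, and pre-summed annihilation legs from two
simulation engines). These are regression anchors for the cycle arithmetic
and the resolution scan; the explicit-water simulations behind them are not
re-run here.

## Synthetic fixtures and their limits

`make_toy_complex` generates a deterministic α-helical Cα trace (rise
0.15 nm, twist 100°, radius 0.23 nm → consecutive spacing ≈ 0.383 nm, kept
within 10 % of 0.38 nm by a small seeded jitter), 3–8 satellite atoms per
residue, and a 5–20 atom ligand cluster within 0.5 nm of a pocket residue.
The toy force field (`demo.ToyComplexModel`) holds the receptor rigid and
moves only ligand atoms; the ligand's internal structure is maintained by
harmonic bonds between every atom pair, ligand–protein attraction is a
Gō-style Lennard-Jones with per-pair σ chosen so the native distance sits at
the minimum, charges are small synthetic alternating partials, and
coarse-grained beads repel through WCA. Because the toy ligand has no
intramolecular *non-bonded* terms, the decoupling and annihilation
transformations coincide on it by construction. These fixtures exercise
every piece of the alchemical machinery at desk scale but carry no
chemistry: toy ΔG values are not comparable to the lysozyme benchmark, and
sub-nanosecond toy trajectories carry large statistical errors.

## Acceptance checks

`tests/test_acceptance.py` verifies:

1. the cycle ledger reproduces the benchmark binding values and leg totals
   exactly from their printed components;
2. the resolution scan reproduces δ²(aa-3) = 448.62 and δ²(aa-6) = 11.74 and
   selects 6 atomistic residues;
3. harmonic-alchemy TI covers the closed form (k_BT/2)ln 4 ≈ 1.7174 kJ/mol
   with its own 95 % CI for ≥ 90 % of 20 seeds;
4. the elastic-network Hessian matches finite differences to 10⁻⁴, has
   exactly six rigid-body modes, agrees with a Langevin Boltzmann-sampling
   RMSF oracle within 5 % per bead, and recovers a planted k_nb = 160 within
   ±10 %;
5. the analytic restraint removal matches direct quadrature within 1 % in
   the stiff-spring regime, with the V°-additivity and force-constant
   scaling identities holding to 10⁻⁸;
6. soft-core λ = 1 equals plain Lennard-Jones and λ = 0 vanishes on an
   r-grid, and the reaction-field energy vanishes at the cutoff.
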