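# Methods

## The σ-bonded model

The η⁵ interaction between rhodium and the Cp* ring is represented by five
explicit Rh–C harmonic bonds. This preserves compatibility with standard
Amber-style machinery but misrepresents the local physics in two known
ways: the averaged N–Rh–C equilibrium angles squeeze the ring carbons
toward the ring center, and they push all ligands away from the metal. The
published parameter sets counteract both effects by construction —
elongated aromatic C–C equilibria inside Cp* and shortened metal–ligand
bond equilibria — so the *parameters* must be read as effective quantities
whose only contract is that unconstrained dynamics reproduces the target
geometry. All five ring carbons share one atom type (Y1), both
coordinating nitrogens one type (Y6), and the 2,2′ carbons of the diimine
one type (YC), which makes the ring rotation a symmetry of the potential.
Every torsion containing the metal carries a zero barrier; the metal also
participates in no angle terms within the Cp* ring block (Y1–M1–Y1,
M1–Y1–Y1, M1–Y1–c3 are present with zero force constants), since the σ
bonds and the N–Rh–C angles already determine the metal-site geometry.

Functional form and conventions: harmonic bonds and angles, Fourier
torsions `(V_n/divider)[1 + cos(nφ − γ)]` with the frcmod IDIVF divider,
12-6 Lennard-Jones with Lorentz–Berthelot combination of the per-type
R*/2 and well depth, Coulomb with `k_e = 332.0522 kcal·Å·mol⁻¹·e⁻²`,
1-2/1-3 exclusions, and 1-4 interactions divided by 1.2 (electrostatic)
and 2.0 (van der Waals). Pair classification uses shortest bond-graph
distance, so ring-internal 1-3 paths win over longer ones. Gas-phase
evaluations use no cutoff; periodic systems use plain truncation with the
minimum-image convention in an orthorhombic box (no Ewald summation — the
toolkit targets desk-scale systems of at most a few thousand atoms, and
the nonbonded pair list is explicit O(N²)).

Angles are evaluated in radians with the arccos argument clamped to
|cos θ| ≤ 1 − 1e-12; torsions use the atan2 formulation, and their
analytic forces were validated against central finite differences
(relative agreement ≤ 1e-6 on randomized systems).

## Parameters, typing and charges

The custom Rh parameters ship as `rh1.frcmod` / `rh3.frcmod`. Custom types
fall back to their standard counterparts (Y1/YC → ca, Y6 → nb, Y8 → cl)
for any term the custom tables do not list — e.g. Y1–Y1–c3 resolves to
ca–ca–c3 — against a vendored minimal subset of general-Amber-style
parameters (`standard_subset.frcmod`, nominal first-generation values,
which for these aromatic types are close to the second generation). The
metal's 12-6 parameters are a fixture choice (UFF-derived, R*/2 =
1.4645 Å, ε = 0.053 kcal/mol); they act only on 1-4-and-beyond pairs and
on solvent.

Per-atom charges are a documented fixture: the published aggregates fix
the metal (−0.7 e reduced, −0.3 e oxidized), the chloride (−0.4 e), the
methyl-hydrogen range (+0.08/+0.10 e) and the net charge (0 / +1); within
those constraints the remaining values follow a type-based pattern with
modest local dipoles, the ligand totals closed exactly by a uniform shift,
and everything symmetrized over the automorphism classes. Symmetry classes
are computed by iterative neighborhood color refinement on the typed bond
graph (so phen and dppz work unchanged), which for this family coincides
with the automorphism orbit partition.

## Sampler

BAOAB-splitting Langevin dynamics (time step 2 fs, collision frequency
1 ps⁻¹, 300 K unless stated), with SHAKE applied after each drift
half-step to all hydrogen-containing bonds (relative tolerance 1e-7) and
RATTLE velocity projections after the kicks. Waters are rigid 3-site
TIP3P-class molecules (0.9572 Å, 104.52°, −0.834/+0.417 e) made rigid by
constraining both O–H bonds and the H–H edge — a deliberate simplification
relative to 4-site models, adequate for the qualitative solvation
analyses here. Kinetic temperature subtracts one degree of freedom per
constraint and, for unthermostatted runs, net translation; note the
full-step velocities of the BAOAB scheme read a few percent cold at 2 fs
for the stiff modes, while configurational sampling (what the structural
means use) is the scheme's strong point. Minimization runs steepest
descent with adaptive step length followed by conjugate gradient, with
SHAKE disabled. Heating ramps the thermostat target linearly from 0 K
(100 ps by default) before constant-temperature equilibration.
Solvation builds a cubic box from a jittered-lattice water generator at
0.0334 Å⁻³, removes waters within 2.4 Å of the solute, and adds one free
chloride counter-ion for net-charged complexes.

## Calibration loop

Because the σ-model couples antagonistic terms, equilibrium parameters
cannot be set to the target values directly. The loop runs a short
gas-phase simulation (200–300 ps per iteration by default, first 20%
discarded), measures the target descriptors, and applies damped
proportional feedback `new_eq = old_eq − 0.5·(mean − target)` per
symmetry-equivalence class, only when the error exceeds both the stopping
threshold and twice the block standard error (10 blocks) — adjustments are
never made to chase noise. Convergence requires every bond error below
0.01 Å and every angle error below 1°; force constants are never touched.
Centroid descriptors (M1–Cp*, Y6–M1–Cp*) are diagnostics: they gate
convergence but respond only through the adjustable bond/angle classes.
Dihedral descriptors use the folded |φ| convention (mean magnitude on
[0°, 180°]), so a near-planar methyl reports ≈174° rather than the
circular mean collapsing to 180° for a symmetric ±174° mixture.

## Scans and analysis

Scans displace one rigid ligand (Cp* ring + methyls, the whole diimine, or
the halide) with all other atoms fixed: distances translate along the
metal–anchor axis; around-axis rotations turn about it; in-plane and
out-of-plane rotations use the two perpendicular axes of the
metal–anchor–ligand frame, anchored at the Cp* centroid (unweighted Y1
mean) or the Y6 midpoint. Profiles are reported per term class relative to
the zero-displacement point. Two symmetry facts worth noting: the bonded
profile of the around-axis rotation is exactly 72°-periodic but *not*
flat — the ten N–Rh–C angle terms leave a ≈5 kcal/mol periodic ripple,
an intrinsic feature of the σ-bonded approximation with these published
force constants — and mirror evenness holds for the out-of-plane
rotations, while the "in-plane" rotation is a pitch within the complex's
mirror plane and is genuinely asymmetric (toward versus away from Cp*).

The RDF uses minimum-image distances, shell-volume and bulk-density
normalization (0.05 Å bins by default). The SDF superposes every frame
onto the first by Kabsch alignment of a user-chosen rigid selection
(recommended: metal + diimine heavy atoms, excluding the rotating Cp*),
bins a species on a cubic lattice of 0.2 Å cells, and marks cells whose
mean per-frame count reaches 5× the bulk expectation
(0.0334 Å⁻³ × 0.008 Å³ ≈ 2.7 × 10⁻⁴ molecules per cell; oxygen cutoff
1.34 × 10⁻³, hydrogen 2× that since each molecule carries two).

## Synthetic data and what passing tests show

All test inputs are generated: ideal complex geometries assembled from
internal coordinates (exact on the metal-proximal reference descriptors,
planar aromatic rings, standard values elsewhere), fixture charges as
above, jittered-lattice water boxes, and synthetic calibration cases whose
targets come from simulating a known-truth topology before perturbing its
equilibria (±0.05 Å / ±5°). These fixtures emulate idealized, noise-free
starting structures; they do not emulate conformational disorder of real
solvated ensembles, counter-ion placement statistics, or polarization.

Problem sizes are chosen for a single-CPU desk run: validation dynamics of
1 ns per oxidation state (a 12 ns run for distribution diagnostics),
calibration iterations of 200–300 ps. Two desk-scale limits are explicit:
(1) the reference structural means come from solvated-ensemble
simulations, and in bare gas phase the unscreened monopole electrostatics
of the net-charged Rh(III) complex shift the soft inter-ligand angles by
several degrees and the metal–ligand distances by ≈0.02–0.03 Å — a
charge-free control reproduces every reference mean to ≤0.02 Å / 1°,
isolating the cause; (2) fully decorrelating 10⁴ samples of the ring
rotation coordinate (relaxation ≈10 ps across the residual rotation
barrier) would need ~100 ns, so strict pairwise distribution-identity
statistics at that sample size are out of desk-scale reach, while the
nitrogen-pooled comparison (insensitive to rotation mixing) confirms the
underlying symmetry.

## Known limitations

No Ewald electrostatics, no pressure coupling (NVT only, box pre-sized to
the target density), explicit O(N²) nonbonded pair list, no polarizable
terms (polarizabilities in the parameter files are carried but unused),
and no automatic typing beyond the α-diimine/Cp*/halide family.
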