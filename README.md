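# rhcpff

A self-contained molecular-mechanics toolkit for pentamethylcyclopentadienyl
(Cp*) rhodium complexes with aromatic α-diimine ligands — the
[(bpy)Rh<sup>III</sup>(Cp\*)Cl]<sup>+</sup> catalysts used in NAD⁺/NADH
redox chemistry, CO₂ reduction and hydrogenation, and their reduced
[(bpy)Rh<sup>I</sup>(Cp\*)] intermediate — in both oxidation states and for
the bpy, phen and dppz ligands.

Classical force fields cannot represent the η⁵ Rh–Cp* bond directly, so the
package implements the **σ-bonded model**: the delocalized metal–ring
interaction is replaced by five explicit Rh–C bonds whose parameters are
deliberately *non-physical* (e.g. an equilibrium Rh–C length well below the
observed one) so that, in balance with averaged N–Rh–C angle terms, the
*simulated* geometry is correct. The potential is the standard Amber form

```
E = Σ k_b (r − r0)² + Σ k_θ (θ − θ0)² + Σ (V_n/divider)[1 + cos(nφ − γ)]
  + Σ_{i<j} [ A_ij/R_ij¹² − B_ij/R_ij⁶ + q_i q_j / (ε R_ij) ]
```

with 1-2/1-3 exclusions, Amber 1-4 scaling (1.2 / 2.0), Lorentz–Berthelot
combination, and every metal-containing torsion at zero barrier.

What's inside:

- `energy` — decomposed energies and analytic forces (numba kernels),
- `topology` — σ-model atom typing (M1/Y1/Y6/Y8/YC), term enumeration,
  automorphism-orbit symmetry classes, charge symmetrization,
- `io` — Amber frcmod, PDB, and a plain-text multi-frame XYZ trajectory,
- `sampler` — minimization, BAOAB Langevin dynamics with SHAKE on
  hydrogen-containing bonds, heating protocol, water-box solvation,
- `calibrate` — the iterative equilibrium-parameter calibration loop
  (adjust r0/θ0 until simulated means hit target geometry; force constants
  frozen),
- `scans` — rigid ligand-displacement scans with per-term energy profiles,
- `analysis` — RDF, solute-aligned 3D spatial distribution functions on a
  0.2 Å voxel grid, and the structural distribution diagnostics,
- `fixtures` — bundled custom parameters (`rh1.frcmod`, `rh3.frcmod`), a
  minimal standard-type subset, ideal geometries and fixture charges for
  all six complexes, water boxes, synthetic calibration cases.

## Worked example

```python
import numpy as np
import rhcpff as r

# build the neutral Rh(I)-bpy complex from bundled fixtures
structure, coords, topo = r.prepared_complex("bpy", "I")

x0, trace = r.minimize(topo, coords)
print(f"minimized: {trace[0]:.2f} -> {trace[-1]:.2f} kcal/mol")

cfg = r.SamplerConfig(steps=250_000, seed=11, snapshot_interval=100)  # 0.5 ns
traj = r.run_langevin(topo, x0, cfg)

table = r.measure_structural_means(traj, ["M1-Y1", "M1-Cp*", "Y6-M1-Y6"], topo)
print(table[["descriptor", "mean", "std"]])
```

prints (to the third decimal, machine-dependent in the last digit):

```
minimized: 25.96 -> 9.93 kcal/mol
  descriptor    mean    std
0      M1-Y1   2.227  0.065
1     M1-Cp*   1.865  0.036
2   Y6-M1-Y6  78.480  1.401
```

The Rh–C mean of 2.23 Å emerges from an equilibrium *parameter* of 2.16 Å:
the ten N–Rh–C angle terms push the ring outward and the shortened bond
equilibria compensate — the signature of the σ-bonded model. The bite angle
(N–Rh–N) averages 78° although its equilibrium parameter is 108°, because
the chelate ring closure opposes the angle term.

A thin CLI wraps the same functionality:

```
rhcpff simulate  --structure ideal_bpy_I.pdb --frcmod standard_subset.frcmod \
                 --frcmod rh1.frcmod --charges charges_bpy_I.txt \
                 --steps 100000 --seed 1 --out traj.xyz
rhcpff calibrate --structure ... --targets targets.tsv --out final.tsv --report rep.tsv
rhcpff scan      --structure ... --mode ring-around --grid -36:36:25 --out profile.tsv
rhcpff analyze   angles --traj traj.xyz --structure ... --out angles.tsv
```

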