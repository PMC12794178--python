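"""Minimizer, Langevin/SHAKE integrator, heating protocol and solvation."""
import numpy as np
import pytest

import rhcpff as r
from rhcpff.constants import KB
from rhcpff.energy import CompiledSystem
from rhcpff.sampler import build_water_topology, hydrogen_constraints, ramp_schedule
from rhcpff.terms import AtomSpec, BondTerm, Topology


def _single_bond_topology(k=100.0, r0=1.5, mass=12.0):
    atoms = [
        AtomSpec(0, "A", "C", "cx", mass, 0.0, 0.0, 0.0),
        AtomSpec(1, "B", "C", "cx", mass, 0.0, 0.0, 0.0),
    ]
    return Topology(atoms=atoms, bonds=[BondTerm(0, 1, k, r0)], exclusions={(0, 1)})


class TestMinimize:
    def test_displaced_harmonic_bond_converges_to_equilibrium(self):
        topo = _single_bond_topology()
        x, trace = r.minimize(topo, np.array([[0.0, 0, 0], [2.3, 0, 0]]))
        assert np.linalg.norm(x[0] - x[1]) == pytest.approx(1.5, abs=1e-4)
        assert trace[-1] <= trace[0]

    def test_steepest_descent_phase_is_non_increasing(self, rh1):
        _, coords, topo = rh1
        rng = np.random.default_rng(0)
        x0 = coords + rng.normal(0, 0.05, coords.shape)
        _, trace = r.minimize(topo, x0, n_steepest=400, n_conjugate=0)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_water_dimer_matches_grid_search_oracle(self):
        """Full minimization lands within 0.2 A of the O-O separation found
        by a dense 1-D grid search over rigid-monomer separation."""
        topo = build_water_topology(2)
        from rhcpff.fixtures import water_geometry

        mono = water_geometry()
        # donor: one O-H pointing along +x toward the acceptor O
        donor = mono.copy()
        # rotate so H1 points along +x
        v = donor[1] / np.linalg.norm(donor[1])
        axis_rot = np.array([[v[0], v[1], 0], [-v[1], v[0], 0], [0, 0, 1.0]])
        donor = donor @ axis_rot.T

        # acceptor with its H-H bisector along +x (hydrogens pointing away)
        rot90 = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        acceptor = mono @ rot90.T

        def dimer(sep):
            return np.vstack([donor, acceptor + np.array([sep, 0.0, 0.0])])

        system = CompiledSystem(topo)
        seps = np.arange(2.2, 4.5, 0.01)
        energies = [system.potential(dimer(s)) for s in seps]
        oracle_oo = seps[int(np.argmin(energies))]
        x, _ = r.minimize(topo, dimer(5.0), n_steepest=2000, n_conjugate=2000)
        oo = np.linalg.norm(x[0] - x[3])
        assert oo == pytest.approx(oracle_oo, abs=0.2)

    def test_overlapping_atoms_abort_with_pair_diagnostic(self):
        from rhcpff.sampler import SimulationError

        topo = _single_bond_topology()
        for a in topo.atoms:
            a.vdw_radius, a.vdw_well_depth = 1.9, 0.1
        topo.exclusions = set()
        with pytest.raises(SimulationError, match="closest pair"):
            r.minimize(topo, np.array([[0.0, 0, 0], [1e-30, 0, 0]]))


class TestLangevin:
    def test_seeded_determinism(self, rh1, rh1_min):
        _, _, topo = rh1
        x0, _ = rh1_min
        cfg = r.SamplerConfig(steps=2000, seed=42, snapshot_interval=100)
        t1 = r.run_langevin(topo, x0, cfg)
        t2 = r.run_langevin(topo, x0, cfg)
        assert np.array_equal(t1.frames, t2.frames)

    def test_ideal_gas_equipartition(self):
        """100 noninteracting particles thermalize to 300 K (within 3 SE)."""
        atoms = [AtomSpec(i, f"P{i}", "C", "cx", 12.0) for i in range(100)]
        topo = Topology(atoms=atoms)
        topo.exclusions = {(i, j) for i in range(100) for j in range(i + 1, 100)}
        rng = np.random.default_rng(0)
        x0 = rng.uniform(0, 50, (100, 3))
        cfg = r.SamplerConfig(steps=50_000, seed=3, snapshot_interval=50, shake_enabled=False)
        _, info = r.run_langevin(topo, x0, cfg, return_state=True)
        temps = info["temperatures"][200:]
        blocks = temps[: len(temps) // 10 * 10].reshape(10, -1).mean(axis=1)
        se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(temps.mean() - 300.0) <= 3 * se + 1.0

    def test_harmonic_bond_length_variance(self):
        """var(r) ~= kB T / (2 k) from the Boltzmann distribution of a
        harmonic bond (radial-Jacobian correction negligible for r0 >> sigma)."""
        topo = _single_bond_topology(k=300.0, r0=1.5)
        cfg = r.SamplerConfig(
            timestep=0.5, steps=400_000, seed=9, snapshot_interval=40, shake_enabled=False
        )
        traj = r.run_langevin(topo, np.array([[0.0, 0, 0], [1.5, 0, 0]]), cfg)
        rs = np.linalg.norm(traj.frames[:, 0] - traj.frames[:, 1], axis=1)[500:]
        expected = KB * 300.0 / (2 * 300.0)
        assert rs.var() == pytest.approx(expected, rel=0.10)

    def test_shake_keeps_hydrogen_bonds_at_constraint_length(self, rh1, rh1_min):
        _, _, topo = rh1
        x0, _ = rh1_min
        cfg = r.SamplerConfig(steps=5000, seed=5, snapshot_interval=50)
        traj = r.run_langevin(topo, x0, cfg)
        c_idx, c_d = hydrogen_constraints(topo)
        for f in range(traj.n_frames):
            d = np.linalg.norm(
                traj.frames[f, c_idx[:, 0]] - traj.frames[f, c_idx[:, 1]], axis=1
            )
            assert np.abs(d - c_d).max() / c_d.min() < 1e-6

    def test_nve_energy_drift_bound(self, rh1, rh1_min):
        """Thermostat off, SHAKE off, 0.5 fs timestep: total-energy drift
        of the gas-phase complex stays below 1e-3 kcal/mol/ps."""
        _, _, topo = rh1
        x0, _ = rh1_min
        cfg = r.SamplerConfig(
            timestep=0.5, friction=0.0, steps=40_000, seed=1,
            snapshot_interval=100, shake_enabled=False, temperature=300.0,
        )
        _, info = r.run_langevin(topo, x0, cfg, return_state=True)
        dof = 3 * topo.n_atoms - 3
        etot = info["potentials"] + 0.5 * dof * KB * info["temperatures"]
        t = np.arange(len(etot)) * cfg.snapshot_interval * cfg.timestep * 1e-3
        slope = np.polyfit(t, etot, 1)[0]
        assert abs(slope) < 1e-3

    def test_divergent_dynamics_raises(self):
        topo = _single_bond_topology(k=1e6, r0=1.0)
        cfg = r.SamplerConfig(timestep=50.0, steps=2000, seed=0, shake_enabled=False)
        from rhcpff.sampler import SimulationError

        with pytest.raises(SimulationError, match="diverged"):
            r.run_langevin(topo, np.array([[0.0, 0, 0], [3.0, 0, 0]]), cfg)


class TestHeating:
    def test_ramp_schedule_endpoints(self):
        cfg = r.SamplerConfig(timestep=2.0, temperature=300.0)
        sched = ramp_schedule(cfg, ramp_steps=50_000)  # 100 ps at 2 fs
        assert sched[0] == 0.0
        assert sched[-1] == pytest.approx(300.0 * (50_000 - 1) / 50_000)

    def test_zero_length_ramp_is_pure_equilibration(self, rh1, rh1_min):
        _, _, topo = rh1
        x0, _ = rh1_min
        cfg = r.SamplerConfig(steps=1000, seed=2, snapshot_interval=100)
        a = r.heat_then_equilibrate(topo, x0, cfg, ramp_steps=0)
        b = r.run_langevin(topo, x0, r.SamplerConfig(steps=1000, seed=3, snapshot_interval=100))
        assert a.n_frames == b.n_frames

    def test_heating_reproducible_under_fixed_seed(self, rh1, rh1_min):
        _, _, topo = rh1
        x0, _ = rh1_min
        cfg = r.SamplerConfig(steps=4000, seed=7, snapshot_interval=200)
        a = r.heat_then_equilibrate(topo, x0, cfg, ramp_steps=2000)
        b = r.heat_then_equilibrate(topo, x0, cfg, ramp_steps=2000)
        assert np.array_equal(a.frames, b.frames)

    def test_heating_reaches_target_temperature(self, rh1, rh1_min):
        _, _, topo = rh1
        x0, _ = rh1_min
        cfg = r.SamplerConfig(steps=30_000, seed=4, snapshot_interval=100)
        _, info = r.heat_then_equilibrate(
            topo, x0, cfg, ramp_steps=15_000, return_state=True
        )
        temps = info["temperatures"]
        assert temps[:20].mean() < temps[-50:].mean()
        assert temps[-50:].mean() == pytest.approx(300.0, rel=0.10)


class TestSolvate:
    def test_neutral_complex_gets_no_counterion(self, rh1):
        _, coords, topo = rh1
        solv, x, box = r.solvate(topo, coords, padding=12.0, cutoff=10.0, seed=1)
        assert not any(a.atom_type == "cl" and a.charge == -1.0 for a in solv.atoms)
        assert solv.net_charge == 0.0

    def test_charged_complex_gets_one_chloride(self, rh3):
        _, coords, topo = rh3
        solv, x, box = r.solvate(topo, coords, padding=12.0, cutoff=10.0, seed=1)
        ions = [a for a in solv.atoms if a.atom_type == "cl" and a.charge == -1.0]
        assert len(ions) == 1
        assert solv.net_charge == 0.0

    def test_no_water_oxygen_near_solute(self, rh1):
        _, coords, topo = rh1
        solv, x, box = r.solvate(topo, coords, padding=12.0, cutoff=10.0, seed=2)
        n0 = topo.n_atoms
        o_idx = [a.index for a in solv.atoms if a.atom_type == "ow"]
        dmin = min(
            np.linalg.norm(x[:n0] - x[o], axis=1).min() for o in o_idx
        )
        assert dmin >= 2.4

    def test_water_count_matches_density_for_point_solute(self):
        """A box around a single tiny solute holds density*volume waters
        within 5% (only a handful are carved out)."""
        atoms = [AtomSpec(0, "X", "C", "cx", 12.0)]
        topo = Topology(atoms=atoms)
        solv, x, box = r.solvate(topo, np.zeros((1, 3)), padding=10.0, cutoff=10.0, seed=3)
        n_w = sum(1 for a in solv.atoms if a.atom_type == "ow")
        expected = 0.0334 * box[0] ** 3
        assert n_w == pytest.approx(expected, rel=0.05)

    def test_padding_below_cutoff_rejected(self, rh1):
        _, coords, topo = rh1
        with pytest.raises(ValueError, match="padding"):
            r.solvate(topo, coords, padding=5.0, cutoff=10.0)
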