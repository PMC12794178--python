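"""RDF, SDF and distribution analysis on synthetic and simulated data."""
import numpy as np
import pytest
from scipy import stats

import rhcpff as r
from rhcpff.analysis import bulk_expectation_per_cell, kabsch
from rhcpff.trajectory import Trajectory


def _uniform_traj(n_atoms, n_frames, edge, seed):
    rng = np.random.default_rng(seed)
    frames = rng.uniform(0, edge, (n_frames, n_atoms, 3))
    boxes = np.full((n_frames, 3), float(edge))
    return Trajectory(frames, boxes, 0.1)


class TestRDF:
    def test_uniform_bulk_is_unity_within_counting_error(self):
        traj = _uniform_traj(400, 60, 20.0, seed=0)
        res = r.rdf(traj, np.arange(5), np.arange(5, 400), bin_width=0.25, r_max=9.0)
        frames, nc = 60, 5
        rho = 395 / 20.0**3
        shell = 4 / 3 * np.pi * ((res.bin_centers + 0.125) ** 3 - (res.bin_centers - 0.125) ** 3)
        expected_counts = frames * nc * rho * shell
        # Poisson 3-sigma band around g = 1
        tol = 3.0 / np.sqrt(expected_counts)
        assert np.all(np.abs(res.g - 1.0) <= np.maximum(tol, 1.0))

    def test_two_fixed_particles_single_bin(self):
        frames = np.array([[[0.0, 0, 0], [3.0, 0, 0]]])
        traj = Trajectory(frames, np.full((1, 3), 20.0), 0.1)
        res = r.rdf(traj, np.array([0]), np.array([1]), bin_width=0.1, r_max=8.0)
        nz = np.nonzero(res.counts)[0]
        assert len(nz) == 1
        assert res.bin_centers[nz[0]] == pytest.approx(3.05, abs=0.051)

    def test_exclusion_sphere_gives_zero_core_and_enhanced_shell(self):
        rng = np.random.default_rng(1)
        edge, n, frames = 20.0, 300, 80
        center = np.full(3, edge / 2)
        pts = []
        for _ in range(frames):
            p = rng.uniform(0, edge, (2 * n, 3))
            p = p[np.linalg.norm(p - center, axis=1) > 2.0][:n]
            pts.append(np.vstack([center, p]))
        traj = Trajectory(np.array(pts), np.full((frames, 3), edge), 0.1)
        res = r.rdf(traj, np.array([0]), np.arange(1, n + 1), bin_width=0.25, r_max=9.0)
        assert np.all(res.g[res.bin_centers < 1.9] == 0.0)
        outer = res.g[res.bin_centers > 2.5]
        enhancement = 1.0 / (1.0 - (4 / 3 * np.pi * 2.0**3) / edge**3)
        assert outer.mean() == pytest.approx(enhancement, rel=0.02)

    def test_r_max_beyond_half_box_rejected(self):
        traj = _uniform_traj(10, 2, 20.0, seed=2)
        with pytest.raises(ValueError, match="half"):
            r.rdf(traj, np.array([0]), np.arange(1, 10), r_max=11.0)

    def test_empty_selection_rejected(self):
        traj = _uniform_traj(10, 2, 20.0, seed=3)
        with pytest.raises(ValueError, match="empty"):
            r.rdf(traj, np.array([], dtype=int), np.arange(10))


class TestSDF:
    def test_bulk_expectation_per_voxel(self):
        # ambient water number density in 0.2 A cells
        assert bulk_expectation_per_cell(0.2) == pytest.approx(0.0334 * 0.008)

    def test_count_conservation(self):
        rng = np.random.default_rng(4)
        anchors = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0]])
        frames = []
        for _ in range(50):
            frames.append(np.vstack([anchors, rng.uniform(-4, 4, (30, 3))]))
        traj = Trajectory(np.array(frames), None, 0.1)
        grid = r.sdf(traj, np.arange(3), np.arange(3, 33), cell_edge=0.4, extent=6.0)
        binned = grid.mean_counts.sum() * grid.n_frames
        assert binned <= 50 * 30
        assert binned >= 0.9 * 50 * 30  # nearly all atoms fall inside the grid

    def test_uniform_bulk_has_empty_high_density_mask(self):
        """With enough frames no voxel of a uniform system sustains five
        times the bulk expectation."""
        rng = np.random.default_rng(5)
        edge = 10.0
        density = 0.0334
        n = int(density * edge**3)
        anchors = np.array([[1.0, 1, 1], [4.0, 1, 1], [1.0, 4, 1]])
        n_frames = 12_000
        frames = np.empty((n_frames, 3 + n, 3))
        frames[:, :3] = anchors
        frames[:, 3:] = rng.uniform(0, edge, (n_frames, n, 3))
        traj = Trajectory(frames, None, 0.1)
        grid = r.sdf(
            traj, np.arange(3), np.arange(3, 3 + n),
            cell_edge=0.2, cutoff_multiplier=5.0, bulk_density=density, extent=4.0,
        )
        assert grid.high_density_mask.mean() == pytest.approx(0.0, abs=1e-4)

    def test_localized_species_is_masked(self):
        anchors = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0]])
        frames = np.repeat(np.vstack([anchors, [[1.0, 1.0, 1.0]]])[None], 200, axis=0)
        traj = Trajectory(frames, None, 0.1)
        grid = r.sdf(traj, np.arange(3), np.array([3]), cell_edge=0.2, extent=3.0)
        assert grid.high_density_mask.sum() == 1

    def test_degenerate_alignment_rejected(self):
        collinear = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(collinear, collinear)


class TestAngleDistributions:
    def test_replicated_frame_gives_delta_histograms(self, rh1):
        _, coords, topo = rh1
        traj = Trajectory(np.repeat(coords[None], 10, axis=0), None, 0.1)
        ds = r.angle_distribution_set(traj, topo)
        assert len(ds.histograms) == 10
        for centers, freq in ds.histograms.values():
            assert (freq > 0).sum() == 1  # all mass in a single 1-degree bin

    def test_frozen_ring_splits_into_distinct_families(self, rh1):
        """Without ring rotation the ten angle histograms depend on which
        carbon faces which nitrogen: jittered-but-frozen frames give large
        pairwise KS distances for some pairs."""
        _, coords, topo = rh1
        rng = np.random.default_rng(6)
        frames = coords[None] + rng.normal(0, 0.02, (400, *coords.shape))
        ds = r.angle_distribution_set(Trajectory(frames, None, 0.1), topo)
        names = list(ds.samples)
        ks_max = max(
            stats.ks_2samp(ds.samples[a], ds.samples[b]).statistic
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        )
        assert ks_max > 0.5


class TestPlanarityDihedrals:
    def test_ideal_geometry_conventions(self, rh1):
        """Planar bpy reports a 0-degree inter-ring torsion; in-plane
        methyls report 180 degrees."""
        _, coords, topo = rh1
        traj = Trajectory(np.repeat(coords[None], 3, axis=0), None, 0.1)
        ds = r.ring_plane_dihedrals(traj, topo)
        inter = ds.samples["diimine-inter-ring"]
        assert np.abs(inter).max() < 1e-6
        methyl = ds.samples["cp*-methyl-plane"]
        assert np.allclose(methyl, 180.0, atol=1e-6)

    def test_histograms_integrate_to_one(self, rh1_traj, rh1):
        _, _, topo = rh1
        short = Trajectory(rh1_traj.frames[:500], None, rh1_traj.frame_spacing)
        for fn in (r.ring_plane_dihedrals, r.angle_distribution_set):
            ds = fn(short, topo)
            for centers, freq in ds.histograms.values():
                width = centers[1] - centers[0]
                assert freq.sum() * width == pytest.approx(1.0, rel=1e-9)

    def test_nitrogen_pooled_angle_distributions_match(self, rh1_long_traj, rh1):
        """Pooling the five ring-carbon angles per nitrogen gives two
        5e4-sample distributions related by the complex's mirror symmetry;
        their KS distance is small even at desk-scale sampling (this does
        not require the slow ring-rotation coordinate to mix)."""
        from scipy import stats

        _, _, topo = rh1
        ds = r.angle_distribution_set(rh1_long_traj, topo)
        by_n = {}
        for name, v in ds.samples.items():
            by_n.setdefault(name.split("-")[0], []).append(v)
        pools = [np.concatenate(v) for v in by_n.values()]
        assert len(pools) == 2
        assert stats.ks_2samp(pools[0], pools[1]).statistic < 0.02

    def test_methyls_pulled_toward_metal_in_dynamics(self, rh1_traj, rh1):
        _, _, topo = rh1
        ds = r.ring_plane_dihedrals(rh1_traj, topo)
        assert ds.samples["cp*-methyl-plane"].mean() < 179.0
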