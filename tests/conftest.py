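import numpy as np
import pytest

import rhcpff as r
from rhcpff.trajectory import Trajectory


@pytest.fixture(scope="session")
def rh1():
    """(structure, ideal coords, topology) for the neutral Rh(I)-bpy complex."""
    return r.prepared_complex("bpy", "I")


@pytest.fixture(scope="session")
def rh3():
    return r.prepared_complex("bpy", "III")


@pytest.fixture(scope="session")
def rh1_min(rh1):
    _, coords, topo = rh1
    x, trace = r.minimize(topo, coords)
    return x, trace


@pytest.fixture(scope="session")
def rh3_min(rh3):
    _, coords, topo = rh3
    x, trace = r.minimize(topo, coords)
    return x, trace


def _production(topo, x0, steps, interval, seed, drop_fraction=1.0 / 6.0):
    cfg = r.SamplerConfig(steps=steps, seed=seed, snapshot_interval=interval)
    traj = r.run_langevin(topo, x0, cfg)
    drop = int(drop_fraction * traj.n_frames)
    return Trajectory(traj.frames[drop:], None, traj.frame_spacing)


@pytest.fixture(scope="session")
def rh1_traj(rh1, rh1_min):
    """1 ns production (after discarding the first 0.2 ns) of Rh(I)-bpy,
    frames every 0.1 ps -> 1e4 samples per structural descriptor."""
    _, _, topo = rh1
    x0, _ = rh1_min
    return _production(topo, x0, steps=600_000, interval=50, seed=2024)


@pytest.fixture(scope="session")
def rh1_long_traj(rh1, rh1_min):
    """12 ns gas-phase run sampled every 1.2 ps: 1e4 frames for the
    distribution-identity checks and long-run structural means."""
    _, _, topo = rh1
    x0, _ = rh1_min
    cfg = r.SamplerConfig(steps=6_600_000, seed=2026, snapshot_interval=600)
    traj = r.run_langevin(topo, x0, cfg)
    return Trajectory(traj.frames[1000:], None, traj.frame_spacing)


@pytest.fixture(scope="session")
def rh3_traj(rh3, rh3_min):
    """1 ns production (after discard) of Rh(III)-bpy, frames every 0.2 ps."""
    _, _, topo = rh3
    x0, _ = rh3_min
    return _production(topo, x0, steps=600_000, interval=100, seed=2025)
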