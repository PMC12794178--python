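"""Energy minimization, Langevin dynamics with SHAKE, and solvation.

The integrator is a BAOAB-splitting Langevin scheme; constraints on
hydrogen-containing bonds (and the rigid three-site waters, including
their H-H virtual edge) are enforced with SHAKE after each drift and
RATTLE velocity projections after each kick.  Degrees of freedom for the
kinetic temperature subtract the constraint count and net translation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from . import _kernels
from .constants import WATER_NUMBER_DENSITY
from .energy import CompiledSystem
from .terms import AngleTerm, AtomSpec, BondTerm, NonbondedSettings, Topology
from .trajectory import Trajectory
from .fixtures import WATER_ANGLE, WATER_OH, WATER_Q_H, WATER_Q_O, water_geometry


@dataclass
class SamplerConfig:
    """Dynamics settings. timestep in fs, friction in ps^-1, cutoff in A."""

    timestep: float = 2.0
    temperature: float = 300.0
    friction: float = 1.0
    steps: int = 1000
    shake_enabled: bool = True
    shake_tolerance: float = 1e-7
    cutoff: float | None = None
    seed: int = 0
    snapshot_interval: int = 100

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.shake_tolerance <= 0:
            raise ValueError("shake tolerance must be positive")


class SimulationError(RuntimeError):
    pass


def hydrogen_constraints(topology: Topology) -> tuple[np.ndarray, np.ndarray]:
    """(index pairs, target lengths) for all bonds containing hydrogen."""
    idx, d = [], []
    for b in topology.bonds:
        if topology.atoms[b.i].element == "H" or topology.atoms[b.j].element == "H":
            idx.append((b.i, b.j))
            d.append(b.equilibrium)
    return (
        np.array(idx, dtype=np.int64).reshape(-1, 2),
        np.array(d, dtype=float),
    )


def _diagnose_overlap(topology: Topology, coords: np.ndarray) -> str:
    n = topology.n_atoms
    best = (np.inf, 0, 1)
    for i in range(n):
        d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
        if d.size and d.min() < best[0]:
            j = int(np.argmin(d)) + i + 1
            best = (float(d.min()), i, j)
    dmin, i, j = best
    return (
        f"closest pair {topology.atoms[i].name}-{topology.atoms[j].name} "
        f"at {dmin:.3f} A"
    )


def minimize(
    topology: Topology,
    coords: np.ndarray,
    n_steepest: int = 5000,
    n_conjugate: int = 5000,
    settings: NonbondedSettings | None = None,
    box: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Steepest descent followed by conjugate gradient; SHAKE is not
    applied during minimization. Returns (coords, energy trace)."""
    system = CompiledSystem(topology, settings, box)
    x = np.array(coords, dtype=float)
    e, f = system.energy_forces(x)
    if not np.isfinite(e.total):
        raise SimulationError(
            "non-finite starting energy; " + _diagnose_overlap(topology, x)
        )
    trace = [e.total]
    step = 1e-4
    for _ in range(n_steepest):
        fmax = np.abs(f).max()
        if fmax < 1e-8:
            break
        trial = x + step * f / fmax
        e_new, f_new = system.energy_forces(trial)
        if e_new.total < trace[-1]:
            x, f = trial, f_new
            trace.append(e_new.total)
            step = min(step * 1.2, 0.5)
        else:
            step *= 0.5
            if step < 1e-12:
                break

    if n_conjugate > 0:
        shape = x.shape

        def fun(flat: np.ndarray) -> tuple[float, np.ndarray]:
            e, f = system.energy_forces(flat.reshape(shape))
            return e.total, -f.ravel()

        res = optimize.minimize(
            fun,
            x.ravel(),
            jac=True,
            method="CG",
            options={"maxiter": n_conjugate, "gtol": 1e-8},
            callback=lambda xk: trace.append(system.potential(xk.reshape(shape))),
        )
        if res.fun <= trace[0]:
            x = res.x.reshape(shape)
            trace.append(float(res.fun))
    if not np.isfinite(trace[-1]):
        raise SimulationError(
            "minimization diverged; " + _diagnose_overlap(topology, x)
        )
    return x, trace


def _run(
    topology: Topology,
    coords: np.ndarray,
    config: SamplerConfig,
    temp_start: float,
    temp_end: float,
    box: np.ndarray | None,
    velocities: np.ndarray | None,
) -> tuple[Trajectory, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    settings = NonbondedSettings(cutoff=config.cutoff)
    system = CompiledSystem(topology, settings, box)
    masses = topology.masses()
    if config.shake_enabled:
        c_idx, c_d = hydrogen_constraints(topology)
    else:
        c_idx = np.empty((0, 2), dtype=np.int64)
        c_d = np.empty(0)
    if velocities is None:
        velocities = _kernels.maxwell_velocities(masses, temp_start, config.seed + 7919)
        if c_idx.shape[0]:
            _kernels.rattle_velocities(
                np.asarray(coords, dtype=float), velocities, 1.0 / masses, c_idx, 1e-10, 100
            )
    dt_ps = config.timestep * 1e-3
    snaps, temps, epots, xf, vf, status = _kernels.run_langevin(
        np.asarray(coords, dtype=float),
        velocities,
        masses,
        *system.kernel_args(),
        dt_ps,
        config.friction,
        temp_start,
        temp_end,
        config.steps,
        config.snapshot_interval,
        c_idx,
        c_d * c_d,
        config.shake_tolerance,
        config.seed,
    )
    if status != 0:
        raise SimulationError(
            "potential energy diverged during dynamics; "
            + _diagnose_overlap(topology, xf)
        )
    boxes = None if box is None else np.tile(np.asarray(box, float), (len(snaps), 1))
    traj = Trajectory(snaps, boxes, frame_spacing=dt_ps * config.snapshot_interval)
    return traj, temps, epots, xf, vf


def run_langevin(
    topology: Topology,
    coords: np.ndarray,
    config: SamplerConfig,
    box: np.ndarray | None = None,
    velocities: np.ndarray | None = None,
    return_state: bool = False,
):
    """Constant-temperature Langevin trajectory (seeded, reproducible)."""
    traj, temps, epots, xf, vf = _run(
        topology, coords, config, config.temperature, config.temperature, box, velocities
    )
    if return_state:
        return traj, {"temperatures": temps, "potentials": epots, "coords": xf, "velocities": vf}
    return traj


def ramp_schedule(config: SamplerConfig, ramp_steps: int) -> np.ndarray:
    """Thermostat target per step of the heating ramp (0 K at step 0)."""
    if ramp_steps == 0:
        return np.empty(0)
    return config.temperature * np.arange(ramp_steps) / ramp_steps


def heat_then_equilibrate(
    topology: Topology,
    coords: np.ndarray,
    config: SamplerConfig,
    ramp_steps: int | None = None,
    box: np.ndarray | None = None,
    return_state: bool = False,
):
    """Linear 0 -> T heating ramp followed by constant-T equilibration.

    By default the ramp covers 100 ps and the remaining configured steps
    equilibrate at the target temperature."""
    if ramp_steps is None:
        ramp_steps = min(config.steps, int(round(100.0 / (config.timestep * 1e-3))))
    vf = None
    frames, boxes = [], []
    temps_all, epots_all = [], []
    x = coords
    if ramp_steps > 0:
        ramp_cfg = replace(config, steps=ramp_steps)
        traj, temps, epots, x, vf = _run(topology, coords, ramp_cfg, 0.0, config.temperature, box, None)
        frames.append(traj.frames)
        temps_all.append(temps)
        epots_all.append(epots)
        if traj.boxes is not None:
            boxes.append(traj.boxes)
    eq_steps = config.steps - ramp_steps
    if eq_steps > 0:
        eq_cfg = replace(config, steps=eq_steps, seed=config.seed + 1)
        traj, temps, epots, x, vf = _run(
            topology, x, eq_cfg, config.temperature, config.temperature, box, vf
        )
        frames.append(traj.frames)
        temps_all.append(temps)
        epots_all.append(epots)
        if traj.boxes is not None:
            boxes.append(traj.boxes)
    out = Trajectory(
        np.concatenate(frames) if frames else np.empty((0, topology.n_atoms, 3)),
        np.concatenate(boxes) if boxes else None,
        frame_spacing=config.timestep * 1e-3 * config.snapshot_interval,
    )
    if return_state:
        return out, {
            "temperatures": np.concatenate(temps_all) if temps_all else np.empty(0),
            "potentials": np.concatenate(epots_all) if epots_all else np.empty(0),
            "coords": x,
            "velocities": vf,
        }
    return out


# ---------------------------------------------------------------------------
# solvation
# ---------------------------------------------------------------------------


def build_water_topology(n_molecules: int) -> Topology:
    """Topology of n rigid 3-site waters (no solute), molecule-major order."""
    atoms: list[AtomSpec] = []
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    excl: set[tuple[int, int]] = set()
    d_hh = 2.0 * WATER_OH * math.sin(math.radians(WATER_ANGLE / 2.0))
    for w in range(n_molecules):
        o, h1, h2 = 3 * w, 3 * w + 1, 3 * w + 2
        atoms.append(AtomSpec(o, f"OW{w + 1}", "O", "ow", 16.0, WATER_Q_O, 1.7683, 0.152))
        atoms.append(AtomSpec(h1, f"HW{w + 1}a", "H", "hw", 1.008, WATER_Q_H, 0.0, 0.0))
        atoms.append(AtomSpec(h2, f"HW{w + 1}b", "H", "hw", 1.008, WATER_Q_H, 0.0, 0.0))
        bonds.append(BondTerm(o, h1, 553.0, WATER_OH))
        bonds.append(BondTerm(o, h2, 553.0, WATER_OH))
        bonds.append(BondTerm(h1, h2, 553.0, d_hh))
        angles.append(AngleTerm(h1, o, h2, 100.0, WATER_ANGLE))
        excl |= {(o, h1), (o, h2), (h1, h2)}
    return Topology(atoms=atoms, bonds=bonds, angles=angles, exclusions=excl)


def solvate(
    topology: Topology,
    coords: np.ndarray,
    padding: float = 20.0,
    density: float = WATER_NUMBER_DENSITY,
    seed: int = 0,
    cutoff: float = 10.0,
    min_solute_distance: float = 2.4,
) -> tuple[Topology, np.ndarray, np.ndarray]:
    """Embed the complex in a cubic periodic box of rigid 3-site water.

    Waters overlapping the solute (O within min_solute_distance of any
    solute atom) are removed; a net-charged solute receives one free
    chloride counter-ion.  Returns (topology, coordinates, box lengths).
    """
    if padding < cutoff:
        raise ValueError(f"padding {padding} A must be at least the cutoff {cutoff} A")
    from .fixtures import water_box  # local to avoid import cycle at module load

    coords = np.asarray(coords, dtype=float)
    center = coords.mean(axis=0)
    extent = (coords.max(axis=0) - coords.min(axis=0)).max()
    edge = extent + 2.0 * padding
    waters, n_w = water_box(edge, density, seed)
    # shift solute to box center
    solute = coords - center + edge / 2.0
    keep = []
    for w in range(n_w):
        o = waters[3 * w]
        if np.linalg.norm(solute - o, axis=1).min() >= min_solute_distance:
            keep.append(w)

    out = topology.copy()
    n0 = out.n_atoms
    need_ion = abs(out.net_charge) > 0.5
    ion_pos = None
    if need_ion:
        # replace the farthest kept water with a chloride counter-ion
        far = max(keep, key=lambda w: np.linalg.norm(waters[3 * w] - edge / 2.0))
        keep.remove(far)
        ion_pos = waters[3 * far]

    new_coords = [solute]
    idx = n0
    if need_ion:
        out.atoms.append(
            AtomSpec(idx, "CL-", "Cl", "cl", 35.45, -1.0, 1.948, 0.265)
        )
        new_coords.append(ion_pos.reshape(1, 3))
        out.net_charge += -1.0
        idx += 1
    k_oh, hoh = 553.0, WATER_ANGLE
    d_hh = 2.0 * WATER_OH * math.sin(math.radians(hoh / 2.0))
    for w in keep:
        o, h1, h2 = idx, idx + 1, idx + 2
        out.atoms.append(AtomSpec(o, "OW", "O", "ow", 16.0, WATER_Q_O, 1.7683, 0.152))
        out.atoms.append(AtomSpec(h1, "HW1", "H", "hw", 1.008, WATER_Q_H, 0.0, 0.0))
        out.atoms.append(AtomSpec(h2, "HW2", "H", "hw", 1.008, WATER_Q_H, 0.0, 0.0))
        out.bonds.append(BondTerm(o, h1, k_oh, WATER_OH))
        out.bonds.append(BondTerm(o, h2, k_oh, WATER_OH))
        # rigid-water H-H edge, constrained during dynamics like the O-H bonds
        out.bonds.append(BondTerm(h1, h2, k_oh, d_hh))
        out.angles.append(AngleTerm(h1, o, h2, 100.0, hoh))
        out.exclusions |= {(o, h1), (o, h2), (h1, h2)}
        new_coords.append(waters[3 * w : 3 * w + 3])
        idx += 3
    all_coords = np.concatenate(new_coords)
    box = np.array([edge, edge, edge])
    return out, all_coords, box
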