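"""Iterative calibration of equilibrium bond/angle parameters.

Because the sigma-bonded model couples antagonistic terms (N-metal-C
angles push ligands outward, metal-ligand bonds pull them in), the
equilibrium parameter that reproduces an observed mean is generally not
the mean itself.  The loop therefore runs a short simulation, compares
simulated means to target values, and applies damped proportional
feedback on the equilibrium parameters of symmetry-equivalent term
classes in lockstep, until every bond error is below 0.01 A and every
angle error below 1 degree.  Force constants are never altered.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .terms import Topology, angle_value, dihedral_value
from .topology import cp_star_ring_indices
from .trajectory import Trajectory

#: descriptors adjusted when calibrating the Rh(I) complexes
DEFAULT_ADJUSTABLE_RH1 = (
    "M1-Y1", "M1-Y6", "Y1-Y1", "Y6-YC", "YC-YC", "Y6-M1-Y6", "M1-Y6-YC",
)
#: additional descriptors for the chloride-bearing Rh(III) complexes
DEFAULT_ADJUSTABLE_RH3 = DEFAULT_ADJUSTABLE_RH1 + ("M1-Y8", "Y6-M1-Y8")

BOND_THRESHOLD = 0.01  # A
ANGLE_THRESHOLD = 1.0  # degrees


@dataclass
class GeometryTarget:
    """A structural target: type-signature descriptor, value, tolerance.

    Descriptors are dash-separated atom-type signatures ("M1-Y1",
    "Y6-M1-Y6", "Y1-Y1-Y1-c3"); the pseudo-atom "Cp*" denotes the
    unweighted centroid of the five ring carbons ("M1-Cp*",
    "Y6-M1-Cp*").  Units follow the descriptor kind (A or degrees).
    """

    descriptor: str
    value: float
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        self.tokens = tuple(self.descriptor.split("-"))

    @property
    def is_bond(self) -> bool:
        return len(self.tokens) == 2

    @property
    def is_angle(self) -> bool:
        return len(self.tokens) == 3

    @property
    def threshold(self) -> float:
        return BOND_THRESHOLD if self.is_bond else ANGLE_THRESHOLD


@dataclass
class CalibrationReport:
    history: pd.DataFrame
    converged: bool
    iterations: int
    final_errors: dict[str, float] = field(default_factory=dict)


class UnknownDescriptorError(KeyError):
    pass


def _type_list(topology: Topology) -> list[str]:
    return [a.atom_type for a in topology.atoms]


def resolve_descriptor(topology: Topology, descriptor: str) -> list[tuple[int, ...]]:
    """All atom-index tuples matching a descriptor's type signature.

    Centroid descriptors return tuples whose 'Cp*' slot is -1; the
    measurement routines substitute the ring centroid there.
    """
    tokens = tuple(descriptor.split("-"))
    types = _type_list(topology)
    out: list[tuple[int, ...]] = []
    if "Cp*" in tokens:
        ring = cp_star_ring_indices(topology)
        if not ring:
            raise UnknownDescriptorError(descriptor)
        m1 = [i for i, t in enumerate(types) if t == "M1"]
        if tokens == ("M1", "Cp*"):
            return [(m1[0], -1)]
        if len(tokens) == 3 and tokens[1] == "M1" and tokens[2] == "Cp*":
            firsts = [i for i, t in enumerate(types) if t == tokens[0]]
            if not firsts:
                raise UnknownDescriptorError(descriptor)
            return [(i, m1[0], -1) for i in firsts]
        raise UnknownDescriptorError(descriptor)
    if len(tokens) == 2:
        for b in topology.bonds:
            sig = (types[b.i], types[b.j])
            if sig == tokens or sig[::-1] == tokens:
                out.append((b.i, b.j))
    elif len(tokens) == 3:
        for a in topology.angles:
            sig = (types[a.i], types[a.j], types[a.k])
            if sig == tokens or sig[::-1] == tokens:
                out.append((a.i, a.j, a.k))
    elif len(tokens) == 4:
        seen = set()
        for d in topology.dihedrals:
            sig = (types[d.i], types[d.j], types[d.k], types[d.l])
            if sig == tokens or sig[::-1] == tokens:
                key = (d.i, d.j, d.k, d.l)
                if key not in seen and key[::-1] not in seen:
                    seen.add(key)
                    out.append(key)
    if not out:
        raise UnknownDescriptorError(descriptor)
    return out


def _samples(topology: Topology, traj: Trajectory, descriptor: str) -> np.ndarray:
    """Per-frame, per-instance samples pooled into one array.

    Bond-like descriptors give distances (A); angle-like give degrees;
    dihedrals are folded to [0, 180] (mean magnitude convention, so a
    near-planar distribution reports e.g. 174 rather than wrapping).
    """
    instances = resolve_descriptor(topology, descriptor)
    frames = traj.frames
    ring = cp_star_ring_indices(topology)
    vals = []
    for inst in instances:
        if len(inst) == 2:
            i, j = inst
            p = frames[:, ring, :].mean(axis=1) if j == -1 else frames[:, j, :]
            vals.append(np.linalg.norm(frames[:, i, :] - p, axis=1))
        elif len(inst) == 3:
            i, j, k = inst
            pk = frames[:, ring, :].mean(axis=1) if k == -1 else frames[:, k, :]
            u = frames[:, i, :] - frames[:, j, :]
            v = pk - frames[:, j, :]
            c = np.einsum("fa,fa->f", u, v) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
            )
            vals.append(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
        else:
            i, j, k, l = inst
            phi = np.array(
                [abs(dihedral_value(f, i, j, k, l)) for f in frames]
            )
            vals.append(phi)
    return np.concatenate(vals)


def _block_se(x: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean from block averages (correlation-aware)."""
    n = len(x)
    if n < 2 * n_blocks:
        return float(np.std(x) / math.sqrt(max(n, 1)))
    m = n // n_blocks
    blocks = x[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(np.std(blocks, ddof=1) / math.sqrt(n_blocks))


def measure_structural_means(
    trajectory: Trajectory, descriptors: list[str], topology: Topology
) -> pd.DataFrame:
    """Mean, standard deviation and block standard error per descriptor."""
    if trajectory.n_frames < 2:
        raise ValueError("need at least two frames")
    rows = []
    for desc in descriptors:
        x = _samples(topology, trajectory, desc)
        rows.append(
            {
                "descriptor": desc,
                "mean": float(np.mean(x)),
                "std": float(np.std(x)),
                "se": _block_se(x),
                "n_samples": len(x),
            }
        )
    return pd.DataFrame(rows)


def _adjust(topology: Topology, descriptor: str, delta: float) -> None:
    """Shift the equilibrium of every term matching the type signature."""
    tokens = tuple(descriptor.split("-"))
    types = _type_list(topology)
    terms = topology.bonds if len(tokens) == 2 else topology.angles
    for t in terms:
        idx = (t.i, t.j) if len(tokens) == 2 else (t.i, t.j, t.k)
        sig = tuple(types[i] for i in idx)
        if sig == tokens or sig[::-1] == tokens:
            t.equilibrium += delta


def calibrate_equilibria(
    topology: Topology,
    coords: np.ndarray,
    targets: list[GeometryTarget],
    sampler_config=None,
    adjustable: tuple[str, ...] = DEFAULT_ADJUSTABLE_RH1,
    max_iterations: int = 30,
    damping: float = 0.5,
    equilibration_fraction: float = 0.2,
) -> tuple[Topology, CalibrationReport]:
    """Drive simulated structural means onto the targets.

    Each iteration runs a short gas-phase Langevin simulation, measures
    the target descriptors, and (when converged is not yet reached)
    applies new_eq = old_eq - damping * (mean - target) to every
    adjustable descriptor whose error exceeds both its convergence
    threshold and twice the block standard error.  Non-adjustable targets
    (e.g. centroid diagnostics) contribute to the convergence check only.
    Returns the adjusted topology and a per-iteration report; on
    non-convergence the report has converged=False (no exception).
    """
    from .sampler import SamplerConfig, minimize, run_langevin

    config = sampler_config or SamplerConfig(steps=100_000, snapshot_interval=100)
    topo = topology.copy()
    records = []
    converged = False
    x0, _ = minimize(topo, coords, n_steepest=500, n_conjugate=500)
    final_errors: dict[str, float] = {}
    iteration = 0
    for iteration in range(1, max_iterations + 1):
        traj = run_langevin(topo, x0, config)
        skip = int(equilibration_fraction * traj.n_frames)
        prod = Trajectory(traj.frames[skip:], None, traj.frame_spacing)
        table = measure_structural_means(prod, [t.descriptor for t in targets], topo)
        table = table.set_index("descriptor")
        errors = {}
        adjusted_now = {}
        for tgt in targets:
            mean = table.loc[tgt.descriptor, "mean"]
            se = table.loc[tgt.descriptor, "se"]
            err = mean - tgt.value
            errors[tgt.descriptor] = err
            if (
                tgt.descriptor in adjustable
                and abs(err) > tgt.threshold
                and abs(err) > 2.0 * se
            ):
                adjusted_now[tgt.descriptor] = -damping * err
            records.append(
                {
                    "iteration": iteration,
                    "descriptor": tgt.descriptor,
                    "target": tgt.value,
                    "mean": mean,
                    "error": err,
                    "se": se,
                    "adjustment": adjusted_now.get(tgt.descriptor, 0.0),
                }
            )
        final_errors = errors
        ok = all(
            abs(errors[t.descriptor]) < t.threshold for t in targets
        )
        if ok:
            converged = True
            break
        if not adjusted_now:
            # every remaining error is within noise; sample longer (capped)
            # rather than chasing it with parameter moves
            base = sampler_config or SamplerConfig(steps=100_000, snapshot_interval=100)
            new_steps = min(config.steps * 2, 4 * base.steps)
            config = SamplerConfig(
                **{**config.__dict__, "steps": new_steps, "seed": config.seed + 1}
            )
            continue
        for desc, delta in adjusted_now.items():
            _adjust(topo, desc, delta)
        config = SamplerConfig(**{**config.__dict__, "seed": config.seed + 1})

    report = CalibrationReport(
        history=pd.DataFrame(records),
        converged=converged,
        iterations=iteration,
        final_errors=final_errors,
    )
    return topo, report
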