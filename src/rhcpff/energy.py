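"""Evaluation of the additive potential and its analytic gradient.

E = sum_bonds k_b (r - r0)^2 + sum_angles k_th (th - th0)^2
  + sum_dihedrals (V_n / divider) [1 + cos(n phi - gamma)]
  + sum_pairs [ A/R^12 - B/R^6 + q_i q_j / (eps R) ]

Lennard-Jones A/B coefficients come from Lorentz-Berthelot combination of
the per-type R* and well depth; 1-2/1-3 pairs are excluded and 1-4 pairs
divided by the Amber scale factors.
"""
from __future__ import annotations

import math

import numpy as np

from . import _kernels
from .terms import EnergyBreakdown, NonbondedSettings, Topology


class CompiledSystem:
    """Flat-array view of a topology for the numba kernels.

    Build once and reuse for hot paths (minimization, dynamics, scans);
    the one-shot :func:`evaluate_energy` / :func:`evaluate_forces` wrap it.
    """

    def __init__(
        self,
        topology: Topology,
        settings: NonbondedSettings | None = None,
        box: np.ndarray | None = None,
    ):
        settings = settings or NonbondedSettings()
        self.topology = topology
        self.settings = settings
        n = topology.n_atoms

        self.bond_idx = np.array([[b.i, b.j] for b in topology.bonds], dtype=np.int64).reshape(-1, 2)
        self.bond_k = np.array([b.force_constant for b in topology.bonds], dtype=float)
        self.bond_r0 = np.array([b.equilibrium for b in topology.bonds], dtype=float)

        angles = [a for a in topology.angles if a.force_constant != 0.0]
        self.ang_idx = np.array([[a.i, a.j, a.k] for a in angles], dtype=np.int64).reshape(-1, 3)
        self.ang_k = np.array([a.force_constant for a in angles], dtype=float)
        self.ang_t0 = np.radians([a.equilibrium for a in angles]).astype(float)

        dihs = [d for d in topology.dihedrals if d.barrier != 0.0]
        self.dih_idx = np.array([[d.i, d.j, d.k, d.l] for d in dihs], dtype=np.int64).reshape(-1, 4)
        self.dih_v = np.array([d.barrier / d.divider for d in dihs], dtype=float)
        self.dih_n = np.array([d.multiplicity for d in dihs], dtype=float)
        self.dih_g = np.radians([d.phase for d in dihs]).astype(float)

        # nonbonded pair list with exclusions applied and 1-4 pre-scaled
        q = topology.charges()
        radii = np.array([a.vdw_radius for a in topology.atoms])
        eps = np.array([a.vdw_well_depth for a in topology.atoms])
        ke = settings.coulomb_constant / settings.dielectric
        pi, pj, qq, aa, bb = [], [], [], [], []
        excl = topology.exclusions
        p14 = topology.pairs14
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excl:
                    continue
                rmin = radii[i] + radii[j]
                e = math.sqrt(eps[i] * eps[j])
                a6 = rmin**6
                A = e * a6 * a6
                B = 2.0 * e * a6
                Q = ke * q[i] * q[j]
                if (i, j) in p14:
                    Q /= settings.scale_14_elec
                    A /= settings.scale_14_vdw
                    B /= settings.scale_14_vdw
                pi.append(i)
                pj.append(j)
                qq.append(Q)
                aa.append(A)
                bb.append(B)
        self.pair_idx = np.array(list(zip(pi, pj)), dtype=np.int64).reshape(-1, 2)
        self.pair_qq = np.array(qq, dtype=float)
        self.pair_a = np.array(aa, dtype=float)
        self.pair_b = np.array(bb, dtype=float)

        self.set_box(box)

    def set_box(self, box: np.ndarray | None) -> None:
        if box is None:
            self.box = np.zeros(3)
            self.use_pbc = False
        else:
            self.box = np.asarray(box, dtype=float)
            self.use_pbc = True
        cut = self.settings.cutoff
        self.cutoff2 = float(cut * cut) if cut is not None else -1.0

    def kernel_args(self) -> tuple:
        return (
            self.bond_idx,
            self.bond_k,
            self.bond_r0,
            self.ang_idx,
            self.ang_k,
            self.ang_t0,
            self.dih_idx,
            self.dih_v,
            self.dih_n,
            self.dih_g,
            self.pair_idx,
            self.pair_qq,
            self.pair_a,
            self.pair_b,
            self.box,
            self.use_pbc,
            self.cutoff2,
        )

    def _check(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate array has shape {coords.shape}, expected "
                f"({self.topology.n_atoms}, 3)"
            )
        return coords

    def energy_forces(self, coords: np.ndarray) -> tuple[EnergyBreakdown, np.ndarray]:
        coords = self._check(coords)
        eb, ea, ed, ev, ec, f = _kernels.energy_forces(coords, *self.kernel_args())
        return EnergyBreakdown(eb, ea, ed, ev, ec), f

    def energy(self, coords: np.ndarray) -> EnergyBreakdown:
        return self.energy_forces(coords)[0]

    def forces(self, coords: np.ndarray) -> np.ndarray:
        return self.energy_forces(coords)[1]

    def potential(self, coords: np.ndarray) -> float:
        return self.energy(coords).total


def evaluate_energy(
    topology: Topology,
    coords: np.ndarray,
    settings: NonbondedSettings | None = None,
    box: np.ndarray | None = None,
) -> EnergyBreakdown:
    """Per-term-class decomposition of the potential; components sum to total."""
    return CompiledSystem(topology, settings, box).energy(coords)


def evaluate_forces(
    topology: Topology,
    coords: np.ndarray,
    settings: NonbondedSettings | None = None,
    box: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic negative gradient, kcal mol^-1 A^-1, shape (n_atoms, 3)."""
    return CompiledSystem(topology, settings, box).forces(coords)
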