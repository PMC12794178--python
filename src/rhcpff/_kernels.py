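"""Numerical kernels (numba-compiled).

Everything here works on flat float64/int64 arrays prepared by
:mod:`rhcpff.energy`; angles and phases are in radians, distances in
Angstrom, energies in kcal/mol, time in ps.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .constants import ACCEL_UNIT, KB
from ._kernels_energy import energy_forces  # noqa: F401  (re-exported)


@njit(cache=True)
def shake(coords, ref, invmass, c_idx, c_d2, tol, max_iter):
    """Iteratively project coords onto the constraint manifold.

    ref holds the pre-move coordinates whose bond vectors serve as the
    constraint directions. Returns the iteration count (== max_iter on
    failure to converge)."""
    nc = c_idx.shape[0]
    for it in range(max_iter):
        worst = 0.0
        for c in range(nc):
            i = c_idx[c, 0]
            j = c_idx[c, 1]
            rx = coords[i, 0] - coords[j, 0]
            ry = coords[i, 1] - coords[j, 1]
            rz = coords[i, 2] - coords[j, 2]
            r2 = rx * rx + ry * ry + rz * rz
            diff = c_d2[c] - r2
            rel = abs(diff) / c_d2[c]
            if rel > worst:
                worst = rel
            if rel > tol:
                sx = ref[i, 0] - ref[j, 0]
                sy = ref[i, 1] - ref[j, 1]
                sz = ref[i, 2] - ref[j, 2]
                dot = rx * sx + ry * sy + rz * sz
                g = diff / (2.0 * (invmass[i] + invmass[j]) * dot)
                coords[i, 0] += g * invmass[i] * sx
                coords[i, 1] += g * invmass[i] * sy
                coords[i, 2] += g * invmass[i] * sz
                coords[j, 0] -= g * invmass[j] * sx
                coords[j, 1] -= g * invmass[j] * sy
                coords[j, 2] -= g * invmass[j] * sz
        if worst <= tol:
            return it + 1
    return max_iter


@njit(cache=True)
def rattle_velocities(coords, vel, invmass, c_idx, tol, max_iter):
    """Remove velocity components along the constrained bond directions."""
    nc = c_idx.shape[0]
    for _ in range(max_iter):
        worst = 0.0
        for c in range(nc):
            i = c_idx[c, 0]
            j = c_idx[c, 1]
            rx = coords[i, 0] - coords[j, 0]
            ry = coords[i, 1] - coords[j, 1]
            rz = coords[i, 2] - coords[j, 2]
            r2 = rx * rx + ry * ry + rz * rz
            vx = vel[i, 0] - vel[j, 0]
            vy = vel[i, 1] - vel[j, 1]
            vz = vel[i, 2] - vel[j, 2]
            rv = rx * vx + ry * vy + rz * vz
            g = rv / ((invmass[i] + invmass[j]) * r2)
            crit = abs(rv) / np.sqrt(r2)
            if crit > worst:
                worst = crit
            vel[i, 0] -= g * invmass[i] * rx
            vel[i, 1] -= g * invmass[i] * ry
            vel[i, 2] -= g * invmass[i] * rz
            vel[j, 0] += g * invmass[j] * rx
            vel[j, 1] += g * invmass[j] * ry
            vel[j, 2] += g * invmass[j] * rz
        if worst < tol:
            break
    return vel


@njit(cache=True)
def run_langevin(
    coords,
    vel,
    masses,
    bond_idx,
    bond_k,
    bond_r0,
    ang_idx,
    ang_k,
    ang_t0,
    dih_idx,
    dih_v,
    dih_n,
    dih_g,
    pair_idx,
    pair_qq,
    pair_a,
    pair_b,
    box,
    use_pbc,
    cutoff2,
    dt,
    friction,
    temp_start,
    temp_end,
    n_steps,
    snapshot_interval,
    c_idx,
    c_d2,
    shake_tol,
    seed,
):
    """BAOAB Langevin integrator with optional SHAKE/RATTLE constraints.

    Returns (snapshots, temperatures, potential_energies, final_coords,
    final_velocities, status) where status is 0 on success and 1 if the
    potential energy diverged (> 1e6 kcal/mol).
    Temperatures/energies are recorded at the snapshot interval.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    nc = c_idx.shape[0]
    invmass = 1.0 / masses
    x = coords.copy()
    v = vel.copy()

    n_snap = n_steps // snapshot_interval
    snaps = np.zeros((n_snap, n, 3))
    temps = np.zeros(n_snap)
    epots = np.zeros(n_snap)

    dof = 3 * n - 3 - nc
    if dof < 1:
        dof = 1

    eb, ea, ed, ev, ec, f = energy_forces(
        x, bond_idx, bond_k, bond_r0, ang_idx, ang_k, ang_t0,
        dih_idx, dih_v, dih_n, dih_g, pair_idx, pair_qq, pair_a, pair_b,
        box, use_pbc, cutoff2,
    )
    half = 0.5 * dt
    status = 0
    isnap = 0
    for step in range(n_steps):
        frac = step / n_steps if n_steps > 0 else 1.0
        target_t = temp_start + (temp_end - temp_start) * frac
        # B: half kick
        for i in range(n):
            for a in range(3):
                v[i, a] += half * f[i, a] * ACCEL_UNIT * invmass[i]
        if nc > 0:
            rattle_velocities(x, v, invmass, c_idx, 1e-10, 50)
        # A: half drift (+ SHAKE)
        if nc > 0:
            ref = x.copy()
            xn = x + half * v
            shake(xn, ref, invmass, c_idx, c_d2, shake_tol, 500)
            for i in range(n):
                for a in range(3):
                    v[i, a] = (xn[i, a] - x[i, a]) / half
            x = xn
        else:
            x = x + half * v
        # O: thermostat
        if friction > 0.0:
            c1 = np.exp(-friction * dt)
            for i in range(n):
                c2 = np.sqrt(KB * target_t * ACCEL_UNIT * invmass[i] * (1.0 - c1 * c1))
                for a in range(3):
                    v[i, a] = c1 * v[i, a] + c2 * np.random.standard_normal()
            if nc > 0:
                rattle_velocities(x, v, invmass, c_idx, 1e-10, 50)
        # A: half drift (+ SHAKE)
        if nc > 0:
            ref = x.copy()
            xn = x + half * v
            shake(xn, ref, invmass, c_idx, c_d2, shake_tol, 500)
            for i in range(n):
                for a in range(3):
                    v[i, a] = (xn[i, a] - x[i, a]) / half
            x = xn
        else:
            x = x + half * v
        # force refresh + B: half kick
        eb, ea, ed, ev, ec, f = energy_forces(
            x, bond_idx, bond_k, bond_r0, ang_idx, ang_k, ang_t0,
            dih_idx, dih_v, dih_n, dih_g, pair_idx, pair_qq, pair_a, pair_b,
            box, use_pbc, cutoff2,
        )
        epot = eb + ea + ed + ev + ec
        if epot > 1e6 or not np.isfinite(epot):
            status = 1
            break
        for i in range(n):
            for a in range(3):
                v[i, a] += half * f[i, a] * ACCEL_UNIT * invmass[i]
        if nc > 0:
            rattle_velocities(x, v, invmass, c_idx, 1e-10, 50)

        if (step + 1) % snapshot_interval == 0 and isnap < n_snap:
            ke = 0.0
            for i in range(n):
                ke += 0.5 * masses[i] * (
                    v[i, 0] * v[i, 0] + v[i, 1] * v[i, 1] + v[i, 2] * v[i, 2]
                )
            ke /= ACCEL_UNIT  # kcal/mol
            snaps[isnap] = x
            temps[isnap] = 2.0 * ke / (dof * KB)
            epots[isnap] = epot
            isnap += 1

    return snaps[:isnap], temps[:isnap], epots[:isnap], x, v, status


@njit(cache=True)
def maxwell_velocities(masses, temperature, seed):
    np.random.seed(seed)
    n = masses.shape[0]
    v = np.zeros((n, 3))
    if temperature <= 0.0:
        return v
    for i in range(n):
        s = np.sqrt(KB * temperature * ACCEL_UNIT / masses[i])
        for a in range(3):
            v[i, a] = s * np.random.standard_normal()
    # remove net momentum
    ptot = np.zeros(3)
    mtot = 0.0
    for i in range(n):
        mtot += masses[i]
        for a in range(3):
            ptot[a] += masses[i] * v[i, a]
    for i in range(n):
        for a in range(3):
            v[i, a] -= ptot[a] / mtot
    return v
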