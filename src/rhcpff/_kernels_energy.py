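"""Allocation-free force/energy kernel (numba)."""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def energy_forces(
    coords,
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
):
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    e_bond = 0.0
    e_angle = 0.0
    e_dih = 0.0
    e_vdw = 0.0
    e_coul = 0.0
    bx = box[0]
    by = box[1]
    bz = box[2]

    for t in range(bond_idx.shape[0]):
        i = bond_idx[t, 0]
        j = bond_idx[t, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        if use_pbc:
            dx -= bx * np.round(dx / bx)
            dy -= by * np.round(dy / by)
            dz -= bz * np.round(dz / bz)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[t]
        e_bond += bond_k[t] * dr * dr
        fmag = -2.0 * bond_k[t] * dr / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    for t in range(ang_idx.shape[0]):
        i = ang_idx[t, 0]
        j = ang_idx[t, 1]
        k = ang_idx[t, 2]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[k, 0] - coords[j, 0]
        vy = coords[k, 1] - coords[j, 1]
        vz = coords[k, 2] - coords[j, 2]
        if use_pbc:
            ux -= bx * np.round(ux / bx)
            uy -= by * np.round(uy / by)
            uz -= bz * np.round(uz / bz)
            vx -= bx * np.round(vx / bx)
            vy -= by * np.round(vy / by)
            vz -= bz * np.round(vz / bz)
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0 - 1e-12:
            c = 1.0 - 1e-12
        if c < -1.0 + 1e-12:
            c = -1.0 + 1e-12
        theta = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        dth = theta - ang_t0[t]
        e_angle += ang_k[t] * dth * dth
        coef = 2.0 * ang_k[t] * dth / s
        dcix = (vx / nv - c * ux / nu) / nu
        dciy = (vy / nv - c * uy / nu) / nu
        dciz = (vz / nv - c * uz / nu) / nu
        dckx = (ux / nu - c * vx / nv) / nv
        dcky = (uy / nu - c * vy / nv) / nv
        dckz = (uz / nu - c * vz / nv) / nv
        forces[i, 0] += coef * dcix
        forces[i, 1] += coef * dciy
        forces[i, 2] += coef * dciz
        forces[k, 0] += coef * dckx
        forces[k, 1] += coef * dcky
        forces[k, 2] += coef * dckz
        forces[j, 0] -= coef * (dcix + dckx)
        forces[j, 1] -= coef * (dciy + dcky)
        forces[j, 2] -= coef * (dciz + dckz)

    for t in range(dih_idx.shape[0]):
        i = dih_idx[t, 0]
        j = dih_idx[t, 1]
        k = dih_idx[t, 2]
        l = dih_idx[t, 3]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        b3x = coords[l, 0] - coords[k, 0]
        b3y = coords[l, 1] - coords[k, 1]
        b3z = coords[l, 2] - coords[k, 2]
        if use_pbc:
            b1x -= bx * np.round(b1x / bx)
            b1y -= by * np.round(b1y / by)
            b1z -= bz * np.round(b1z / bz)
            b2x -= bx * np.round(b2x / bx)
            b2y -= by * np.round(b2y / by)
            b2z -= bz * np.round(b2z / bz)
            b3x -= bx * np.round(b3x / bx)
            b3y -= by * np.round(b3y / by)
            b3z -= bz * np.round(b3z / bz)
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-18 or n2sq < 1e-18:
            continue
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx = n1x * n2x + n1y * n2y + n1z * n2z
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        my = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        phi = np.arctan2(my, mx)
        e_dih += dih_v[t] * (1.0 + np.cos(dih_n[t] * phi - dih_g[t]))
        dedphi = -dih_v[t] * dih_n[t] * np.sin(dih_n[t] * phi - dih_g[t])
        gi = dedphi * nb2 / n1sq
        gl = -dedphi * nb2 / n2sq
        fix = gi * n1x
        fiy = gi * n1y
        fiz = gi * n1z
        flx = gl * n2x
        fly = gl * n2y
        flz = gl * n2z
        tm = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        tn = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[l, 0] += flx
        forces[l, 1] += fly
        forces[l, 2] += flz
        fjx = -fix - tm * fix + tn * flx
        fjy = -fiy - tm * fiy + tn * fly
        fjz = -fiz - tm * fiz + tn * flz
        forces[j, 0] += fjx
        forces[j, 1] += fjy
        forces[j, 2] += fjz
        forces[k, 0] += -flx + tm * fix - tn * flx
        forces[k, 1] += -fly + tm * fiy - tn * fly
        forces[k, 2] += -flz + tm * fiz - tn * flz

    for t in range(pair_idx.shape[0]):
        i = pair_idx[t, 0]
        j = pair_idx[t, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        if use_pbc:
            dx -= bx * np.round(dx / bx)
            dy -= by * np.round(dy / by)
            dz -= bz * np.round(dz / bz)
        r2 = dx * dx + dy * dy + dz * dz
        if cutoff2 > 0.0 and r2 > cutoff2:
            continue
        inv2 = 1.0 / r2
        inv6 = inv2 * inv2 * inv2
        r = np.sqrt(r2)
        e_vdw += pair_a[t] * inv6 * inv6 - pair_b[t] * inv6
        e_coul += pair_qq[t] / r
        fmag = (
            12.0 * pair_a[t] * inv6 * inv6 - 6.0 * pair_b[t] * inv6
        ) * inv2 + pair_qq[t] / (r2 * r)
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    return e_bond, e_angle, e_dih, e_vdw, e_coul, forces
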