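"""Numba kernels for the Langevin propagator (BAOAB splitting).

All arithmetic is in the package unit system (A, kcal/mol, amu, ps).
The kernels are deliberately monolithic: one jitted function advances a
replica for its whole step budget so the Python interpreter never sits
in the inner loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .constants import ACCEL_CONVERSION, COULOMB_CONSTANT, PAIR_DIELECTRIC


@njit(cache=True)
def _grid_eval(values, ox, oy, oz, hx, hy, hz, x, y, z):
    """Quadratic B-spline value and gradient of one grid at one point.

    Points outside the interpolable interior are clamped to it (the
    hard walls keep particles inside; clamping only matters transiently).
    """
    nx, ny, nz = values.shape
    ux = (x - ox) / hx
    uy = (y - oy) / hy
    uz = (z - oz) / hz
    if ux < 0.5:
        ux = 0.5
    elif ux > nx - 1.5:
        ux = nx - 1.5
    if uy < 0.5:
        uy = 0.5
    elif uy > ny - 1.5:
        uy = ny - 1.5
    if uz < 0.5:
        uz = 0.5
    elif uz > nz - 1.5:
        uz = nz - 1.5
    ix = int(round(ux))
    iy = int(round(uy))
    iz = int(round(uz))
    if ix < 1:
        ix = 1
    elif ix > nx - 2:
        ix = nx - 2
    if iy < 1:
        iy = 1
    elif iy > ny - 2:
        iy = ny - 2
    if iz < 1:
        iz = 1
    elif iz > nz - 2:
        iz = nz - 2
    sx = ux - ix
    sy = uy - iy
    sz = uz - iz

    wx0 = 0.5 * (0.5 - sx) ** 2
    wx1 = 0.75 - sx * sx
    wx2 = 0.5 * (0.5 + sx) ** 2
    dx0 = sx - 0.5
    dx1 = -2.0 * sx
    dx2 = sx + 0.5
    wy0 = 0.5 * (0.5 - sy) ** 2
    wy1 = 0.75 - sy * sy
    wy2 = 0.5 * (0.5 + sy) ** 2
    dy0 = sy - 0.5
    dy1 = -2.0 * sy
    dy2 = sy + 0.5
    wz0 = 0.5 * (0.5 - sz) ** 2
    wz1 = 0.75 - sz * sz
    wz2 = 0.5 * (0.5 + sz) ** 2
    dz0 = sz - 0.5
    dz1 = -2.0 * sz
    dz2 = sz + 0.5

    val = 0.0
    gx = 0.0
    gy = 0.0
    gz = 0.0
    wxs = (wx0, wx1, wx2)
    dxs = (dx0, dx1, dx2)
    wys = (wy0, wy1, wy2)
    dys = (dy0, dy1, dy2)
    wzs = (wz0, wz1, wz2)
    dzs = (dz0, dz1, dz2)
    for a in range(3):
        for b in range(3):
            for c in range(3):
                v = values[ix + a - 1, iy + b - 1, iz + c - 1]
                val += v * wxs[a] * wys[b] * wzs[c]
                gx += v * dxs[a] * wys[b] * wzs[c]
                gy += v * wxs[a] * dys[b] * wzs[c]
                gz += v * wxs[a] * wys[b] * dzs[c]
    return val, gx / hx, gy / hy, gz / hz


@njit(cache=True)
def compute_forces(
    pos,
    forces,
    q,
    eps,
    rmin_pair,
    pairs_on,
    pair_rc2,
    pair_shift,
    fence_pos,
    fence_q,
    fence_lj,
    fence_rmin,
    fence_eps,
    fence_kappa,
    fence_rc2,
    fence_shift,
    kp,
    zplane,
    kw,
    xlo,
    xhi,
    ylo,
    yhi,
    walls_on,
    corral_x,
    corral_on,
    ext_amp,
    ext_x0,
    ext_sigma,
    use_core,
    core_vals,
    core_meta,
    use_phix,
    phix_vals,
    phix_meta,
):
    """Fill ``forces`` in place; returns potential energy (kcal/mol)."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    energy = 0.0
    qqfac = COULOMB_CONSTANT * q * q / PAIR_DIELECTRIC

    if pairs_on:
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if pair_rc2 > 0.0 and r2 > pair_rc2:
                    continue
                r = np.sqrt(r2)
                sr6 = (rmin_pair * rmin_pair / r2) ** 3
                energy += eps * (sr6 * sr6 - 2.0 * sr6) + qqfac / r - pair_shift
                fmag = 12.0 * eps * (sr6 * sr6 - sr6) / r + qqfac / r2
                fx = fmag * dx / r
                fy = fmag * dy / r
                fz = fmag * dz / r
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz

    nf = fence_pos.shape[0]
    for i in range(n):
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]

        for k in range(nf):
            dx = x - fence_pos[k, 0]
            dy = y - fence_pos[k, 1]
            dz = z - fence_pos[k, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if fence_rc2 > 0.0 and r2 > fence_rc2:
                continue
            r = np.sqrt(r2)
            fmag = 0.0
            if fence_lj:
                sr6 = (fence_rmin[k] * fence_rmin[k] / r2) ** 3
                energy += fence_eps * (sr6 * sr6 - 2.0 * sr6)
                fmag += 12.0 * fence_eps * (sr6 * sr6 - sr6) / r
            if fence_q[k] != 0.0:
                pref = COULOMB_CONSTANT * q * fence_q[k] / PAIR_DIELECTRIC
                u = pref * np.exp(-fence_kappa * r) / r
                energy += u
                fmag += u * (fence_kappa * r + 1.0) / r
            energy -= fence_shift[k]
            if fmag != 0.0:
                forces[i, 0] += fmag * dx / r
                forces[i, 1] += fmag * dy / r
                forces[i, 2] += fmag * dz / r

        # planar restraint (k*dz^2, no 1/2)
        dzp = z - zplane
        energy += kp * dzp * dzp
        forces[i, 2] += -2.0 * kp * dzp

        if walls_on:
            if x < xlo:
                d = x - xlo
                energy += kw * d * d
                forces[i, 0] += -2.0 * kw * d
            elif x > xhi:
                d = x - xhi
                energy += kw * d * d
                forces[i, 0] += -2.0 * kw * d
            if y < ylo:
                d = y - ylo
                energy += kw * d * d
                forces[i, 1] += -2.0 * kw * d
            elif y > yhi:
                d = y - yhi
                energy += kw * d * d
                forces[i, 1] += -2.0 * kw * d

        if corral_on and x > corral_x:
            d = x - corral_x
            energy += kw * d * d
            forces[i, 0] += -2.0 * kw * d

        if ext_amp != 0.0:
            arg = (x - ext_x0) / ext_sigma
            u = ext_amp * np.exp(-0.5 * arg * arg)
            energy += u
            forces[i, 0] += u * arg / ext_sigma

        if use_core:
            val, gx, gy, gz = _grid_eval(
                core_vals,
                core_meta[0],
                core_meta[1],
                core_meta[2],
                core_meta[3],
                core_meta[4],
                core_meta[5],
                x,
                y,
                z,
            )
            energy += val
            forces[i, 0] -= gx
            forces[i, 1] -= gy
            forces[i, 2] -= gz
        if use_phix:
            val, gx, gy, gz = _grid_eval(
                phix_vals,
                phix_meta[0],
                phix_meta[1],
                phix_meta[2],
                phix_meta[3],
                phix_meta[4],
                phix_meta[5],
                x,
                y,
                z,
            )
            energy += q * val
            forces[i, 0] -= q * gx
            forces[i, 1] -= q * gy
            forces[i, 2] -= q * gz
    return energy


@njit(cache=True)
def ld_run(
    pos,
    vel,
    n_steps,
    dt,
    gamma,
    kT,
    mass,
    q,
    eps,
    rmin_pair,
    pairs_on,
    pair_rc2,
    pair_shift,
    fence_pos,
    fence_q,
    fence_lj,
    fence_rmin,
    fence_eps,
    fence_kappa,
    fence_rc2,
    fence_shift,
    kp,
    zplane,
    kw,
    xlo,
    xhi,
    ylo,
    yhi,
    walls_on,
    corral_x,
    corral_on,
    ext_amp,
    ext_x0,
    ext_sigma,
    use_core,
    core_vals,
    core_meta,
    use_phix,
    phix_vals,
    phix_meta,
    snapshot_every,
    seed,
    out_pos,
    out_vel,
):
    """BAOAB Langevin propagation of one replica.

    pos/vel are modified in place; snapshots (including the initial
    state as frame 0) go to out_pos/out_vel.  Returns the number of
    frames written, or -1 on non-finite forces (instability).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    accel_fac = ACCEL_CONVERSION / mass
    c1 = np.exp(-gamma * dt)
    # thermal velocity scale: sqrt(kT/m) in A/ps with kT in kcal/mol
    sigma_v = np.sqrt(kT * ACCEL_CONVERSION / mass * (1.0 - c1 * c1))

    compute_forces(
        pos, forces, q, eps, rmin_pair, pairs_on, pair_rc2, pair_shift,
        fence_pos, fence_q, fence_lj, fence_rmin, fence_eps, fence_kappa,
        fence_rc2, fence_shift,
        kp, zplane, kw, xlo, xhi, ylo, yhi, walls_on,
        corral_x, corral_on, ext_amp, ext_x0, ext_sigma,
        use_core, core_vals, core_meta, use_phix, phix_vals, phix_meta,
    )

    frame = 0
    if out_pos.shape[0] > 0:
        for i in range(n):
            for d in range(3):
                out_pos[0, i, d] = pos[i, d]
                out_vel[0, i, d] = vel[i, d]
        frame = 1

    half_dt = 0.5 * dt
    for step in range(n_steps):
        # B: half kick
        for i in range(n):
            for d in range(3):
                vel[i, d] += half_dt * forces[i, d] * accel_fac
        # A: half drift
        for i in range(n):
            for d in range(3):
                pos[i, d] += half_dt * vel[i, d]
        # O: Ornstein-Uhlenbeck
        if gamma > 0.0:
            for i in range(n):
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + sigma_v * np.random.standard_normal()
        # A: half drift
        for i in range(n):
            for d in range(3):
                pos[i, d] += half_dt * vel[i, d]
        # B: half kick with fresh forces
        e = compute_forces(
            pos, forces, q, eps, rmin_pair, pairs_on, pair_rc2, pair_shift,
            fence_pos, fence_q, fence_lj, fence_rmin, fence_eps, fence_kappa,
            fence_rc2, fence_shift,
            kp, zplane, kw, xlo, xhi, ylo, yhi, walls_on,
            corral_x, corral_on, ext_amp, ext_x0, ext_sigma,
            use_core, core_vals, core_meta, use_phix, phix_vals, phix_meta,
        )
        if not np.isfinite(e):
            return -1
        for i in range(n):
            for d in range(3):
                vel[i, d] += half_dt * forces[i, d] * accel_fac

        if snapshot_every > 0 and (step + 1) % snapshot_every == 0 and frame < out_pos.shape[0]:
            for i in range(n):
                for d in range(3):
                    out_pos[frame, i, d] = pos[i, d]
                    out_vel[frame, i, d] = vel[i, d]
            frame += 1
    return frame
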