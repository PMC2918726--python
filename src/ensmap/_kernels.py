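"""Numba kernels for grid accumulation, pose scoring and minimization.

These are performance back-ends for :mod:`ensmap.probe_mapping`; all
scientific definitions (energy model, capping, truncation) live there and
in :mod:`ensmap.probes`.  Kernels are single-threaded and deterministic.

Units: Angstrom, kJ/mol, elementary charges.  The electrostatic channel
stores potential per unit probe charge; ``elec_pref`` below is the pair
prefactor already divided by the distance-dependent dielectric's leading
coefficient (eps(r) = 4r  =>  E = K q q / (4 r^2)).
"""

from __future__ import annotations

import numpy as np
from numba import njit

R_CLAMP = 2.0  # A: electrostatics distance clamp (inside any vdW contact)


@njit(cache=False)
def _lj(sigma, eps, r2, cap):
    if eps == 0.0:
        return 0.0
    s2 = sigma * sigma / r2
    s6 = s2 * s2 * s2
    e = 4.0 * eps * (s6 * s6 - s6)
    if e > cap:
        return cap
    return e


@njit(cache=False)
def accumulate_grid(
    lj_channels,   # (C, nx, ny, nz) float64, modified in place
    elec,          # (nx, ny, nz) float64, modified in place
    origin,        # (3,)
    spacing,       # float
    rec_xyz,       # (R, 3)
    rec_q,         # (R,)
    sigma_cr,      # (C, R) combined sigma per channel class x receptor atom
    eps_cr,        # (C, R)
    cutoff,
    cap,
    coulomb_quarter,  # K/4
):
    C = lj_channels.shape[0]
    nx, ny, nz = elec.shape
    cutoff2 = cutoff * cutoff
    span = int(cutoff / spacing) + 1
    for i in range(rec_xyz.shape[0]):
        ax = (rec_xyz[i, 0] - origin[0]) / spacing
        ay = (rec_xyz[i, 1] - origin[1]) / spacing
        az = (rec_xyz[i, 2] - origin[2]) / spacing
        x0 = max(0, int(ax) - span)
        x1 = min(nx - 1, int(ax) + span + 1)
        y0 = max(0, int(ay) - span)
        y1 = min(ny - 1, int(ay) + span + 1)
        z0 = max(0, int(az) - span)
        z1 = min(nz - 1, int(az) + span + 1)
        for gx in range(x0, x1 + 1):
            dx = (gx - ax) * spacing
            for gy in range(y0, y1 + 1):
                dy = (gy - ay) * spacing
                for gz in range(z0, z1 + 1):
                    dz = (gz - az) * spacing
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 > cutoff2:
                        continue
                    for c in range(C):
                        lj_channels[c, gx, gy, gz] += _lj(
                            sigma_cr[c, i], eps_cr[c, i], max(r2, 1e-12), cap
                        )
                    r = np.sqrt(r2)
                    if r < R_CLAMP:
                        r = R_CLAMP
                    elec[gx, gy, gz] += coulomb_quarter * rec_q[i] / (r * r)


@njit(cache=False)
def _trilinear(field, x, y, z):
    # caller guarantees 0 <= x <= nx-1 etc.
    ix = int(x)
    iy = int(y)
    iz = int(z)
    if ix >= field.shape[0] - 1:
        ix = field.shape[0] - 2
    if iy >= field.shape[1] - 1:
        iy = field.shape[1] - 2
    if iz >= field.shape[2] - 1:
        iz = field.shape[2] - 2
    fx = x - ix
    fy = y - iy
    fz = z - iz
    c00 = field[ix, iy, iz] * (1 - fx) + field[ix + 1, iy, iz] * fx
    c10 = field[ix, iy + 1, iz] * (1 - fx) + field[ix + 1, iy + 1, iz] * fx
    c01 = field[ix, iy, iz + 1] * (1 - fx) + field[ix + 1, iy, iz + 1] * fx
    c11 = field[ix, iy + 1, iz + 1] * (1 - fx) + field[ix + 1, iy + 1, iz + 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


EXCLUDED = 1.0e30  # sentinel for poses pruned by the top-K lower bound


@njit(cache=False)
def _trilinear4(field4, c, x, y, z):
    ix = int(x)
    iy = int(y)
    iz = int(z)
    if ix >= field4.shape[1] - 1:
        ix = field4.shape[1] - 2
    if iy >= field4.shape[2] - 1:
        iy = field4.shape[2] - 2
    if iz >= field4.shape[3] - 1:
        iz = field4.shape[3] - 2
    fx = x - ix
    fy = y - iy
    fz = z - iz
    c00 = field4[c, ix, iy, iz] * (1 - fx) + field4[c, ix + 1, iy, iz] * fx
    c10 = field4[c, ix, iy + 1, iz] * (1 - fx) + field4[c, ix + 1, iy + 1, iz] * fx
    c01 = field4[c, ix, iy, iz + 1] * (1 - fx) + field4[c, ix + 1, iy, iz + 1] * fx
    c11 = (
        field4[c, ix, iy + 1, iz + 1] * (1 - fx)
        + field4[c, ix + 1, iy + 1, iz + 1] * fx
    )
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(cache=False)
def score_rotations(
    lj_channels,  # (C, nx, ny, nz) sub-grid fields
    elec,         # (nx, ny, nz)
    rot_bodies,   # (K, A, 3): probe body coords per rotation, sub-grid units
    cls_idx,      # (A,) channel index per probe atom
    charges,      # (A,)
    cand_idx,     # (M, 3) float64 sub-grid indices of candidate centroids
    suffix_lb,    # (A + 1,) lower bound of contributions of atoms a..A-1 (<= 0)
    threshold,    # prune poses provably above this energy (+inf disables)
    out,          # (K, M) float64
):
    """Interpolated pose energies, with sound top-K pruning.

    Points outside the box contribute exactly zero (the box extends at
    least one nonbonded cutoff beyond every receptor atom, so the field
    vanishes there).  A pose is abandoned — marked ``EXCLUDED`` — as soon
    as its partial energy plus the remaining atoms' global lower bound
    exceeds ``threshold``: its true energy then provably exceeds the
    current K-th best, so it cannot enter the retained set.
    """
    K, A, _ = rot_bodies.shape
    M = cand_idx.shape[0]
    nx, ny, nz = elec.shape
    for k in range(K):
        for m in range(M):
            e = 0.0
            for a in range(A):
                if e + suffix_lb[a] > threshold:
                    e = EXCLUDED
                    break
                x = cand_idx[m, 0] + rot_bodies[k, a, 0]
                y = cand_idx[m, 1] + rot_bodies[k, a, 1]
                z = cand_idx[m, 2] + rot_bodies[k, a, 2]
                if (
                    x < 0.0
                    or y < 0.0
                    or z < 0.0
                    or x > nx - 1
                    or y > ny - 1
                    or z > nz - 1
                ):
                    continue
                e += _trilinear4(lj_channels, cls_idx[a], x, y, z)
                if charges[a] != 0.0:
                    e += charges[a] * _trilinear(elec, x, y, z)
            out[k, m] = e


@njit(cache=False)
def _quat_to_mat(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1 - 2 * (y * y + z * z)
    R[0, 1] = 2 * (x * y - w * z)
    R[0, 2] = 2 * (x * z + w * y)
    R[1, 0] = 2 * (x * y + w * z)
    R[1, 1] = 1 - 2 * (x * x + z * z)
    R[1, 2] = 2 * (y * z - w * x)
    R[2, 0] = 2 * (x * z - w * y)
    R[2, 1] = 2 * (y * z + w * x)
    R[2, 2] = 1 - 2 * (x * x + y * y)


@njit(cache=False)
def _quat_mul(a, b, out):
    out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]


@njit(cache=False)
def _pose_energy_grad(
    body, rot, trans, rec_xyz, sigma_ar, eps_ar, qpref_ar, cutoff2, cap, grad
):
    """Direct pair-sum energy and per-atom Cartesian gradient (in place)."""
    A = body.shape[0]
    R = rec_xyz.shape[0]
    e = 0.0
    for a in range(A):
        px = rot[0, 0] * body[a, 0] + rot[0, 1] * body[a, 1] + rot[0, 2] * body[a, 2] + trans[0]
        py = rot[1, 0] * body[a, 0] + rot[1, 1] * body[a, 1] + rot[1, 2] * body[a, 2] + trans[1]
        pz = rot[2, 0] * body[a, 0] + rot[2, 1] * body[a, 1] + rot[2, 2] * body[a, 2] + trans[2]
        gx = 0.0
        gy = 0.0
        gz = 0.0
        for i in range(R):
            dx = px - rec_xyz[i, 0]
            dy = py - rec_xyz[i, 1]
            dz = pz - rec_xyz[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > cutoff2:
                continue
            if r2 < 1e-12:
                r2 = 1e-12
            sigma = sigma_ar[a, i]
            eps = eps_ar[a, i]
            if eps > 0.0:
                s2 = sigma * sigma / r2
                s6 = s2 * s2 * s2
                elj = 4.0 * eps * (s6 * s6 - s6)
                if elj > cap:
                    e += cap  # flat cap: no gradient
                else:
                    e += elj
                    dedr_r = 4.0 * eps * (-12.0 * s6 * s6 + 6.0 * s6) / r2
                    gx += dedr_r * dx
                    gy += dedr_r * dy
                    gz += dedr_r * dz
            qp = qpref_ar[a, i]
            if qp != 0.0:
                r = np.sqrt(r2)
                if r < R_CLAMP:
                    e += qp / (R_CLAMP * R_CLAMP)  # clamped: no gradient
                else:
                    e += qp / r2
                    dedr_r = -2.0 * qp / (r2 * r2)
                    gx += dedr_r * dx
                    gy += dedr_r * dy
                    gz += dedr_r * dz
        grad[a, 0] = gx
        grad[a, 1] = gy
        grad[a, 2] = gz
        e = e + 0.0
    return e


@njit(cache=False)
def _pose_energy_only(body, rot, trans, rec_xyz, sigma_ar, eps_ar, qpref_ar, cutoff2, cap):
    A = body.shape[0]
    R = rec_xyz.shape[0]
    e = 0.0
    for a in range(A):
        px = rot[0, 0] * body[a, 0] + rot[0, 1] * body[a, 1] + rot[0, 2] * body[a, 2] + trans[0]
        py = rot[1, 0] * body[a, 0] + rot[1, 1] * body[a, 1] + rot[1, 2] * body[a, 2] + trans[1]
        pz = rot[2, 0] * body[a, 0] + rot[2, 1] * body[a, 1] + rot[2, 2] * body[a, 2] + trans[2]
        for i in range(R):
            dx = px - rec_xyz[i, 0]
            dy = py - rec_xyz[i, 1]
            dz = pz - rec_xyz[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > cutoff2:
                continue
            if r2 < 1e-12:
                r2 = 1e-12
            e += _lj(sigma_ar[a, i], eps_ar[a, i], r2, cap)
            qp = qpref_ar[a, i]
            if qp != 0.0:
                r2c = r2 if r2 > R_CLAMP * R_CLAMP else R_CLAMP * R_CLAMP
                e += qp / r2c
    return e


@njit(cache=False)
def minimize_batch(
    body,        # (A, 3)
    quats,       # (B, 4) w,x,y,z - modified in place
    trans,       # (B, 3) - modified in place
    rec_xyz,     # (R, 3)
    sigma_ar,    # (A, R)
    eps_ar,      # (A, R)
    qpref_ar,    # (A, R) = K q_a q_i / 4
    cutoff,
    cap,
    max_iter,
    energies,    # (B,) out: final direct energies
    converged,   # (B,) uint8 out
):
    """Rigid-body gradient descent with per-pose backtracking.

    The accepted energy sequence is non-increasing by construction, so
    the returned energy never exceeds the direct energy of the input pose.
    """
    B = quats.shape[0]
    A = body.shape[0]
    cutoff2 = cutoff * cutoff
    rot = np.empty((3, 3))
    grad = np.empty((A, 3))
    dq = np.empty(4)
    qnew = np.empty(4)
    for b in range(B):
        q = quats[b]
        t = trans[b].copy()
        _quat_to_mat(q, rot)
        e = _pose_energy_grad(
            body, rot, t, rec_xyz, sigma_ar, eps_ar, qpref_ar, cutoff2, cap, grad
        )
        lr = 0.05
        done = False
        for _ in range(max_iter):
            # force on centroid and torque about it
            fx = 0.0
            fy = 0.0
            fz = 0.0
            tx = 0.0
            ty = 0.0
            tz = 0.0
            for a in range(A):
                gx = grad[a, 0]
                gy = grad[a, 1]
                gz = grad[a, 2]
                fx += gx
                fy += gy
                fz += gz
                rx = rot[0, 0] * body[a, 0] + rot[0, 1] * body[a, 1] + rot[0, 2] * body[a, 2]
                ry = rot[1, 0] * body[a, 0] + rot[1, 1] * body[a, 1] + rot[1, 2] * body[a, 2]
                rz = rot[2, 0] * body[a, 0] + rot[2, 1] * body[a, 1] + rot[2, 2] * body[a, 2]
                tx += ry * gz - rz * gy
                ty += rz * gx - rx * gz
                tz += rx * gy - ry * gx
            gnorm = np.sqrt(fx * fx + fy * fy + fz * fz + tx * tx + ty * ty + tz * tz)
            if gnorm < 1e-8:
                done = True
                break
            # propose step
            ntx = t[0] - lr * fx
            nty = t[1] - lr * fy
            ntz = t[2] - lr * fz
            wx = -lr * tx
            wy = -lr * ty
            wz = -lr * tz
            ang = np.sqrt(wx * wx + wy * wy + wz * wz)
            if ang > 0.5:  # cap rotation step at 0.5 rad
                sc = 0.5 / ang
                wx *= sc
                wy *= sc
                wz *= sc
                ang = 0.5
            if ang > 1e-12:
                s = np.sin(0.5 * ang) / ang
                dq[0] = np.cos(0.5 * ang)
                dq[1] = wx * s
                dq[2] = wy * s
                dq[3] = wz * s
            else:
                dq[0] = 1.0
                dq[1] = 0.0
                dq[2] = 0.0
                dq[3] = 0.0
            _quat_mul(dq, q, qnew)
            qn = np.sqrt(qnew[0] ** 2 + qnew[1] ** 2 + qnew[2] ** 2 + qnew[3] ** 2)
            for j in range(4):
                qnew[j] /= qn
            _quat_to_mat(qnew, rot)
            tnew = np.empty(3)
            tnew[0] = ntx
            tnew[1] = nty
            tnew[2] = ntz
            enew = _pose_energy_only(
                body, rot, tnew, rec_xyz, sigma_ar, eps_ar, qpref_ar, cutoff2, cap
            )
            if enew <= e:
                if e - enew < 1e-9 and lr < 1e-3:
                    e = enew
                    for j in range(4):
                        q[j] = qnew[j]
                    t = tnew
                    done = True
                    break
                e = enew
                for j in range(4):
                    q[j] = qnew[j]
                t = tnew
                lr = min(lr * 1.3, 0.5)
                _quat_to_mat(q, rot)
                e = _pose_energy_grad(
                    body, rot, t, rec_xyz, sigma_ar, eps_ar, qpref_ar, cutoff2, cap, grad
                )
            else:
                lr *= 0.5
                _quat_to_mat(q, rot)  # restore rotation of current q
                if lr < 1e-6:
                    done = True
                    break
        trans[b, 0] = t[0]
        trans[b, 1] = t[1]
        trans[b, 2] = t[2]
        energies[b] = e
        converged[b] = 1 if done else 0
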