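"""Numba kernels: energy terms and the Metropolis sweep.

All energies are in kT at the reference temperature; temperatures are
dimensionless multipliers.  The kernels operate on flat arrays prepared
by :class:`chromatinmc.forcefield.EnergyModel`:

``pos``      (n+1, 3) joint positions, nm
``frames``   (n, 3, 3) per-segment orthonormal frames, rows u, v, f
``p``        scalar parameter vector, see the P_* index constants

Moves are rigid rotations (single-segment twist, crankshaft of a short
sub-chain, pivot of a head/tail), so segment lengths are preserved and
delta energies only involve the boundary joints plus non-bonded pairs
that cross the moved/static partition.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# parameter vector layout
P_LB = 0       # Bjerrum length, nm
P_LAM = 1      # Debye screening length, nm
P_ESRC2 = 2    # electrostatic cutoff^2, nm^2
P_EMAX = 3     # max internucleosomal attraction, kT
P_SIGS = 4     # side-by-side contact distance, nm
P_SIGE = 5     # face-to-face contact distance, nm
P_SIG0 = 6     # range parameter of the shifted 12-6
P_RC = 7       # internucleosomal cutoff, nm
P_SCALE = 8    # depth normalization so the global minimum is -E_max
P_W0 = 9       # isotropic depth weight
P_W1 = 10      # axis-alignment depth weight
P_W2 = 11      # stacking (axis-to-r) depth weight
P_CAP = 12     # excluded-volume cap, kT
P_RDNA = 13    # linker DNA radius, nm
P_RNUC = 14    # effective nucleosome radius for DNA-nucleosome contacts, nm
P_NNFRAC = 15  # nucleosome-nucleosome hard-contact fraction of sigma(omega)
P_EVON = 16    # excluded volume enabled flag
P_ZMIN = 17    # clamp for the reduced separation of the 12-6 core
P_SKIP_LL2 = 18  # linker-linker midpoint-distance^2 early exit
P_SKIP_SS2 = 19  # stem-stem midpoint-distance^2 early exit
P_SKIP_SL2 = 20  # stem-linker midpoint-distance^2 early exit
N_PARAMS = 21

# energy-term indices
T_STRETCH, T_BEND, T_TWIST, T_ES, T_NUC, T_EV = 0, 1, 2, 3, 4, 5


@njit(cache=True)
def _rodrigues(ax, ay, az, angle):
    """Rotation matrix about a unit axis."""
    c = math.cos(angle)
    s = math.sin(angle)
    C = 1.0 - c
    R = np.empty((3, 3))
    R[0, 0] = c + ax * ax * C
    R[0, 1] = ax * ay * C - az * s
    R[0, 2] = ax * az * C + ay * s
    R[1, 0] = ay * ax * C + az * s
    R[1, 1] = c + ay * ay * C
    R[1, 2] = ay * az * C - ax * s
    R[2, 0] = az * ax * C - ay * s
    R[2, 1] = az * ay * C + ax * s
    R[2, 2] = c + az * az * C
    return R


@njit(cache=True)
def _rotate_rows(mat, R):
    """Apply R to each row vector of a (3, 3) frame, in place."""
    for r in range(3):
        x = mat[r, 0]
        y = mat[r, 1]
        z = mat[r, 2]
        mat[r, 0] = R[0, 0] * x + R[0, 1] * y + R[0, 2] * z
        mat[r, 1] = R[1, 0] * x + R[1, 1] * y + R[1, 2] * z
        mat[r, 2] = R[2, 0] * x + R[2, 1] * y + R[2, 2] * z


@njit(cache=True)
def _joint_elastic(pos, frames, kbend, theta0, ktwist, j):
    """Bend + twist energy at interior joint j (between segments j-1 and j)."""
    ax = pos[j, 0] - pos[j - 1, 0]
    ay = pos[j, 1] - pos[j - 1, 1]
    az = pos[j, 2] - pos[j - 1, 2]
    bx = pos[j + 1, 0] - pos[j, 0]
    by = pos[j + 1, 1] - pos[j, 1]
    bz = pos[j + 1, 2] - pos[j, 2]
    na = math.sqrt(ax * ax + ay * ay + az * az)
    nb = math.sqrt(bx * bx + by * by + bz * bz)
    c = (ax * bx + ay * by + az * bz) / (na * nb)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    theta = math.acos(c)
    dth = theta - theta0[j - 1]
    eb = 0.5 * kbend[j - 1] * dth * dth

    # twist: parallel-transport v of segment j-1 onto segment j
    u0x, u0y, u0z = frames[j - 1, 0, 0], frames[j - 1, 0, 1], frames[j - 1, 0, 2]
    u1x, u1y, u1z = frames[j, 0, 0], frames[j, 0, 1], frames[j, 0, 2]
    cxx = u0y * u1z - u0z * u1y
    cxy = u0z * u1x - u0x * u1z
    cxz = u0x * u1y - u0y * u1x
    s = math.sqrt(cxx * cxx + cxy * cxy + cxz * cxz)
    cu = u0x * u1x + u0y * u1y + u0z * u1z
    vx, vy, vz = frames[j - 1, 1, 0], frames[j - 1, 1, 1], frames[j - 1, 1, 2]
    if s > 1e-12:
        ang = math.atan2(s, cu)
        R = _rodrigues(cxx / s, cxy / s, cxz / s, ang)
        tx = R[0, 0] * vx + R[0, 1] * vy + R[0, 2] * vz
        ty = R[1, 0] * vx + R[1, 1] * vy + R[1, 2] * vz
        tz = R[2, 0] * vx + R[2, 1] * vy + R[2, 2] * vz
        vx, vy, vz = tx, ty, tz
    dv = vx * frames[j, 1, 0] + vy * frames[j, 1, 1] + vz * frames[j, 1, 2]
    df = vx * frames[j, 2, 0] + vy * frames[j, 2, 1] + vz * frames[j, 2, 2]
    psi = math.atan2(df, dv)
    et = 0.5 * ktwist[j - 1] * psi * psi
    return eb, et


@njit(cache=True)
def elastic_full(pos, frames, l0, kstretch, kbend, theta0, ktwist):
    n = l0.shape[0]
    e_s = 0.0
    for i in range(n):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        dl = math.sqrt(dx * dx + dy * dy + dz * dz) - l0[i]
        e_s += 0.5 * kstretch[i] * dl * dl
    e_b = 0.0
    e_t = 0.0
    for j in range(1, n):
        eb, et = _joint_elastic(pos, frames, kbend, theta0, ktwist, j)
        e_b += eb
        e_t += et
    return e_s, e_b, e_t


@njit(cache=True)
def _pt_seg_dist2(px, py, pz, qx, qy, qz, vx, vy, vz):
    vv = vx * vx + vy * vy + vz * vz
    t = 0.0
    if vv > 1e-16:
        t = ((px - qx) * vx + (py - qy) * vy + (pz - qz) * vz) / vv
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
    dx = px - qx - t * vx
    dy = py - qy - t * vy
    dz = pz - qz - t * vz
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _seg_seg_dist2(p0x, p0y, p0z, ux, uy, uz, q0x, q0y, q0z, vx, vy, vz):
    """Minimum squared distance between segments p0+s*u and q0+t*v, s,t in [0,1]."""
    wx = p0x - q0x
    wy = p0y - q0y
    wz = p0z - q0z
    a = ux * ux + uy * uy + uz * uz
    b = ux * vx + uy * vy + uz * vz
    c = vx * vx + vy * vy + vz * vz
    d = ux * wx + uy * wy + uz * wz
    e = vx * wx + vy * wy + vz * wz
    D = a * c - b * b
    sD = D
    tD = D
    if D < 1e-12:
        sN = 0.0
        sD = 1.0
        tN = e
        tD = c
    else:
        sN = b * e - c * d
        tN = a * e - b * d
        if sN < 0.0:
            sN = 0.0
            tN = e
            tD = c
        elif sN > sD:
            sN = sD
            tN = e + b
            tD = c
    if tN < 0.0:
        tN = 0.0
        if -d < 0.0:
            sN = 0.0
        elif -d > a:
            sN = sD
        else:
            sN = -d
            sD = a
    elif tN > tD:
        tN = tD
        if (-d + b) < 0.0:
            sN = 0.0
        elif (-d + b) > a:
            sN = sD
        else:
            sN = -d + b
            sD = a
    sc = 0.0 if abs(sN) < 1e-12 else sN / sD
    tc = 0.0 if abs(tN) < 1e-12 else tN / tD
    dx = wx + sc * ux - tc * vx
    dy = wy + sc * uy - tc * vy
    dz = wz + sc * uz - tc * vz
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, inline="always")
def _nuc_geom(pos, frames, stem_seg, nuc_off, nuc_axis, k):
    """Lab-frame center and symmetry axis of nucleosome k (6 scalars)."""
    s = stem_seg[k]
    o0 = nuc_off[k, 0]
    o1 = nuc_off[k, 1]
    o2 = nuc_off[k, 2]
    a0 = nuc_axis[k, 0]
    a1 = nuc_axis[k, 1]
    a2 = nuc_axis[k, 2]
    cx = (
        0.5 * (pos[s, 0] + pos[s + 1, 0])
        + o0 * frames[s, 0, 0] + o1 * frames[s, 1, 0] + o2 * frames[s, 2, 0]
    )
    cy = (
        0.5 * (pos[s, 1] + pos[s + 1, 1])
        + o0 * frames[s, 0, 1] + o1 * frames[s, 1, 1] + o2 * frames[s, 2, 1]
    )
    cz = (
        0.5 * (pos[s, 2] + pos[s + 1, 2])
        + o0 * frames[s, 0, 2] + o1 * frames[s, 1, 2] + o2 * frames[s, 2, 2]
    )
    ex = a0 * frames[s, 0, 0] + a1 * frames[s, 1, 0] + a2 * frames[s, 2, 0]
    ey = a0 * frames[s, 0, 1] + a1 * frames[s, 1, 1] + a2 * frames[s, 2, 1]
    ez = a0 * frames[s, 0, 2] + a1 * frames[s, 1, 2] + a2 * frames[s, 2, 2]
    return cx, cy, cz, ex, ey, ez


@njit(cache=True)
def nuc_pair_terms(rx, ry, rz, eix, eiy, eiz, ejx, ejy, ejz, p):
    """Anisotropic internucleosomal potential + hard-core overlap penalty.

    Returns (attractive/shifted 12-6 term, excluded-volume term), both kT.
    The depth is largest and the contact distance smallest for coaxial
    face-to-face stacking; the potential is truncated and shifted to zero
    at the cutoff, and depth-normalized (P_SCALE) so the global minimum is
    exactly -E_max.
    """
    r2 = rx * rx + ry * ry + rz * rz
    rc = p[P_RC]
    if r2 >= rc * rc or r2 < 1e-20:
        if r2 < 1e-20:  # coincident centers: full overlap penalty
            return 0.0, p[P_CAP] if p[P_EVON] > 0.5 else 0.0
        return 0.0, 0.0
    r = math.sqrt(r2)
    rhx, rhy, rhz = rx / r, ry / r, rz / r
    ai = eix * rhx + eiy * rhy + eiz * rhz
    aj = ejx * rhx + ejy * rhy + ejz * rhz
    a = 0.5 * (ai * ai + aj * aj)
    ee = eix * ejx + eiy * ejy + eiz * ejz
    sig = p[P_SIGS] + (p[P_SIGE] - p[P_SIGS]) * a
    eps = p[P_EMAX] * (p[P_W0] + p[P_W1] * ee * ee + p[P_W2] * a)

    sig0 = p[P_SIG0]
    zmin = p[P_ZMIN]
    z = (r - sig + sig0) / sig0
    if z < zmin:
        z = zmin
    z6 = 1.0 / (z * z * z * z * z * z)
    u = z6 * z6 - 2.0 * z6
    zc = (rc - sig + sig0) / sig0
    if zc < zmin:
        zc = zmin
    zc6 = 1.0 / (zc * zc * zc * zc * zc * zc)
    u -= zc6 * zc6 - 2.0 * zc6
    e_nuc = p[P_SCALE] * eps * u

    e_ev = 0.0
    if p[P_EVON] > 0.5:
        contact = p[P_NNFRAC] * sig
        if r < contact:
            x = (contact - r) / contact
            e_ev = p[P_CAP] * x * x * x * x
            if e_ev > p[P_CAP]:
                e_ev = p[P_CAP]
    return e_nuc, e_ev


@njit(cache=True)
def _pair_terms(i, j, pos, frames, is_stem, seg_nuc, q,
                stem_seg, nuc_off, nuc_axis, p):
    """Non-bonded terms (es, nuc, ev) for segment pair i < j."""
    mix = 0.5 * (pos[i, 0] + pos[i + 1, 0])
    miy = 0.5 * (pos[i, 1] + pos[i + 1, 1])
    miz = 0.5 * (pos[i, 2] + pos[i + 1, 2])
    mjx = 0.5 * (pos[j, 0] + pos[j + 1, 0])
    mjy = 0.5 * (pos[j, 1] + pos[j + 1, 1])
    mjz = 0.5 * (pos[j, 2] + pos[j + 1, 2])
    dx = mjx - mix
    dy = mjy - miy
    dz = mjz - miz
    m2 = dx * dx + dy * dy + dz * dz

    if is_stem[i] and is_stem[j]:
        if m2 > p[P_SKIP_SS2]:
            return 0.0, 0.0, 0.0
        cix, ciy, ciz, eix, eiy, eiz = _nuc_geom(
            pos, frames, stem_seg, nuc_off, nuc_axis, seg_nuc[i])
        cjx, cjy, cjz, ejx, ejy, ejz = _nuc_geom(
            pos, frames, stem_seg, nuc_off, nuc_axis, seg_nuc[j])
        e_nuc, e_ev = nuc_pair_terms(
            cjx - cix, cjy - ciy, cjz - ciz,
            eix, eiy, eiz, ejx, ejy, ejz, p,
        )
        return 0.0, e_nuc, e_ev

    if is_stem[i] or is_stem[j]:
        if m2 > p[P_SKIP_SL2]:
            return 0.0, 0.0, 0.0
        if j - i < 3:  # stem and its entering/exiting linker segments
            return 0.0, 0.0, 0.0
        if p[P_EVON] < 0.5:
            return 0.0, 0.0, 0.0
        if is_stem[i]:
            gx, gy, gz, _, _, _ = _nuc_geom(
                pos, frames, stem_seg, nuc_off, nuc_axis, seg_nuc[i])
            lk = j
        else:
            gx, gy, gz, _, _, _ = _nuc_geom(
                pos, frames, stem_seg, nuc_off, nuc_axis, seg_nuc[j])
            lk = i
        d2 = _pt_seg_dist2(
            gx, gy, gz,
            pos[lk, 0], pos[lk, 1], pos[lk, 2],
            pos[lk + 1, 0] - pos[lk, 0],
            pos[lk + 1, 1] - pos[lk, 1],
            pos[lk + 1, 2] - pos[lk, 2],
        )
        contact = p[P_RDNA] + p[P_RNUC]
        if d2 < contact * contact:
            x = (contact - math.sqrt(d2)) / contact
            e = p[P_CAP] * x * x * x * x
            return 0.0, 0.0, e if e < p[P_CAP] else p[P_CAP]
        return 0.0, 0.0, 0.0

    # linker-linker
    if m2 > p[P_SKIP_LL2]:
        return 0.0, 0.0, 0.0
    if j - i < 2:
        return 0.0, 0.0, 0.0
    e_es = 0.0
    if m2 < p[P_ESRC2]:
        qq = q[i] * q[j]
        if qq != 0.0:
            r = math.sqrt(m2)
            e_es = p[P_LB] * qq * math.exp(-r / p[P_LAM]) / r
    e_ev = 0.0
    if p[P_EVON] > 0.5:
        d2 = _seg_seg_dist2(
            pos[i, 0], pos[i, 1], pos[i, 2],
            pos[i + 1, 0] - pos[i, 0], pos[i + 1, 1] - pos[i, 1],
            pos[i + 1, 2] - pos[i, 2],
            pos[j, 0], pos[j, 1], pos[j, 2],
            pos[j + 1, 0] - pos[j, 0], pos[j + 1, 1] - pos[j, 1],
            pos[j + 1, 2] - pos[j, 2],
        )
        contact = 2.0 * p[P_RDNA]
        if d2 < contact * contact:
            x = (contact - math.sqrt(d2)) / contact
            e_ev = p[P_CAP] * x * x * x * x
            if e_ev > p[P_CAP]:
                e_ev = p[P_CAP]
    return e_es, 0.0, e_ev


@njit(cache=True)
def nonbonded_full(pos, frames, is_stem, seg_nuc, q, stem_seg, nuc_off, nuc_axis, p):
    n = is_stem.shape[0]
    e_es = 0.0
    e_nuc = 0.0
    e_ev = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            a, b, c = _pair_terms(
                i, j, pos, frames, is_stem, seg_nuc, q,
                stem_seg, nuc_off, nuc_axis, p,
            )
            e_es += a
            e_nuc += b
            e_ev += c
    return e_es, e_nuc, e_ev


@njit(cache=True)
def _nonbonded_cross(a, b, pos, frames, is_stem, seg_nuc, q,
                     stem_seg, nuc_off, nuc_axis, p):
    """Non-bonded terms for pairs with exactly one member in [a, b)."""
    n = is_stem.shape[0]
    e_es = 0.0
    e_nuc = 0.0
    e_ev = 0.0
    for i in range(a, b):
        for j in range(0, a):
            x, y, z = _pair_terms(
                j, i, pos, frames, is_stem, seg_nuc, q,
                stem_seg, nuc_off, nuc_axis, p,
            )
            e_es += x
            e_nuc += y
            e_ev += z
        for j in range(b, n):
            x, y, z = _pair_terms(
                i, j, pos, frames, is_stem, seg_nuc, q,
                stem_seg, nuc_off, nuc_axis, p,
            )
            e_es += x
            e_nuc += y
            e_ev += z
    return e_es, e_nuc, e_ev


@njit(cache=True)
def full_energy(pos, frames, l0, kstretch, is_stem, seg_nuc, q,
                kbend, theta0, ktwist, stem_seg, nuc_off, nuc_axis, p):
    out = np.zeros(6)
    e_s, e_b, e_t = elastic_full(pos, frames, l0, kstretch, kbend, theta0, ktwist)
    out[T_STRETCH] = e_s
    out[T_BEND] = e_b
    out[T_TWIST] = e_t
    e_es, e_nuc, e_ev = nonbonded_full(
        pos, frames, is_stem, seg_nuc, q, stem_seg, nuc_off, nuc_axis, p
    )
    out[T_ES] = e_es
    out[T_NUC] = e_nuc
    out[T_EV] = e_ev
    return out


@njit(cache=True)
def _boundary_elastic(pos, frames, kbend, theta0, ktwist, joints):
    n = kbend.shape[0] + 1
    eb = 0.0
    et = 0.0
    for jj in range(joints.shape[0]):
        j = joints[jj]
        if 1 <= j <= n - 1:
            b, t = _joint_elastic(pos, frames, kbend, theta0, ktwist, j)
            eb += b
            et += t
    return eb, et


@njit(cache=True)
def run_mc(pos, frames, l0, kstretch, is_stem, seg_nuc, q,
           kbend, theta0, ktwist, stem_seg, nuc_off, nuc_axis, p,
           T, n_moves, seed, amp_twist, amp_crank, amp_pivot,
           p_twist, p_crank, crank_max, eterms):
    """Run n_moves Metropolis moves at temperature T, updating state in place.

    ``eterms`` (length 6, running per-term energies) is updated
    incrementally with each accepted move.  Returns the accepted count.
    """
    np.random.seed(seed)
    n = l0.shape[0]
    nbflag = (np.sum(q * q) > 0.0) or (p[P_EVON] > 0.5) or (stem_seg.shape[0] > 0)
    buf_pos = np.empty((n + 1, 3))
    buf_frames = np.empty((n, 3, 3))
    joints2 = np.empty(2, np.int64)
    joints1 = np.empty(1, np.int64)
    accepted = 0

    for _ in range(n_moves):
        sel = np.random.random()
        d_bend = 0.0
        d_twist = 0.0
        d_es = 0.0
        d_nuc = 0.0
        d_ev = 0.0

        if sel < p_twist:
            i = np.random.randint(0, n)
            joints2[0] = i
            joints2[1] = i + 1
            eb0, et0 = _boundary_elastic(pos, frames, kbend, theta0, ktwist, joints2)
            stem_move = is_stem[i] and nbflag
            if stem_move:
                es0, nu0, ev0 = _nonbonded_cross(
                    i, i + 1, pos, frames, is_stem, seg_nuc, q,
                    stem_seg, nuc_off, nuc_axis, p,
                )
            else:
                es0 = nu0 = ev0 = 0.0
            for r in range(3):
                for c in range(3):
                    buf_frames[i, r, c] = frames[i, r, c]
            ang = (2.0 * np.random.random() - 1.0) * amp_twist
            R = _rodrigues(frames[i, 0, 0], frames[i, 0, 1], frames[i, 0, 2], ang)
            _rotate_rows(frames[i], R)
            eb1, et1 = _boundary_elastic(pos, frames, kbend, theta0, ktwist, joints2)
            if stem_move:
                es1, nu1, ev1 = _nonbonded_cross(
                    i, i + 1, pos, frames, is_stem, seg_nuc, q,
                    stem_seg, nuc_off, nuc_axis, p,
                )
            else:
                es1 = nu1 = ev1 = 0.0
            d_bend = eb1 - eb0
            d_twist = et1 - et0
            d_es = es1 - es0
            d_nuc = nu1 - nu0
            d_ev = ev1 - ev0
            dE = d_bend + d_twist + d_es + d_nuc + d_ev
            if dE <= 0.0 or (dE / T < 700.0 and np.random.random() < math.exp(-dE / T)):
                accepted += 1
            else:
                for r in range(3):
                    for c in range(3):
                        frames[i, r, c] = buf_frames[i, r, c]
                continue

        elif sel < p_twist + p_crank and n >= 3:
            i = np.random.randint(0, n - 1)
            span_max = min(crank_max, n - i)
            if span_max < 2:
                continue
            span = np.random.randint(2, span_max + 1)
            j = i + span
            axx = pos[j, 0] - pos[i, 0]
            axy = pos[j, 1] - pos[i, 1]
            axz = pos[j, 2] - pos[i, 2]
            an = math.sqrt(axx * axx + axy * axy + axz * axz)
            if an < 1e-9:
                continue
            joints2[0] = i
            joints2[1] = j
            eb0, et0 = _boundary_elastic(pos, frames, kbend, theta0, ktwist, joints2)
            if nbflag:
                es0, nu0, ev0 = _nonbonded_cross(
                    i, j, pos, frames, is_stem, seg_nuc, q,
                    stem_seg, nuc_off, nuc_axis, p,
                )
            else:
                es0 = nu0 = ev0 = 0.0
            for k in range(i + 1, j):
                for c in range(3):
                    buf_pos[k, c] = pos[k, c]
            for k in range(i, j):
                for r in range(3):
                    for c in range(3):
                        buf_frames[k, r, c] = frames[k, r, c]
            ang = (2.0 * np.random.random() - 1.0) * amp_crank
            R = _rodrigues(axx / an, axy / an, axz / an, ang)
            for k in range(i + 1, j):
                x = pos[k, 0] - pos[i, 0]
                y = pos[k, 1] - pos[i, 1]
                z = pos[k, 2] - pos[i, 2]
                pos[k, 0] = pos[i, 0] + R[0, 0] * x + R[0, 1] * y + R[0, 2] * z
                pos[k, 1] = pos[i, 1] + R[1, 0] * x + R[1, 1] * y + R[1, 2] * z
                pos[k, 2] = pos[i, 2] + R[2, 0] * x + R[2, 1] * y + R[2, 2] * z
            for k in range(i, j):
                _rotate_rows(frames[k], R)
            eb1, et1 = _boundary_elastic(pos, frames, kbend, theta0, ktwist, joints2)
            if nbflag:
                es1, nu1, ev1 = _nonbonded_cross(
                    i, j, pos, frames, is_stem, seg_nuc, q,
                    stem_seg, nuc_off, nuc_axis, p,
                )
            else:
                es1 = nu1 = ev1 = 0.0
            d_bend = eb1 - eb0
            d_twist = et1 - et0
            d_es = es1 - es0
            d_nuc = nu1 - nu0
            d_ev = ev1 - ev0
            dE = d_bend + d_twist + d_es + d_nuc + d_ev
            if dE <= 0.0 or (dE / T < 700.0 and np.random.random() < math.exp(-dE / T)):
                accepted += 1
            else:
                for k in range(i + 1, j):
                    for c in range(3):
                        pos[k, c] = buf_pos[k, c]
                for k in range(i, j):
                    for r in range(3):
                        for c in range(3):
                            frames[k, r, c] = buf_frames[k, r, c]
                continue

        else:
            j = np.random.randint(1, n)
            head = np.random.random() < 0.5
            if head:
                a, b = 0, j
                lo_pos, hi_pos = 0, j
            else:
                a, b = j, n
                lo_pos, hi_pos = j + 1, n + 1
            joints1[0] = j
            eb0, et0 = _boundary_elastic(pos, frames, kbend, theta0, ktwist, joints1)
            if nbflag:
                es0, nu0, ev0 = _nonbonded_cross(
                    a, b, pos, frames, is_stem, seg_nuc, q,
                    stem_seg, nuc_off, nuc_axis, p,
                )
            else:
                es0 = nu0 = ev0 = 0.0
            for k in range(lo_pos, hi_pos):
                for c in range(3):
                    buf_pos[k, c] = pos[k, c]
            for k in range(a, b):
                for r in range(3):
                    for c in range(3):
                        buf_frames[k, r, c] = frames[k, r, c]
            axx = np.random.normal()
            axy = np.random.normal()
            axz = np.random.normal()
            an = math.sqrt(axx * axx + axy * axy + axz * axz)
            if an < 1e-12:
                continue
            ang = (2.0 * np.random.random() - 1.0) * amp_pivot
            R = _rodrigues(axx / an, axy / an, axz / an, ang)
            for k in range(lo_pos, hi_pos):
                x = pos[k, 0] - pos[j, 0]
                y = pos[k, 1] - pos[j, 1]
                z = pos[k, 2] - pos[j, 2]
                pos[k, 0] = pos[j, 0] + R[0, 0] * x + R[0, 1] * y + R[0, 2] * z
                pos[k, 1] = pos[j, 1] + R[1, 0] * x + R[1, 1] * y + R[1, 2] * z
                pos[k, 2] = pos[j, 2] + R[2, 0] * x + R[2, 1] * y + R[2, 2] * z
            for k in range(a, b):
                _rotate_rows(frames[k], R)
            eb1, et1 = _boundary_elastic(pos, frames, kbend, theta0, ktwist, joints1)
            if nbflag:
                es1, nu1, ev1 = _nonbonded_cross(
                    a, b, pos, frames, is_stem, seg_nuc, q,
                    stem_seg, nuc_off, nuc_axis, p,
                )
            else:
                es1 = nu1 = ev1 = 0.0
            d_bend = eb1 - eb0
            d_twist = et1 - et0
            d_es = es1 - es0
            d_nuc = nu1 - nu0
            d_ev = ev1 - ev0
            dE = d_bend + d_twist + d_es + d_nuc + d_ev
            if dE <= 0.0 or (dE / T < 700.0 and np.random.random() < math.exp(-dE / T)):
                accepted += 1
            else:
                for k in range(lo_pos, hi_pos):
                    for c in range(3):
                        pos[k, c] = buf_pos[k, c]
                for k in range(a, b):
                    for r in range(3):
                        for c in range(3):
                            frames[k, r, c] = buf_frames[k, r, c]
                continue

        eterms[T_BEND] += d_bend
        eterms[T_TWIST] += d_twist
        eterms[T_ES] += d_es
        eterms[T_NUC] += d_nuc
        eterms[T_EV] += d_ev

    return accepted
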