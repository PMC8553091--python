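"""Numba kernels: force evaluation and the inner integration loop.

Everything here operates on plain numpy arrays in (pN, um, s) units.  The
x direction is periodic; bond and pair geometry always uses the minimum
image along x.  Segments are short (~0.1 um) compared to the box width
(2 um), so a single image shift chosen from segment midpoints is exact.

Force sign conventions: every potential-derived channel returns -grad(E).
Channels accumulate into a caller-provided (N, 3) array.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# channel indices used by the chunk accumulator
CH_SPRING, CH_BEND, CH_CROSSLINK, CH_EXCLUDED = 0, 1, 2, 3
CH_LEADING, CH_MOTOR, CH_CONFINE, CH_THERMAL = 4, 5, 6, 7
N_CHANNELS = 8

# motor mode codes
MODE_UNIFORM, MODE_BACK, MODE_MEMBRANE = 0, 1, 2

# advance_chunk status codes
OK, UNSTABLE, PAIR_OVERFLOW = 0, 1, 2


@njit(cache=True)
def _min_image_dx(dx, box_w):
    # coordinates are wrapped, so |dx| < box_w: branches beat fmod
    if dx > 0.5 * box_w:
        return dx - box_w
    if dx <= -0.5 * box_w:
        return dx + box_w
    return dx


@njit(cache=True)
def _image_shift(diff, box_w):
    """Shift (multiple of box_w) that maps the second point next to the
    first; valid for |diff| < 1.5 * box_w."""
    if diff > 0.5 * box_w:
        return box_w
    if diff < -0.5 * box_w:
        return -box_w
    return 0.0


@njit(cache=True)
def seg_seg_closest(p0x, p0y, p0z, p1x, p1y, p1z,
                    q0x, q0y, q0z, q1x, q1y, q1z):
    """Closest approach between 3D segments P(s)=P0+s*(P1-P0), Q(t).

    Returns (dist, s, t).  Parallel segments use the midpoint of P as the
    witness (deterministic tie rule).  Coordinates must already be in the
    same periodic image.
    """
    d1x = p1x - p0x; d1y = p1y - p0y; d1z = p1z - p0z
    d2x = q1x - q0x; d2y = q1y - q0y; d2z = q1z - q0z
    rx = p0x - q0x; ry = p0y - q0y; rz = p0z - q0z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    b = d1x * d2x + d1y * d2y + d1z * d2z
    c = d1x * rx + d1y * ry + d1z * rz
    f = d2x * rx + d2y * ry + d2z * rz
    eps = 1e-14
    if a < eps or e < eps:
        # degenerate segment: treat as point(s)
        s = 0.0
        t = 0.0
        if e >= eps:
            t = min(max(f / e, 0.0), 1.0)
        if a >= eps:
            s = min(max(-c / a, 0.0), 1.0)
    else:
        denom = a * e - b * b
        if denom > eps * a * e:
            s = (b * f - c * e) / denom
            s = min(max(s, 0.0), 1.0)
        else:
            s = 0.5     # parallel: midpoint witness
        t = (b * s + f) / e
        if t < 0.0:
            t = 0.0
            s = min(max(-c / a, 0.0), 1.0)
        elif t > 1.0:
            t = 1.0
            s = min(max((b - c) / a, 0.0), 1.0)
    cx = p0x + s * d1x - (q0x + t * d2x)
    cy = p0y + s * d1y - (q0y + t * d2y)
    cz = p0z + s * d1z - (q0z + t * d2z)
    dist = np.sqrt(cx * cx + cy * cy + cz * cz)
    return dist, s, t


@njit(cache=True)
def spring_forces(pos, bond_i, bond_j, rest, k, box_w, F):
    """Harmonic bonds: F_i = -k (d - rest) d_hat_ij.  Returns the number of
    bonds with near-zero length (flagged numerical trouble)."""
    bad = 0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]; j = bond_j[b]
        dx = _min_image_dx(pos[i, 0] - pos[j, 0], box_w)
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < 1e-12:
            bad += 1
            continue
        fmag = -k * (d - rest[b]) / d
        fx = fmag * dx; fy = fmag * dy; fz = fmag * dz
        F[i, 0] += fx; F[i, 1] += fy; F[i, 2] += fz
        F[j, 0] -= fx; F[j, 1] -= fy; F[j, 2] -= fz
    return bad


@njit(cache=True)
def crosslink_forces(pos, cl_i, cl_j, cl_k, cl_rest, box_w, F):
    """Crosslink springs with per-link spring constant and rest length."""
    bad = 0
    for b in range(cl_i.shape[0]):
        i = cl_i[b]; j = cl_j[b]
        dx = _min_image_dx(pos[i, 0] - pos[j, 0], box_w)
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < 1e-12:
            bad += 1
            continue
        fmag = -cl_k[b] * (d - cl_rest[b]) / d
        F[i, 0] += fmag * dx; F[i, 1] += fmag * dy; F[i, 2] += fmag * dz
        F[j, 0] -= fmag * dx; F[j, 1] -= fmag * dy; F[j, 2] -= fmag * dz
    return bad


@njit(cache=True)
def bending_forces(pos, trip_i, trip_j, trip_k, kappa_over_l0, box_w, F):
    """Cosine bending, E = (kappa/l0) * sum_j (1 - cos theta_j).

    cos theta = u_hat . v_hat with u = r_j - r_i, v = r_k - r_j; forces are
    -grad E and therefore favor straight filaments.
    """
    for m in range(trip_i.shape[0]):
        i = trip_i[m]; j = trip_j[m]; k = trip_k[m]
        ux = _min_image_dx(pos[j, 0] - pos[i, 0], box_w)
        uy = pos[j, 1] - pos[i, 1]
        uz = pos[j, 2] - pos[i, 2]
        vx = _min_image_dx(pos[k, 0] - pos[j, 0], box_w)
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        lu = np.sqrt(ux * ux + uy * uy + uz * uz)
        lv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if lu < 1e-12 or lv < 1e-12:
            continue
        ux /= lu; uy /= lu; uz /= lu
        vx /= lv; vy /= lv; vz /= lv
        cth = ux * vx + uy * vy + uz * vz
        # grad_i c = -(v_hat - c u_hat)/lu ; grad_k c = (u_hat - c v_hat)/lv
        gix = -(vx - cth * ux) / lu
        giy = -(vy - cth * uy) / lu
        giz = -(vz - cth * uz) / lu
        gkx = (ux - cth * vx) / lv
        gky = (uy - cth * vy) / lv
        gkz = (uz - cth * vz) / lv
        # F_m = -grad_m E = (kappa/l0) grad_m c
        F[i, 0] += kappa_over_l0 * gix
        F[i, 1] += kappa_over_l0 * giy
        F[i, 2] += kappa_over_l0 * giz
        F[k, 0] += kappa_over_l0 * gkx
        F[k, 1] += kappa_over_l0 * gky
        F[k, 2] += kappa_over_l0 * gkz
        F[j, 0] -= kappa_over_l0 * (gix + gkx)
        F[j, 1] -= kappa_over_l0 * (giy + gky)
        F[j, 2] -= kappa_over_l0 * (giz + gkz)


@njit(cache=True)
def branch_angle_forces(pos, br_i, br_j, br_k, eps_angle, cos0, box_w, F):
    """Angular restraint E = eps * (cos theta - cos theta_0)^2 on branch
    triplets, theta between the mother direction (i->j) and the daughter
    direction (j->k)."""
    for m in range(br_i.shape[0]):
        i = br_i[m]; j = br_j[m]; k = br_k[m]
        ux = _min_image_dx(pos[j, 0] - pos[i, 0], box_w)
        uy = pos[j, 1] - pos[i, 1]
        uz = pos[j, 2] - pos[i, 2]
        vx = _min_image_dx(pos[k, 0] - pos[j, 0], box_w)
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        lu = np.sqrt(ux * ux + uy * uy + uz * uz)
        lv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if lu < 1e-12 or lv < 1e-12:
            continue
        ux /= lu; uy /= lu; uz /= lu
        vx /= lv; vy /= lv; vz /= lv
        cth = ux * vx + uy * vy + uz * vz
        pref = -2.0 * eps_angle * (cth - cos0)   # -dE/dc
        gix = -(vx - cth * ux) / lu
        giy = -(vy - cth * uy) / lu
        giz = -(vz - cth * uz) / lu
        gkx = (ux - cth * vx) / lv
        gky = (uy - cth * vy) / lv
        gkz = (uz - cth * vz) / lv
        F[i, 0] += pref * gix; F[i, 1] += pref * giy; F[i, 2] += pref * giz
        F[k, 0] += pref * gkx; F[k, 1] += pref * gky; F[k, 2] += pref * gkz
        F[j, 0] -= pref * (gix + gkx)
        F[j, 1] -= pref * (giy + gky)
        F[j, 2] -= pref * (giz + gkz)


@njit(cache=True)
def excluded_volume_forces(pos, bond_i, bond_j, pairs, n_pairs,
                           k_ex, d_ex, box_w, F,
                           pair_dist=None, bead_moved=None):
    """Segment-segment repulsion for candidate bond pairs.

    When the closest distance is below d_ex a force of magnitude
    k_ex * (d_ex - d) acts along the closest-approach direction; each
    segment's share is split over its two endpoint beads by the lever rule
    (the endpoint nearer the witness point takes the larger share).
    """
    for p in range(n_pairs):
        a = pairs[p, 0]; b = pairs[p, 1]
        ia = bond_i[a]; ja = bond_j[a]
        ib = bond_i[b]; jb = bond_j[b]
        if pair_dist is not None and bead_moved is not None:
            # the pair distance can have shrunk since the list build by
            # at most the two segments' largest bead displacements
            ma = max(bead_moved[ia], bead_moved[ja])
            mb = max(bead_moved[ib], bead_moved[jb])
            if pair_dist[p] - ma - mb > d_ex:
                continue
        # image shift of segment b toward segment a, from midpoints
        mida = 0.5 * (pos[ia, 0] + pos[ja, 0])
        midb = 0.5 * (pos[ib, 0] + pos[jb, 0])
        shift = _image_shift(mida - midb, box_w)
        d, s, t = seg_seg_closest(
            pos[ia, 0], pos[ia, 1], pos[ia, 2],
            pos[ja, 0], pos[ja, 1], pos[ja, 2],
            pos[ib, 0] + shift, pos[ib, 1], pos[ib, 2],
            pos[jb, 0] + shift, pos[jb, 1], pos[jb, 2])
        if d >= d_ex:
            continue
        cax = pos[ia, 0] + s * (pos[ja, 0] - pos[ia, 0])
        cay = pos[ia, 1] + s * (pos[ja, 1] - pos[ia, 1])
        caz = pos[ia, 2] + s * (pos[ja, 2] - pos[ia, 2])
        cbx = pos[ib, 0] + shift + t * (pos[jb, 0] - pos[ib, 0])
        cby = pos[ib, 1] + t * (pos[jb, 1] - pos[ib, 1])
        cbz = pos[ib, 2] + t * (pos[jb, 2] - pos[ib, 2])
        nx = cax - cbx; ny = cay - cby; nz = caz - cbz
        if d < 1e-12:
            # exactly overlapping segments: undefined direction, tiny x kick
            nx, ny, nz = 1.0, 0.0, 0.0
            d1 = 1.0
        else:
            d1 = d
        fmag = k_ex * (d_ex - d) / d1
        fx = fmag * nx; fy = fmag * ny; fz = fmag * nz
        # lever rule: witness at parameter s => endpoint i gets (1-s)
        F[ia, 0] += (1.0 - s) * fx; F[ia, 1] += (1.0 - s) * fy
        F[ia, 2] += (1.0 - s) * fz
        F[ja, 0] += s * fx; F[ja, 1] += s * fy; F[ja, 2] += s * fz
        F[ib, 0] -= (1.0 - t) * fx; F[ib, 1] -= (1.0 - t) * fy
        F[ib, 2] -= (1.0 - t) * fz
        F[jb, 0] -= t * fx; F[jb, 1] -= t * fy; F[jb, 2] -= t * fz


@njit(cache=True)
def leading_edge_forces(pos, fil_ptr, fil_beads, f_push_total, box_w, F,
                        chsum):
    """Polymerization pushing force.

    A filament qualifies if any bead lies at y <= 0; the total force
    f_push_total is split equally over all its beads, directed along the
    barbed-to-pointed unit vector of the segment closest to the pointed end
    (bead 1 -> bead 0; pointed end is index 0).
    Returns the number of pushed filaments.
    """
    n_pushed = 0
    for fidx in range(fil_ptr.shape[0] - 1):
        lo = fil_ptr[fidx]; hi = fil_ptr[fidx + 1]
        if hi - lo < 2:
            continue
        qualifies = False
        for m in range(lo, hi):
            if pos[fil_beads[m], 1] <= 0.0:
                qualifies = True
                break
        if not qualifies:
            continue
        b0 = fil_beads[lo]; b1 = fil_beads[lo + 1]
        dx = _min_image_dx(pos[b0, 0] - pos[b1, 0], box_w)
        dy = pos[b0, 1] - pos[b1, 1]
        dz = pos[b0, 2] - pos[b1, 2]
        norm = np.sqrt(dx * dx + dy * dy + dz * dz)
        if norm < 1e-12:
            continue
        per_bead = f_push_total / (hi - lo)
        fx = per_bead * dx / norm
        fy = per_bead * dy / norm
        fz = per_bead * dz / norm
        for m in range(lo, hi):
            bb = fil_beads[m]
            F[bb, 0] += fx; F[bb, 1] += fy; F[bb, 2] += fz
            chsum[0] += fx; chsum[1] += fy; chsum[2] += fz
        n_pushed += 1
    return n_pushed


@njit(cache=True)
def _fa_xy_dist(x, y, p0x, p0y, p1x, p1y, box_w):
    # minimum image relative to the segment midpoint (capsule < box)
    abx = p1x - p0x
    aby = p1y - p0y
    midx = p0x + 0.5 * abx
    dx = _min_image_dx(x - midx, box_w) + 0.5 * abx
    dy = y - p0y
    ab2 = abx * abx + aby * aby
    if ab2 < 1e-30:
        s = 0.0
    else:
        s = (dx * abx + dy * aby) / ab2
        s = min(max(s, 0.0), 1.0)
    ex = dx - s * abx
    ey = dy - s * aby
    return np.sqrt(ex * ex + ey * ey)


@njit(cache=True)
def motor_forces(pos, fil_ptr, fil_beads, mode, f_uniform, f_back, f_membrane,
                 y_back, membrane_z, fa_p0x, fa_p0y, fa_p1x, fa_p1y,
                 fa_halfw, fa_height, box_w, F, chsum):
    """Motor pulling force in one of three modes.

    uniform: +y on every bead; back: +y on beads with y > y_back;
    membrane: on beads within the bottom membrane layer and outside the FA
    capsule, directed along the bead's filament barbed-to-pointed axis.
    """
    n = pos.shape[0]
    if mode == MODE_UNIFORM:
        for i in range(n):
            F[i, 1] += f_uniform
            chsum[1] += f_uniform
    elif mode == MODE_BACK:
        for i in range(n):
            if pos[i, 1] > y_back:
                F[i, 1] += f_back
                chsum[1] += f_back
    else:
        for fidx in range(fil_ptr.shape[0] - 1):
            lo = fil_ptr[fidx]; hi = fil_ptr[fidx + 1]
            if hi - lo < 2:
                continue
            b0 = fil_beads[lo]; b1 = fil_beads[lo + 1]
            dx = _min_image_dx(pos[b0, 0] - pos[b1, 0], box_w)
            dy = pos[b0, 1] - pos[b1, 1]
            dz = pos[b0, 2] - pos[b1, 2]
            norm = np.sqrt(dx * dx + dy * dy + dz * dz)
            if norm < 1e-12:
                continue
            ux = dx / norm; uy = dy / norm; uz = dz / norm
            for m in range(lo, hi):
                bb = fil_beads[m]
                z = pos[bb, 2]
                if z < 0.0 or z > membrane_z:
                    continue
                if z <= fa_height and _fa_xy_dist(
                        pos[bb, 0], pos[bb, 1], fa_p0x, fa_p0y,
                        fa_p1x, fa_p1y, box_w) <= fa_halfw:
                    continue    # inside FA capsule: not pulled
                F[bb, 0] += f_membrane * ux
                F[bb, 1] += f_membrane * uy
                F[bb, 2] += f_membrane * uz
                chsum[0] += f_membrane * ux
                chsum[1] += f_membrane * uy
                chsum[2] += f_membrane * uz


@njit(cache=True)
def confinement_forces(pos, box_h, f_conf, top_wall, F, chsum):
    """Constant restoring force toward the box interior at the z walls."""
    for i in range(pos.shape[0]):
        if pos[i, 2] < 0.0:
            F[i, 2] += f_conf
            chsum[2] += f_conf
        elif top_wall and pos[i, 2] > box_h:
            F[i, 2] -= f_conf
            chsum[2] -= f_conf


# ---------------------------------------------------------------------------
# neighbor search
# ---------------------------------------------------------------------------

@njit(cache=True)
def build_segment_pairs(pos, bond_i, bond_j, box_w, cutoff, pairs,
                        dist_cutoff=1e30, pair_dist=None):
    """Cell-list candidate pairs of bonds with midpoint distance < cutoff
    and true segment-segment distance < dist_cutoff.

    Pairs sharing a bead are excluded.  x is periodic.  When ``pair_dist``
    is given, the segment-segment distance at build time is stored per
    pair (it lets the force loop skip pairs that cannot have entered
    interaction range yet).  Returns the number of pairs found, or -1 if
    the ``pairs`` buffer overflowed.
    """
    nb = bond_i.shape[0]
    if nb < 2:
        return 0
    mid = np.empty((nb, 3))
    for b in range(nb):
        i = bond_i[b]; j = bond_j[b]
        dx = _min_image_dx(pos[j, 0] - pos[i, 0], box_w)
        mid[b, 0] = (pos[i, 0] + 0.5 * dx) % box_w
        mid[b, 1] = 0.5 * (pos[i, 1] + pos[j, 1])
        mid[b, 2] = 0.5 * (pos[i, 2] + pos[j, 2])
    ymin = mid[:, 1].min(); ymax = mid[:, 1].max()
    zmin = mid[:, 2].min(); zmax = mid[:, 2].max()
    ncx = max(1, int(box_w / cutoff))
    csx = box_w / ncx
    ncy = max(1, int((ymax - ymin) / cutoff) + 1)
    ncz = max(1, int((zmax - zmin) / cutoff) + 1)
    ncell = ncx * ncy * ncz
    # counting sort of segments into cells
    cell_of = np.empty(nb, dtype=np.int64)
    count = np.zeros(ncell + 1, dtype=np.int64)
    for b in range(nb):
        cx = min(int(mid[b, 0] / csx), ncx - 1)
        cy = min(int((mid[b, 1] - ymin) / cutoff), ncy - 1)
        cz = min(int((mid[b, 2] - zmin) / cutoff), ncz - 1)
        c = (cz * ncy + cy) * ncx + cx
        cell_of[b] = c
        count[c + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(nb, dtype=np.int64)
    fill = count[:ncell].copy()
    for b in range(nb):
        c = cell_of[b]
        order[fill[c]] = b
        fill[c] += 1
    cut2 = cutoff * cutoff
    np_found = 0
    maxp = pairs.shape[0]
    for b in range(nb):
        cx = min(int(mid[b, 0] / csx), ncx - 1)
        cy = min(int((mid[b, 1] - ymin) / cutoff), ncy - 1)
        cz = min(int((mid[b, 2] - zmin) / cutoff), ncz - 1)
        for oz in range(-1, 2):
            z2 = cz + oz
            if z2 < 0 or z2 >= ncz:
                continue
            for oy in range(-1, 2):
                y2 = cy + oy
                if y2 < 0 or y2 >= ncy:
                    continue
                for ox in range(-1, 2):
                    x2 = (cx + ox) % ncx
                    c2 = (z2 * ncy + y2) * ncx + x2
                    for m in range(count[c2], count[c2 + 1]):
                        b2 = order[m]
                        if b2 <= b:
                            continue
                        ia = bond_i[b]; ja = bond_j[b]
                        ib = bond_i[b2]; jb = bond_j[b2]
                        if ia == ib or ia == jb or ja == ib or ja == jb:
                            continue
                        dx = _min_image_dx(mid[b, 0] - mid[b2, 0], box_w)
                        dy = mid[b, 1] - mid[b2, 1]
                        dz = mid[b, 2] - mid[b2, 2]
                        if dx * dx + dy * dy + dz * dz >= cut2:
                            continue
                        dd = 0.0
                        if dist_cutoff < 1e29:
                            shift = _image_shift(
                                mid[b, 0] - mid[b2, 0], box_w)
                            dd, _, _ = seg_seg_closest(
                                pos[ia, 0], pos[ia, 1], pos[ia, 2],
                                pos[ja, 0], pos[ja, 1], pos[ja, 2],
                                pos[ib, 0] + shift, pos[ib, 1], pos[ib, 2],
                                pos[jb, 0] + shift, pos[jb, 1], pos[jb, 2])
                            if dd >= dist_cutoff:
                                continue
                        if np_found >= maxp:
                            return -1
                        pairs[np_found, 0] = b
                        pairs[np_found, 1] = b2
                        if pair_dist is not None:
                            pair_dist[np_found] = dd
                        np_found += 1
    return np_found


@njit(cache=True)
def bead_pair_candidates(pos, fil_of_bead, box_w, dmin, dmax, pairs):
    """All inter-filament bead pairs with separation in [dmin, dmax].

    Cell list over beads; used for crosslink candidate enumeration.
    Returns count, or -1 on buffer overflow.
    """
    n = pos.shape[0]
    if n < 2:
        return 0
    cutoff = dmax
    ymin = pos[:, 1].min(); zmin = pos[:, 2].min()
    ymax = pos[:, 1].max(); zmax = pos[:, 2].max()
    ncx = max(1, int(box_w / cutoff))
    csx = box_w / ncx
    ncy = max(1, int((ymax - ymin) / cutoff) + 1)
    ncz = max(1, int((zmax - zmin) / cutoff) + 1)
    ncell = ncx * ncy * ncz
    cell_of = np.empty(n, dtype=np.int64)
    count = np.zeros(ncell + 1, dtype=np.int64)
    for b in range(n):
        cx = min(int((pos[b, 0] % box_w) / csx), ncx - 1)
        cy = min(int((pos[b, 1] - ymin) / cutoff), ncy - 1)
        cz = min(int((pos[b, 2] - zmin) / cutoff), ncz - 1)
        c = (cz * ncy + cy) * ncx + cx
        cell_of[b] = c
        count[c + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:ncell].copy()
    for b in range(n):
        c = cell_of[b]
        order[fill[c]] = b
        fill[c] += 1
    lo2 = dmin * dmin; hi2 = dmax * dmax
    found = 0
    maxp = pairs.shape[0]
    for b in range(n):
        cx = min(int((pos[b, 0] % box_w) / csx), ncx - 1)
        cy = min(int((pos[b, 1] - ymin) / cutoff), ncy - 1)
        cz = min(int((pos[b, 2] - zmin) / cutoff), ncz - 1)
        for oz in range(-1, 2):
            z2 = cz + oz
            if z2 < 0 or z2 >= ncz:
                continue
            for oy in range(-1, 2):
                y2 = cy + oy
                if y2 < 0 or y2 >= ncy:
                    continue
                for ox in range(-1, 2):
                    x2 = (cx + ox) % ncx
                    c2 = (z2 * ncy + y2) * ncx + x2
                    for m in range(count[c2], count[c2 + 1]):
                        b2 = order[m]
                        if b2 <= b:
                            continue
                        if fil_of_bead[b] == fil_of_bead[b2]:
                            continue
                        dx = _min_image_dx(pos[b, 0] - pos[b2, 0], box_w)
                        dy = pos[b, 1] - pos[b2, 1]
                        dz = pos[b, 2] - pos[b2, 2]
                        d2 = dx * dx + dy * dy + dz * dz
                        if lo2 <= d2 <= hi2:
                            if found >= maxp:
                                return -1
                            pairs[found, 0] = b
                            pairs[found, 1] = b2
                            found += 1
    return found


# ---------------------------------------------------------------------------
# energies (for gradient oracles and T=0 relaxation tests)
# ---------------------------------------------------------------------------

@njit(cache=True)
def potential_energy(pos, bond_i, bond_j, bond_rest, k_actin,
                     trip_i, trip_j, trip_k, kappa_over_l0,
                     cl_i, cl_j, cl_k, cl_rest,
                     br_i, br_j, br_k, eps_angle, cos0,
                     pairs, n_pairs, k_ex, d_ex, box_w):
    e = 0.0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]; j = bond_j[b]
        dx = _min_image_dx(pos[i, 0] - pos[j, 0], box_w)
        dy = pos[i, 1] - pos[j, 1]; dz = pos[i, 2] - pos[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * k_actin * (d - bond_rest[b]) ** 2
    for b in range(cl_i.shape[0]):
        i = cl_i[b]; j = cl_j[b]
        dx = _min_image_dx(pos[i, 0] - pos[j, 0], box_w)
        dy = pos[i, 1] - pos[j, 1]; dz = pos[i, 2] - pos[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * cl_k[b] * (d - cl_rest[b]) ** 2
    for m in range(trip_i.shape[0]):
        i = trip_i[m]; j = trip_j[m]; k = trip_k[m]
        ux = _min_image_dx(pos[j, 0] - pos[i, 0], box_w)
        uy = pos[j, 1] - pos[i, 1]; uz = pos[j, 2] - pos[i, 2]
        vx = _min_image_dx(pos[k, 0] - pos[j, 0], box_w)
        vy = pos[k, 1] - pos[j, 1]; vz = pos[k, 2] - pos[j, 2]
        lu = np.sqrt(ux * ux + uy * uy + uz * uz)
        lv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if lu < 1e-12 or lv < 1e-12:
            continue
        cth = (ux * vx + uy * vy + uz * vz) / (lu * lv)
        e += kappa_over_l0 * (1.0 - cth)
    for m in range(br_i.shape[0]):
        i = br_i[m]; j = br_j[m]; k = br_k[m]
        ux = _min_image_dx(pos[j, 0] - pos[i, 0], box_w)
        uy = pos[j, 1] - pos[i, 1]; uz = pos[j, 2] - pos[i, 2]
        vx = _min_image_dx(pos[k, 0] - pos[j, 0], box_w)
        vy = pos[k, 1] - pos[j, 1]; vz = pos[k, 2] - pos[j, 2]
        lu = np.sqrt(ux * ux + uy * uy + uz * uz)
        lv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if lu < 1e-12 or lv < 1e-12:
            continue
        cth = (ux * vx + uy * vy + uz * vz) / (lu * lv)
        e += eps_angle * (cth - cos0) ** 2
    for p in range(n_pairs):
        a = pairs[p, 0]; b = pairs[p, 1]
        ia = bond_i[a]; ja = bond_j[a]
        ib = bond_i[b]; jb = bond_j[b]
        mida = 0.5 * (pos[ia, 0] + pos[ja, 0])
        midb = 0.5 * (pos[ib, 0] + pos[jb, 0])
        shift = _image_shift(mida - midb, box_w)
        d, s, t = seg_seg_closest(
            pos[ia, 0], pos[ia, 1], pos[ia, 2],
            pos[ja, 0], pos[ja, 1], pos[ja, 2],
            pos[ib, 0] + shift, pos[ib, 1], pos[ib, 2],
            pos[jb, 0] + shift, pos[jb, 1], pos[jb, 2])
        if d < d_ex:
            e += 0.5 * k_ex * (d_ex - d) ** 2
    return e


# ---------------------------------------------------------------------------
# chunked integration
# ---------------------------------------------------------------------------

@njit(cache=True)
def advance_chunk(pos, x_wraps, zeta, bound_mask, noise,
                  bond_i, bond_j, bond_rest, k_actin,
                  trip_i, trip_j, trip_k, kappa_over_l0,
                  cl_i, cl_j, cl_k, cl_rest,
                  br_i, br_j, br_k, eps_angle, cos0,
                  fil_ptr, fil_beads,
                  f_push_total, mode, f_uniform, f_back, f_membrane,
                  y_back, membrane_z,
                  fa_p0x, fa_p0y, fa_p1x, fa_p1y, fa_halfw, fa_height,
                  box_w, box_h, f_conf, top_wall,
                  k_ex, d_ex, dt, kBT, max_disp,
                  pairs, pair_dist, bead_moved, nb_meta, pos_ref,
                  clamp_mask, clamp_vel,
                  accum, drag_accum):
    """Advance ``noise.shape[0]`` Euler-Maruyama steps with fixed topology.

    ``nb_meta``: int64[2] = (n_pairs, rebuild_flag).  ``pos_ref`` holds bead
    positions at the last neighbor build; the pair list is rebuilt (with a
    true segment-distance filter of d_ex + skin) whenever any bead moved
    more than half the skin since the build.  ``clamp_mask`` marks beads
    driven kinematically at ``clamp_vel`` (mechanical tests); they ignore
    forces.  ``accum`` ((N_CHANNELS+1, 3) float64) collects per-step sums
    of the external channels over all beads (internal channels sum to zero
    by Newton's third law and stay zero here); its last row counts
    (steps, bead-steps, pushed filament-steps).  ``drag_accum`` (2, 3)
    collects the deterministic force sum (= mean of zeta*v over thermal
    noise) for unbound (row 0) and FA-bound (row 1) beads.
    Returns a status code.
    """
    n = pos.shape[0]
    nsteps = noise.shape[0]
    skin = 0.04
    return_code = OK
    F = np.empty((n, 3))
    # per-bead displacement since the last neighbor build
    if nb_meta[0] >= 0 and nb_meta[1] == 0:
        for i in range(n):
            dx = _min_image_dx(pos[i, 0] - pos_ref[i, 0], box_w)
            dy = pos[i, 1] - pos_ref[i, 1]
            dz = pos[i, 2] - pos_ref[i, 2]
            bead_moved[i] = np.sqrt(dx * dx + dy * dy + dz * dz)
    for step in range(nsteps):
        # neighbor rebuild check
        if nb_meta[1] == 1 or nb_meta[0] < 0:
            nb_meta[1] = 0
            # midpoint cutoff: longest bond + interaction range + skin
            maxlen = 0.0
            for b in range(bond_i.shape[0]):
                i = bond_i[b]; j = bond_j[b]
                dx = _min_image_dx(pos[i, 0] - pos[j, 0], box_w)
                dy = pos[i, 1] - pos[j, 1]; dz = pos[i, 2] - pos[j, 2]
                L = np.sqrt(dx * dx + dy * dy + dz * dz)
                if L > maxlen:
                    maxlen = L
            npairs = build_segment_pairs(
                pos, bond_i, bond_j, box_w, maxlen + d_ex + skin, pairs,
                d_ex + skin, pair_dist)
            if npairs < 0:
                return PAIR_OVERFLOW
            nb_meta[0] = npairs
            nb_meta[2] += 1
            for i in range(n):
                pos_ref[i, 0] = pos[i, 0]
                pos_ref[i, 1] = pos[i, 1]
                pos_ref[i, 2] = pos[i, 2]
                bead_moved[i] = 0.0
        for i in range(n):
            F[i, 0] = 0.0; F[i, 1] = 0.0; F[i, 2] = 0.0

        spring_forces(pos, bond_i, bond_j, bond_rest, k_actin, box_w, F)
        bending_forces(pos, trip_i, trip_j, trip_k, kappa_over_l0, box_w, F)
        branch_angle_forces(pos, br_i, br_j, br_k, eps_angle, cos0, box_w, F)
        crosslink_forces(pos, cl_i, cl_j, cl_k, cl_rest, box_w, F)
        excluded_volume_forces(pos, bond_i, bond_j, pairs, nb_meta[0],
                               k_ex, d_ex, box_w, F,
                               pair_dist, bead_moved)
        if f_push_total != 0.0:
            npush = leading_edge_forces(pos, fil_ptr, fil_beads,
                                        f_push_total, box_w, F,
                                        accum[CH_LEADING])
            accum[N_CHANNELS, 2] += npush
        motor_forces(pos, fil_ptr, fil_beads, mode, f_uniform, f_back,
                     f_membrane, y_back, membrane_z, fa_p0x, fa_p0y,
                     fa_p1x, fa_p1y, fa_halfw, fa_height, box_w, F,
                     accum[CH_MOTOR])
        confinement_forces(pos, box_h, f_conf, top_wall, F,
                           accum[CH_CONFINE])

        # thermal + integration
        moved = 0.0
        for i in range(n):
            if clamp_mask[i]:
                pos[i, 0] += clamp_vel[i, 0] * dt
                pos[i, 1] += clamp_vel[i, 1] * dt
                pos[i, 2] += clamp_vel[i, 2] * dt
            else:
                amp = np.sqrt(2.0 * kBT * zeta[i] / dt)
                ftx = amp * noise[step, i, 0]
                fty = amp * noise[step, i, 1]
                ftz = amp * noise[step, i, 2]
                accum[CH_THERMAL, 0] += ftx
                accum[CH_THERMAL, 1] += fty
                accum[CH_THERMAL, 2] += ftz
                if bound_mask[i]:
                    drag_accum[1, 0] += F[i, 0]
                    drag_accum[1, 1] += F[i, 1]
                    drag_accum[1, 2] += F[i, 2]
                else:
                    drag_accum[0, 0] += F[i, 0]
                    drag_accum[0, 1] += F[i, 1]
                    drag_accum[0, 2] += F[i, 2]
                inv = dt / zeta[i]
                # instability test on the force-driven part only: thermal
                # kicks are legitimately large at small dt
                det = (abs(F[i, 0]) + abs(F[i, 1]) + abs(F[i, 2])) * inv
                if det > max_disp:
                    return_code = UNSTABLE
                pos[i, 0] += (F[i, 0] + ftx) * inv
                pos[i, 1] += (F[i, 1] + fty) * inv
                pos[i, 2] += (F[i, 2] + ftz) * inv
            # wrap x with counter
            if pos[i, 0] >= box_w:
                w = int(pos[i, 0] // box_w)
                pos[i, 0] -= w * box_w
                x_wraps[i] += w
            elif pos[i, 0] < 0.0:
                w = int(np.floor(pos[i, 0] / box_w))
                pos[i, 0] -= w * box_w
                x_wraps[i] += w
                if pos[i, 0] >= box_w:   # -tiny folded onto the boundary
                    pos[i, 0] -= box_w
                    x_wraps[i] += 1
            dx = _min_image_dx(pos[i, 0] - pos_ref[i, 0], box_w)
            dy = pos[i, 1] - pos_ref[i, 1]
            dz = pos[i, 2] - pos_ref[i, 2]
            dd = dx * dx + dy * dy + dz * dz
            bead_moved[i] = np.sqrt(dd)
            if dd > moved:
                moved = dd
        accum[N_CHANNELS, 0] += 1.0        # step counter
        accum[N_CHANNELS, 1] += n          # bead-steps
        if np.sqrt(moved) > 0.5 * skin:
            nb_meta[1] = 1
        if return_code != OK:
            return return_code
    return return_code
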