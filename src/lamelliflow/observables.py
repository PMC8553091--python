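"""Measured quantities: flow and density profiles, bond tension, filament
bending, force balance and the virial stress tensor.

Profiles are resolved along y (distance from the leading edge); maps are
xy grids averaged over time and z.  Stresses are reported in Pa
(1 pN/um^2 = 1 Pa), with tension positive under extension, so that
sigma_T = sigma_yy - (sigma_xx + sigma_zz)/2 is positive when the network
is stretched along the flow direction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .params import AVOGADRO_UM3
from .state import NetworkState
from .integrator import Frame


@dataclass
class Profile1D:
    """Binned profile along y."""
    edges: np.ndarray
    value: np.ndarray          # nan where a bin had no samples
    count: np.ndarray
    window: float = 0.0        # averaging window [s]

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class Map2D:
    """xy grid averaged over time and z."""
    x_edges: np.ndarray
    y_edges: np.ndarray
    value: np.ndarray
    count: np.ndarray


@dataclass
class StressTensor:
    """Virial stress over a stated volume (Pa)."""
    sigma: np.ndarray          # (3, 3), symmetric
    volume: float

    @property
    def sigma_T(self) -> float:
        s = self.sigma
        return float(s[1, 1] - 0.5 * (s[0, 0] + s[2, 2]))


# ---------------------------------------------------------------------------
# flow
# ---------------------------------------------------------------------------

def _frame_pairs(frames: Sequence[Frame], lag: float) -> List[Tuple[Frame, Frame]]:
    pairs = []
    times = np.array([f.t for f in frames])
    for i, f0 in enumerate(frames):
        target = f0.t + lag
        j = int(np.argmin(np.abs(times - target)))
        if j > i and abs(times[j] - target) < 0.26 * lag:
            pairs.append((f0, frames[j]))
    return pairs


def bead_velocities(f0: Frame, f1: Frame) -> Tuple[np.ndarray, np.ndarray]:
    """Per-bead (y position, dy/dt) for beads present in both frames,
    matched by persistent uid."""
    common, i0, i1 = np.intersect1d(f0.uid, f1.uid, return_indices=True)
    dt = f1.t - f0.t
    vy = (f1.pos[i1, 1] - f0.pos[i0, 1]) / dt
    y_mid = 0.5 * (f0.pos[i0, 1] + f1.pos[i1, 1])
    return y_mid, vy


def retrograde_flow_profile(frames: Sequence[Frame], edges: np.ndarray,
                            lag: float = 1.0) -> Profile1D:
    """Mean dy/dt per y bin (positive = retrograde), finite-differenced
    over frame pairs ``lag`` seconds apart and matched by bead uid."""
    edges = np.asarray(edges, dtype=float)
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    total = np.zeros(edges.size - 1)
    count = np.zeros(edges.size - 1)
    pairs = _frame_pairs(frames, lag)
    if not pairs:   # fall back to consecutive frames
        pairs = list(zip(frames[:-1], frames[1:]))
    for f0, f1 in pairs:
        y, vy = bead_velocities(f0, f1)
        idx = np.digitize(y, edges) - 1
        ok = (idx >= 0) & (idx < edges.size - 1)
        np.add.at(total, idx[ok], vy[ok])
        np.add.at(count, idx[ok], 1)
    value = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    window = frames[-1].t - frames[0].t
    return Profile1D(edges, value, count, window)


def mean_retrograde_speed(frames: Sequence[Frame], lag: float = 1.0) -> float:
    """All-bead average dy/dt over the frame window [um/s]."""
    pairs = _frame_pairs(frames, lag)
    if not pairs:
        pairs = list(zip(frames[:-1], frames[1:]))
    vals = [bead_velocities(f0, f1)[1] for f0, f1 in pairs]
    return float(np.mean(np.concatenate(vals)))


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def density_profile(frames: Sequence[Frame] | Frame, edges: np.ndarray,
                    box_width: float, box_height: float) -> Profile1D:
    """F-actin concentration (uM) per y bin.

    Each bond carries 37 monomers, half attributed to each endpoint bead;
    the per-bin monomer count is divided by the bin volume
    box_width * dy * box_height.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    edges = np.asarray(edges, dtype=float)
    total = np.zeros(edges.size - 1)
    for f in frames:
        idx = np.digitize(f.pos[:, 1], edges) - 1
        ok = (idx >= 0) & (idx < edges.size - 1)
        np.add.at(total, idx[ok], f.monomers[ok])
    total /= len(frames)
    vol = box_width * np.diff(edges) * box_height
    conc = total / (AVOGADRO_UM3 * vol)
    return Profile1D(edges, conc, total)


def frame_from_state(state: NetworkState) -> Frame:
    """Snapshot the state into an observable frame."""
    p = state.packed()
    half = state.params.monomers_per_segment / 2.0
    mono = np.zeros(state.n_beads)
    np.add.at(mono, p["bond_i"], half)
    np.add.at(mono, p["bond_j"], half)
    return Frame(t=state.t, uid=state.uid.copy(), pos=state.pos.copy(),
                 x_unwrapped=state.unwrapped_x(),
                 fa_bound=state.fa_bound.copy(), monomers=mono)


# ---------------------------------------------------------------------------
# bond tension
# ---------------------------------------------------------------------------

def bond_tensions(state: NetworkState) -> Tuple[np.ndarray, np.ndarray]:
    """Per actin bond: midpoint (x, y) and scalar k*(l0 - d).

    Positive values mean compression (bond shorter than rest length),
    negative extension.
    """
    p = state.packed()
    prm = state.params
    d = state.pos[p["bond_j"]] - state.pos[p["bond_i"]]
    dx = np.mod(d[:, 0], prm.box_width)
    d[:, 0] = np.where(dx > prm.box_width / 2, dx - prm.box_width, dx)
    dist = np.linalg.norm(d, axis=1)
    tension = prm.k_actin * (p["bond_rest"] - dist)
    mid = state.pos[p["bond_i"]] + 0.5 * d
    mid[:, 0] = np.mod(mid[:, 0], prm.box_width)
    return mid[:, :2], tension


def bond_tension_map(states: Iterable[NetworkState] | NetworkState,
                     x_edges: np.ndarray, y_edges: np.ndarray) -> Map2D:
    """Time- and z-averaged bond tension on an xy grid (pN)."""
    if isinstance(states, NetworkState):
        states = [states]
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    total = np.zeros((x_edges.size - 1, y_edges.size - 1))
    count = np.zeros_like(total)
    for st in states:
        mid, tension = bond_tensions(st)
        ix = np.digitize(mid[:, 0], x_edges) - 1
        iy = np.digitize(mid[:, 1], y_edges) - 1
        ok = (ix >= 0) & (ix < total.shape[0]) & (iy >= 0) \
            & (iy < total.shape[1])
        np.add.at(total, (ix[ok], iy[ok]), tension[ok])
        np.add.at(count, (ix[ok], iy[ok]), 1)
    value = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return Map2D(x_edges, y_edges, value, count)


# ---------------------------------------------------------------------------
# filament bending
# ---------------------------------------------------------------------------

def bending_angle_samples(state: NetworkState) -> Tuple[np.ndarray, np.ndarray]:
    """(middle-bead y, chord angle in degrees) for intact full-length
    filaments.

    The angle is between the two half-filament chords (bead 0 -> middle
    bead and middle bead -> last bead); severed fragments are skipped.
    """
    n_full = state.params.beads_per_filament
    mid_idx = n_full // 2
    ys, angles = [], []
    w = state.params.box_width
    for beads in state.filaments:
        if beads.size != n_full:
            continue
        r0 = state.pos[beads[0]]
        rm = state.pos[beads[mid_idx]]
        r1 = state.pos[beads[-1]]
        c1 = rm - r0
        c2 = r1 - rm
        for c in (c1, c2):
            dx = c[0] % w
            c[0] = dx - w if dx > w / 2 else dx
        cosang = (c1 @ c2) / (np.linalg.norm(c1) * np.linalg.norm(c2))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        ys.append(rm[1])
    return np.asarray(ys), np.asarray(angles)


def bending_angle_profile(samples: Sequence[Tuple[np.ndarray, np.ndarray]],
                          edges: np.ndarray) -> Tuple[Profile1D, Profile1D]:
    """Aggregate (y, angle) samples into mean and upper-quartile profiles."""
    edges = np.asarray(edges, dtype=float)
    nb = edges.size - 1
    per_bin: List[List[float]] = [[] for _ in range(nb)]
    for ys, angles in samples:
        idx = np.digitize(ys, edges) - 1
        for k, a in zip(idx, angles):
            if 0 <= k < nb:
                per_bin[k].append(a)
    mean = np.array([np.mean(b) if b else np.nan for b in per_bin])
    uq = np.array([np.percentile(b, 75) if b else np.nan for b in per_bin])
    count = np.array([len(b) for b in per_bin], dtype=float)
    return (Profile1D(edges, mean, count),
            Profile1D(edges, uq, count))


# ---------------------------------------------------------------------------
# force balance
# ---------------------------------------------------------------------------

def force_balance_summary(accum: np.ndarray, drag_accum: np.ndarray,
                          box_width: float) -> dict:
    """Time-averaged force balance from the integrator accumulators.

    Returns y components of each channel, per um of leading edge and per
    bead, plus the closure residual push + pull + internal + thermal
    (which the overdamped dynamics balances against total drag).
    """
    from ._kernels import (CH_SPRING, CH_BEND, CH_CROSSLINK, CH_EXCLUDED,
                           CH_LEADING, CH_MOTOR, CH_CONFINE, CH_THERMAL,
                           N_CHANNELS)
    steps = accum[N_CHANNELS, 0]
    bead_steps = accum[N_CHANNELS, 1]
    if steps == 0:
        raise ValueError("no accumulated steps")
    mean_beads = bead_steps / steps
    out = {}
    channels = {"push": CH_LEADING, "pull": CH_MOTOR, "confine": CH_CONFINE,
                "thermal": CH_THERMAL, "spring": CH_SPRING, "bend": CH_BEND,
                "crosslink": CH_CROSSLINK, "excluded": CH_EXCLUDED}
    for name, ch in channels.items():
        mean_y = accum[ch, 1] / steps
        out[f"{name}_per_um"] = mean_y / box_width
        out[f"{name}_per_bead"] = mean_y / max(mean_beads, 1.0)
    for row, name in ((0, "fluid_drag"), (1, "fa_drag")):
        mean_y = drag_accum[row, 1] / steps
        out[f"{name}_per_um"] = mean_y / box_width
        out[f"{name}_per_bead"] = mean_y / max(mean_beads, 1.0)
    # drag rows already contain the deterministic force sum zeta*v averaged
    # over thermal noise; closure: drive - drag ~ 0
    out["residual_per_um"] = (out["push_per_um"] + out["pull_per_um"]
                              + out["confine_per_um"] + out["spring_per_um"]
                              + out["bend_per_um"] + out["crosslink_per_um"]
                              + out["excluded_per_um"]
                              - out["fluid_drag_per_um"]
                              - out["fa_drag_per_um"])
    out["mean_beads"] = mean_beads
    out["n_pushed_filaments"] = accum[N_CHANNELS, 2] / steps
    return out


# ---------------------------------------------------------------------------
# virial stress
# ---------------------------------------------------------------------------

def virial_stress(state: NetworkState, volume: float,
                  selection: Optional[np.ndarray] = None,
                  pairs: Optional[np.ndarray] = None) -> StressTensor:
    """Virial stress tensor over the selected beads (Pa).

    Pairwise interactions (bonds, crosslinks, excluded volume) contribute
    T * d * (d_hat x d_hat) / V with T the pair tension (positive when the
    pair pulls its beads together, i.e. a stretched spring); three-body
    bending/branch terms are decomposed about the triplet centroid.  Each
    interaction is weighted by the fraction of its beads inside the
    selection (clamped beads are excluded by the caller's selection mask).
    """
    from .integrator import build_neighbor_pairs
    from . import _kernels as K
    if volume <= 0:
        raise ValueError("volume must be positive")
    prm = state.params
    w = prm.box_width
    n = state.n_beads
    sel = np.ones(n, dtype=bool) if selection is None else selection
    selw = sel.astype(float)
    sigma = np.zeros((3, 3))
    p = state.packed()

    def mi(d):
        dx = np.mod(d[..., 0], w)
        d[..., 0] = np.where(dx > w / 2, dx - w, dx)
        return d

    def add_pairs(i_arr, j_arr, k_arr, rest_arr):
        if i_arr.size == 0:
            return
        d = mi(state.pos[i_arr] - state.pos[j_arr])
        dist = np.linalg.norm(d, axis=1)
        T = k_arr * (dist - rest_arr)          # >0 when stretched
        wgt = 0.5 * (selw[i_arr] + selw[j_arr])
        coef = wgt * T / np.maximum(dist, 1e-12)
        sigma[:] += np.einsum("b,bi,bj->ij", coef, d, d)

    add_pairs(p["bond_i"], p["bond_j"],
              np.full(p["bond_i"].size, prm.k_actin), p["bond_rest"])
    add_pairs(state.cl_i, state.cl_j, state.cl_k, state.cl_rest)

    # excluded volume: repulsive closest-approach pairs
    if pairs is None:
        pairs = build_neighbor_pairs(state).pairs
    bi, bj = p["bond_i"], p["bond_j"]
    for a, b in pairs:
        ia, ja, ib, jb = bi[a], bj[a], bi[b], bj[b]
        mida = 0.5 * (state.pos[ia, 0] + state.pos[ja, 0])
        midb = 0.5 * (state.pos[ib, 0] + state.pos[jb, 0])
        shift = w * np.rint((mida - midb) / w)
        q0 = state.pos[ib].copy(); q0[0] += shift
        q1 = state.pos[jb].copy(); q1[0] += shift
        d, s, t = K.seg_seg_closest(
            state.pos[ia, 0], state.pos[ia, 1], state.pos[ia, 2],
            state.pos[ja, 0], state.pos[ja, 1], state.pos[ja, 2],
            q0[0], q0[1], q0[2], q1[0], q1[1], q1[2])
        if d >= prm.d_excluded or d < 1e-12:
            continue
        ca = state.pos[ia] + s * (state.pos[ja] - state.pos[ia])
        cb = q0 + t * (q1 - q0)
        dvec = ca - cb
        T = -prm.k_excluded * (prm.d_excluded - d)   # compressive pair
        wgt = 0.25 * (selw[ia] + selw[ja] + selw[ib] + selw[jb])
        sigma[:] += wgt * T / d * np.outer(dvec, dvec)

    # three-body terms about the triplet centroid: sum_a F_a (x) (r_a - rc)
    def add_triplets(ti, tj, tk, force_fn):
        for i, j, k in zip(ti, tj, tk):
            Fi, Fj, Fk = force_fn(int(i), int(j), int(k))
            ri = state.pos[i].copy()
            rj = mi((state.pos[j] - state.pos[i])[None, :])[0] + ri
            rk = mi((state.pos[k] - state.pos[j])[None, :])[0] + rj
            rc = (ri + rj + rk) / 3.0
            wgt = (selw[i] + selw[j] + selw[k]) / 3.0
            contrib = (np.outer(Fi, ri - rc) + np.outer(Fj, rj - rc)
                       + np.outer(Fk, rk - rc))
            sigma[:] += -wgt * contrib

    def bend_force(i, j, k):
        return _triplet_forces(state, i, j, k, kind="bend")

    def branch_force(i, j, k):
        return _triplet_forces(state, i, j, k, kind="branch")

    add_triplets(p["trip_i"], p["trip_j"], p["trip_k"], bend_force)
    add_triplets(state.br_i, state.br_j, state.br_k, branch_force)

    sigma[:] = 0.5 * (sigma + sigma.T)
    return StressTensor(sigma / volume, volume)


def _triplet_forces(state: NetworkState, i: int, j: int, k: int,
                    kind: str):
    """Forces of one bending or branch-angle triplet (matching the force
    kernels' conventions)."""
    prm = state.params
    w = prm.box_width

    def mi1(d):
        dx = d[0] % w
        d[0] = dx - w if dx > w / 2 else dx
        return d

    u = mi1(state.pos[j] - state.pos[i])
    v = mi1(state.pos[k] - state.pos[j])
    lu = np.linalg.norm(u)
    lv = np.linalg.norm(v)
    uh, vh = u / lu, v / lv
    c = float(uh @ vh)
    gi = -(vh - c * uh) / lu
    gk = (uh - c * vh) / lv
    if kind == "bend":
        pref = prm.kappa_bend / prm.l0
    else:
        cos0 = np.cos(np.deg2rad(prm.theta_0))
        pref = -2.0 * prm.eps_angle * (c - cos0)
    Fi = pref * gi
    Fk = pref * gk
    Fj = -(Fi + Fk)
    return Fi, Fj, Fk


# ---------------------------------------------------------------------------
# bundling diagnostics
# ---------------------------------------------------------------------------

def nematic_order(state: NetworkState, y_range: Tuple[float, float]) -> float:
    """2D nematic order parameter of segment orientations (xy projection)
    for bonds whose midpoints fall in ``y_range``.

    S = 1 for perfectly aligned segments, ~0 for isotropic.
    """
    p = state.packed()
    prm = state.params
    d = state.pos[p["bond_j"]] - state.pos[p["bond_i"]]
    dx = np.mod(d[:, 0], prm.box_width)
    d[:, 0] = np.where(dx > prm.box_width / 2, dx - prm.box_width, dx)
    mid_y = state.pos[p["bond_i"], 1] + 0.5 * d[:, 1]
    ok = (mid_y >= y_range[0]) & (mid_y <= y_range[1])
    d = d[ok][:, :2]
    if d.shape[0] < 2:
        return np.nan
    norms = np.linalg.norm(d, axis=1)
    d = d[norms > 1e-12] / norms[norms > 1e-12][:, None]
    # 2D nematic: S = sqrt(<cos 2a>^2 + <sin 2a>^2)
    c2 = 2 * d[:, 0] ** 2 - 1.0
    s2 = 2 * d[:, 0] * d[:, 1]
    return float(np.hypot(c2.mean(), s2.mean()))


def x_density_histogram(state: NetworkState, edges: np.ndarray,
                        y_range: Tuple[float, float]) -> np.ndarray:
    """Monomer-weighted histogram of bead x positions within a y band
    (microspike bundles appear as persistent peaks)."""
    edges = np.asarray(edges, dtype=float)
    f = frame_from_state(state)
    ok = (f.pos[:, 1] >= y_range[0]) & (f.pos[:, 1] <= y_range[1])
    hist, _ = np.histogram(f.pos[ok, 0], bins=edges, weights=f.monomers[ok])
    return hist
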