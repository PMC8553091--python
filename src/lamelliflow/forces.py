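"""Force channels of the overdamped equation of motion.

Each bead obeys  zeta_i dr_i/dt = F_spring + F_bend + F_crosslink +
F_excluded + F_leading + F_motor + F_confine + F_thermal, and every
function here evaluates one channel as an (N, 3) array in pN.

The internal channels (spring, bend, crosslink, excluded, branch angle)
are gradients of potentials and sum to zero over all beads; only the
leading-edge push, motor pull, confinement and thermal channels inject net
momentum.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels as K
from .state import NetworkState

MOTOR_MODES = {"uniform": K.MODE_UNIFORM, "back": K.MODE_BACK,
               "membrane": K.MODE_MEMBRANE}


@dataclass
class ForceBreakdown:
    """Per-bead forces split by channel (pN)."""
    spring: np.ndarray
    bend: np.ndarray
    crosslink: np.ndarray
    excluded: np.ndarray
    leading: np.ndarray
    motor: np.ndarray
    confine: np.ndarray
    branch_angle: np.ndarray
    thermal: Optional[np.ndarray] = None

    def total(self) -> np.ndarray:
        tot = (self.spring + self.bend + self.crosslink + self.excluded
               + self.leading + self.motor + self.confine + self.branch_angle)
        if self.thermal is not None:
            tot = tot + self.thermal
        return tot


def _zeros(state: NetworkState) -> np.ndarray:
    return np.zeros((state.n_beads, 3))


def spring_forces(state: NetworkState) -> np.ndarray:
    p = state.packed()
    F = _zeros(state)
    bad = K.spring_forces(state.pos, p["bond_i"], p["bond_j"], p["bond_rest"],
                          state.params.k_actin, state.params.box_width, F)
    if bad:
        raise FloatingPointError(f"{bad} actin bond(s) have zero length")
    return F


def bending_forces(state: NetworkState) -> np.ndarray:
    p = state.packed()
    F = _zeros(state)
    K.bending_forces(state.pos, p["trip_i"], p["trip_j"], p["trip_k"],
                     state.params.kappa_bend / state.params.l0,
                     state.params.box_width, F)
    return F


def crosslink_forces(state: NetworkState) -> np.ndarray:
    F = _zeros(state)
    bad = K.crosslink_forces(state.pos, state.cl_i, state.cl_j, state.cl_k,
                             state.cl_rest, state.params.box_width, F)
    if bad:
        raise FloatingPointError(f"{bad} crosslink(s) have zero length")
    return F


def branch_angle_forces(state: NetworkState) -> np.ndarray:
    F = _zeros(state)
    K.branch_angle_forces(state.pos, state.br_i, state.br_j, state.br_k,
                          state.params.eps_angle,
                          np.cos(np.deg2rad(state.params.theta_0)),
                          state.params.box_width, F)
    return F


def segment_closest_approach(seg_a: np.ndarray, seg_b: np.ndarray,
                             box_width: Optional[float] = None):
    """Closest approach between two 3D segments given as (2, 3) arrays.

    Returns (distance, point_on_a, point_on_b, (s, t)) where s and t are
    the barycentric weights of the closest points along each segment.  When
    ``box_width`` is given the minimum image along x (from midpoints) is
    used.
    """
    a = np.asarray(seg_a, dtype=float)
    b = np.asarray(seg_b, dtype=float).copy()
    for seg in (a, b):
        if np.linalg.norm(seg[1] - seg[0]) == 0.0:
            raise ValueError("zero-length segment")
    if box_width is not None:
        mida = 0.5 * (a[0, 0] + a[1, 0])
        midb = 0.5 * (b[0, 0] + b[1, 0])
        b[:, 0] += box_width * np.rint((mida - midb) / box_width)
    d, s, t = K.seg_seg_closest(a[0, 0], a[0, 1], a[0, 2],
                                a[1, 0], a[1, 1], a[1, 2],
                                b[0, 0], b[0, 1], b[0, 2],
                                b[1, 0], b[1, 1], b[1, 2])
    pa = a[0] + s * (a[1] - a[0])
    pb = b[0] + t * (b[1] - b[0])
    return d, pa, pb, (s, t)


def excluded_volume_forces(state: NetworkState,
                           pairs: Optional[np.ndarray] = None) -> np.ndarray:
    """Excluded-volume channel; ``pairs`` are candidate bond-index pairs
    (built by the integrator's neighbor search when omitted)."""
    from .integrator import build_neighbor_pairs
    p = state.packed()
    if pairs is None:
        pairs = build_neighbor_pairs(state).pairs
    F = _zeros(state)
    K.excluded_volume_forces(state.pos, p["bond_i"], p["bond_j"],
                             np.ascontiguousarray(pairs, dtype=np.int64),
                             pairs.shape[0], state.params.k_excluded,
                             state.params.d_excluded,
                             state.params.box_width, F)
    return F


def leading_edge_forces(state: NetworkState) -> np.ndarray:
    """Polymerization push: filaments with any bead at y <= 0 receive the
    configured total force split equally over all their beads, along the
    barbed-to-pointed direction of the pointed-end segment."""
    p = state.packed()
    F = _zeros(state)
    K.leading_edge_forces(state.pos, p["fil_ptr"], p["fil_beads"],
                          state.params.F_push_total,
                          state.params.box_width, F, np.zeros(3))
    return F


def motor_forces(state: NetworkState, mode: Optional[str] = None) -> np.ndarray:
    mode = state.params.pull_mode if mode is None else mode
    if mode not in MOTOR_MODES:
        raise ValueError(f"unknown pull mode {mode!r}")
    p = state.packed()
    prm = state.params
    fa = state.fa
    F = _zeros(state)
    K.motor_forces(state.pos, p["fil_ptr"], p["fil_beads"],
                   MOTOR_MODES[mode], prm.F_pull_uniform, prm.F_pull_back,
                   prm.F_pull_membrane, prm.y_back_threshold, prm.membrane_z,
                   fa.p0[0], fa.p0[1], fa.p1[0], fa.p1[1],
                   fa.width / 2.0, fa.height, prm.box_width, F,
                   np.zeros(3))
    return F


def confinement_forces(state: NetworkState) -> np.ndarray:
    F = _zeros(state)
    K.confinement_forces(state.pos, state.params.box_height,
                         state.params.confine_force,
                         state.params.top_wall, F, np.zeros(3))
    return F


def thermal_forces(state: NetworkState, dt: Optional[float] = None,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One thermal-force sample: independent Gaussians with per-component
    variance 2 kBT zeta_eff / dt.  Bound beads use their elevated drag so
    that fluctuation and dissipation stay consistent."""
    dt = state.params.dt if dt is None else dt
    rng = state.rng if rng is None else rng
    zeta = effective_drag_array(state)
    amp = np.sqrt(2.0 * state.params.kBT * zeta / dt)
    return amp[:, None] * rng.standard_normal((state.n_beads, 3))


def effective_drag_array(state: NetworkState) -> np.ndarray:
    """Per-bead drag: zeta_b, elevated by kappa_FA while FA-bound."""
    zeta = np.full(state.n_beads, state.params.zeta_b)
    zeta[state.fa_bound] *= state.fa.kappa_FA
    return zeta


def force_breakdown(state: NetworkState, with_thermal: bool = False,
                    pairs: Optional[np.ndarray] = None) -> ForceBreakdown:
    """Evaluate every deterministic channel (optionally plus one thermal
    sample) for the current configuration."""
    return ForceBreakdown(
        spring=spring_forces(state),
        bend=bending_forces(state),
        crosslink=crosslink_forces(state),
        excluded=excluded_volume_forces(state, pairs),
        leading=leading_edge_forces(state),
        motor=motor_forces(state),
        confine=confinement_forces(state),
        branch_angle=branch_angle_forces(state),
        thermal=thermal_forces(state) if with_thermal else None,
    )


def potential_energy(state: NetworkState,
                     pairs: Optional[np.ndarray] = None) -> float:
    """Total potential energy (spring + bend + crosslink + branch +
    excluded volume) in pN.um."""
    from .integrator import build_neighbor_pairs
    p = state.packed()
    if pairs is None:
        pairs = build_neighbor_pairs(state).pairs
    prm = state.params
    return float(K.potential_energy(
        state.pos, p["bond_i"], p["bond_j"], p["bond_rest"], prm.k_actin,
        p["trip_i"], p["trip_j"], p["trip_k"], prm.kappa_bend / prm.l0,
        state.cl_i, state.cl_j, state.cl_k, state.cl_rest,
        state.br_i, state.br_j, state.br_k, prm.eps_angle,
        np.cos(np.deg2rad(prm.theta_0)),
        np.ascontiguousarray(pairs, dtype=np.int64), pairs.shape[0],
        prm.k_excluded, prm.d_excluded, prm.box_width))
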