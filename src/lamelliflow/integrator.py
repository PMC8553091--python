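"""Overdamped (Euler-Maruyama) time stepping and neighbor search.

The equation of motion is first-order in time: each bead moves by
(sum of forces / effective drag) * dt per step, with thermal forces drawn
fresh every step.  The driver advances the system in chunks of up to 250
steps during which the topology is frozen; remodeling events (adhesion
binding, bond expiry, filament insertion, dynamic crosslink refresh) run
between chunks, with chunk boundaries aligned so that the 0.025 s
crosslinker cadence, scheduled bond expiries and requested end times are
always hit exactly.  Everything is counted in integer steps, so a run is a
deterministic function of (parameters, seed) and can be split at any
chunk boundary without changing the trajectory.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional

import numpy as np

from . import _kernels as K
from . import events as ev
from .forces import MOTOR_MODES, effective_drag_array
from .params import Parameters
from .state import NetworkState

MAX_CHUNK = 250            # steps with frozen topology (memory: noise block)
SKIN = 0.04                # neighbor-list skin [um]


class InstabilityError(RuntimeError):
    """A bead moved more than half a rest length in one step."""


def effective_drag(fa_bound: bool, params: Parameters) -> float:
    """Drag of one bead: zeta_b, times kappa_FA while FA-bound."""
    return params.zeta_b * (params.kappa_FA if fa_bound else 1.0)


@dataclass
class NeighborList:
    """Candidate segment (bond) pairs within interaction range + skin."""
    pairs: np.ndarray          # (P, 2) bond indices
    cutoff: float              # midpoint-distance cutoff used [um]
    skin: float = SKIN

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


def build_neighbor_pairs(state: NetworkState,
                         skin: float = SKIN) -> NeighborList:
    """All bond pairs whose segments can be closer than
    d_excluded + skin, respecting the periodic x direction; pairs sharing
    a bead are excluded."""
    p = state.packed()
    nb = p["bond_i"].shape[0]
    if nb < 2:
        return NeighborList(np.zeros((0, 2), dtype=np.int64), 0.0, skin)
    d = state.pos[p["bond_j"]] - state.pos[p["bond_i"]]
    dx = np.mod(d[:, 0], state.params.box_width)
    d[:, 0] = np.where(dx > state.params.box_width / 2,
                       dx - state.params.box_width, dx)
    maxlen = float(np.linalg.norm(d, axis=1).max())
    cutoff = maxlen + state.params.d_excluded + skin
    cap = max(64, 64 * nb)
    while True:
        buf = np.empty((cap, 2), dtype=np.int64)
        found = K.build_segment_pairs(state.pos, p["bond_i"], p["bond_j"],
                                      state.params.box_width, cutoff, buf,
                                      state.params.d_excluded + skin)
        if found >= 0:
            return NeighborList(buf[:found].copy(), cutoff, skin)
        cap *= 2


@dataclass
class Frame:
    """Light trajectory frame used by the observables."""
    t: float
    uid: np.ndarray
    pos: np.ndarray            # wrapped x
    x_unwrapped: np.ndarray
    fa_bound: np.ndarray
    monomers: np.ndarray       # per-bead monomer attribution (37/2 per bond)


class Simulation:
    """Driver binding a :class:`NetworkState` to the integration kernels.

    Parameters
    ----------
    state : the network to evolve (modified in place)
    enable_spawn : insert filaments at the configured rate
    spawn_mode : "fan" | "vertical_near" | "vertical_random" | "branch"
    enable_turnover : age-based bond severing
    enable_dynamic : dynamic crosslink replenishment
    enable_push : leading-edge pushing force
    record_interval : trajectory frame cadence in seconds (None: no frames)
    """

    def __init__(self, state: NetworkState, *,
                 enable_spawn: bool = True,
                 spawn_mode: str = "fan",
                 enable_turnover: bool = True,
                 enable_dynamic: bool = True,
                 enable_push: bool = True,
                 enable_fa_kinetics: bool = True,
                 record_interval: Optional[float] = None):
        self.state = state
        self.enable_spawn = enable_spawn
        self.spawn_mode = spawn_mode
        self.enable_turnover = enable_turnover
        self.enable_dynamic = enable_dynamic
        self.enable_push = enable_push
        self.enable_fa_kinetics = enable_fa_kinetics
        self.record_interval = record_interval
        self.frames: List[Frame] = []
        self.crossings = 0

        prm = state.params
        self._step = int(round(state.t / prm.dt))
        self._cadence = max(1, int(round(prm.crosslink_refresh_interval
                                         / prm.dt)))
        self._record_steps = (None if record_interval is None else
                              max(1, int(round(record_interval / prm.dt))))
        # chunk accumulators (channel force sums; see _kernels.advance_chunk)
        self.accum = np.zeros((K.N_CHANNELS + 1, 3))
        self.drag_accum = np.zeros((2, 3))
        self._alloc()

    # -- buffers -----------------------------------------------------------

    def _alloc(self) -> None:
        n = self.state.n_beads
        nb = max(1, self.state.packed()["bond_i"].shape[0])
        self._pairs = np.empty((max(64, 40 * nb), 2), dtype=np.int64)
        self._pair_dist = np.empty(self._pairs.shape[0])
        self._nb_meta = np.array([-1, 1, 0], dtype=np.int64)  # force rebuild
        self._pos_ref = np.zeros((n, 3))
        self._bead_moved = np.zeros(n)
        self.clamp_mask = np.zeros(n, dtype=bool)
        self.clamp_vel = np.zeros((n, 3))
        self._zeta = effective_drag_array(self.state)

    def _after_topology_change(self) -> None:
        n = self.state.n_beads
        if n != self.clamp_mask.shape[0]:
            # bead renumbering invalidates clamp bookkeeping
            if self.clamp_mask.any():
                raise RuntimeError(
                    "bead count changed with clamped beads active")
            self.clamp_mask = np.zeros(n, dtype=bool)
            self.clamp_vel = np.zeros((n, 3))
        self._pos_ref = np.zeros((n, 3))
        self._bead_moved = np.zeros(n)
        nb = max(1, self.state.packed()["bond_i"].shape[0])
        if self._pairs.shape[0] < 40 * nb:
            self._pairs = np.empty((max(64, 40 * nb), 2), dtype=np.int64)
            self._pair_dist = np.empty(self._pairs.shape[0])
        self._nb_meta[0] = -1
        self._nb_meta[1] = 1
        self._zeta = effective_drag_array(self.state)

    def reset_accumulators(self) -> None:
        self.accum[:] = 0.0
        self.drag_accum[:] = 0.0

    # -- stepping ----------------------------------------------------------

    def _next_expiry_step(self) -> int:
        st = self.state
        dt = st.params.dt
        taus = [st.packed()["bond_tau"], st.cl_tau]
        tau_min = min((float(a.min()) for a in taus if a.size),
                      default=np.inf)
        if not np.isfinite(tau_min):
            return 1 << 60
        return max(self._step + 1, int(np.ceil(tau_min / dt)))

    def _run_chunk(self, n_steps: int) -> None:
        st = self.state
        prm = st.params
        p = st.packed()
        fa = st.fa
        while n_steps > 0:
            n = min(n_steps, MAX_CHUNK)
            noise = st.rng.standard_normal((n, st.n_beads, 3),
                                           dtype=np.float32)
            steps_before = self.accum[K.N_CHANNELS, 0]
            status = K.advance_chunk(
                st.pos, st.x_wraps, self._zeta, st.fa_bound, noise,
                p["bond_i"], p["bond_j"], p["bond_rest"], prm.k_actin,
                p["trip_i"], p["trip_j"], p["trip_k"],
                prm.kappa_bend / prm.l0,
                st.cl_i, st.cl_j, st.cl_k, st.cl_rest,
                st.br_i, st.br_j, st.br_k, prm.eps_angle,
                np.cos(np.deg2rad(prm.theta_0)),
                p["fil_ptr"], p["fil_beads"],
                prm.F_push_total if self.enable_push else 0.0,
                MOTOR_MODES[prm.pull_mode],
                prm.F_pull_uniform, prm.F_pull_back, prm.F_pull_membrane,
                prm.y_back_threshold, prm.membrane_z,
                fa.p0[0], fa.p0[1], fa.p1[0], fa.p1[1],
                fa.width / 2.0, fa.height,
                prm.box_width, prm.box_height, prm.confine_force,
                prm.top_wall,
                prm.k_excluded, prm.d_excluded, prm.dt, prm.kBT,
                prm.l0 / 2.0,
                self._pairs, self._pair_dist, self._bead_moved,
                self._nb_meta, self._pos_ref,
                self.clamp_mask, self.clamp_vel,
                self.accum, self.drag_accum)
            done = int(self.accum[K.N_CHANNELS, 0] - steps_before)
            self._step += done
            n_steps -= done
            if status == K.PAIR_OVERFLOW:
                self._pairs = np.empty((self._pairs.shape[0] * 2, 2),
                                       dtype=np.int64)
                self._pair_dist = np.empty(self._pairs.shape[0])
                self._nb_meta[0] = -1
                continue
            if status == K.UNSTABLE:
                raise InstabilityError(
                    f"force-driven displacement exceeded l0/2 at "
                    f"t={self._step * prm.dt:.6f}s "
                    f"(n_beads={st.n_beads})")
        st.t = self._step * prm.dt

    def _boundary_events(self, elapsed_steps: int) -> None:
        """Fixed event order at a chunk boundary: adhesion binding ->
        expiry/prune -> insertion -> dynamic-link refresh."""
        st = self.state
        prm = st.params
        dt_eff = elapsed_steps * prm.dt
        topo_before = (st.n_beads, st.n_filaments, st.n_crosslinks)
        if self.enable_fa_kinetics:
            ev.fa_binding_update(st, dt_eff)
            self._zeta = effective_drag_array(st)
        if self.enable_turnover:
            ev.expire_bonds(st)
        if self.enable_spawn:
            if self.spawn_mode == "fan":
                ev.spawn_filaments(st, dt_eff)
            elif self.spawn_mode == "vertical_near":
                ev.spawn_vertical_filaments(st, dt_eff, "near_existing")
            elif self.spawn_mode == "vertical_random":
                ev.spawn_vertical_filaments(st, dt_eff, "random_x")
            elif self.spawn_mode == "branch":
                ev.spawn_branches(st, dt_eff)
            else:
                raise ValueError(f"unknown spawn mode {self.spawn_mode!r}")
        if self.enable_dynamic and self._step % self._cadence == 0:
            ev.replenish_dynamic_crosslinks(st)
        if (st.n_beads, st.n_filaments, st.n_crosslinks) != topo_before:
            self._after_topology_change()

    def _record(self) -> None:
        st = self.state
        p = st.packed()
        half = st.params.monomers_per_segment / 2.0
        mono = np.zeros(st.n_beads)
        np.add.at(mono, p["bond_i"], half)
        np.add.at(mono, p["bond_j"], half)
        self.frames.append(Frame(
            t=st.t, uid=st.uid.copy(), pos=st.pos.copy(),
            x_unwrapped=st.unwrapped_x(), fa_bound=st.fa_bound.copy(),
            monomers=mono))

    def advance(self, duration: float,
                callback: Optional[Callable] = None) -> None:
        """Advance the simulation by ``duration`` seconds."""
        prm = self.state.params
        end_step = self._step + int(round(duration / prm.dt))
        if self._record_steps is not None and not self.frames:
            self._record()
        while self._step < end_step:
            next_cadence = ((self._step // self._cadence) + 1) * self._cadence
            targets = [end_step, next_cadence, self._next_expiry_step()]
            if self._record_steps is not None:
                next_rec = ((self._step // self._record_steps) + 1) \
                    * self._record_steps
                targets.append(next_rec)
            boundary = min(targets)
            n = boundary - self._step
            self._run_chunk(n)
            self._boundary_events(n)
            if (self._record_steps is not None
                    and self._step % self._record_steps == 0):
                self._record()
            if callback is not None:
                callback(self)

    def step(self) -> None:
        """A single Euler-Maruyama step followed by the event sub-steps
        (reference path; scenario runs use :meth:`advance`)."""
        self._run_chunk(1)
        self._boundary_events(1)


def bd_step(state: NetworkState, dt: Optional[float] = None,
            rng: Optional[np.random.Generator] = None) -> NetworkState:
    """Advance a state by one time step (convenience wrapper; state is
    modified in place and returned)."""
    if dt is not None and dt != state.params.dt:
        state.params = state.params.replace(dt=dt)
    if rng is not None:
        state.rng = rng
    Simulation(state, enable_spawn=False, enable_turnover=False,
               enable_dynamic=False).step()
    return state


# ---------------------------------------------------------------------------
# bond-crossing audit
# ---------------------------------------------------------------------------

def count_bond_crossings(pos_before: np.ndarray, pos_after: np.ndarray,
                         bond_i: np.ndarray, bond_j: np.ndarray,
                         box_width: float, proximity: float = 0.05) -> int:
    """Diagnostic count of unphysical segment pass-throughs between two
    frames.

    A pair is flagged when the chirality of the two segments (the sign of
    the triple product of the two bond vectors and their connector) flips
    between the frames while the segments stay within ``proximity`` of
    each other.  Purely diagnostic; nothing is corrected.
    """
    nb = bond_i.shape[0]
    if nb < 2:
        return 0
    # candidate pairs from proximity in the first frame
    buf = np.empty((max(64, 64 * nb), 2), dtype=np.int64)
    found = K.build_segment_pairs(pos_before, bond_i, bond_j, box_width,
                                  2 * proximity + 0.2, buf)
    if found < 0:
        raise MemoryError("crossing-audit pair buffer overflow")
    pairs = buf[:found]
    count = 0
    for a, b in pairs:
        ia, ja = bond_i[a], bond_j[a]
        ib, jb = bond_i[b], bond_j[b]
        flip = True
        dists = []
        chis = []
        for pos in (pos_before, pos_after):
            mida = 0.5 * (pos[ia, 0] + pos[ja, 0])
            midb = 0.5 * (pos[ib, 0] + pos[jb, 0])
            shift = box_width * np.rint((mida - midb) / box_width)
            qb0 = pos[ib].copy(); qb0[0] += shift
            qb1 = pos[jb].copy(); qb1[0] += shift
            u = pos[ja] - pos[ia]
            v = qb1 - qb0
            w = qb0 - pos[ia]
            chis.append(np.sign(np.linalg.det(np.stack([u, v, w]))))
            d, _, _ = K.seg_seg_closest(
                pos[ia, 0], pos[ia, 1], pos[ia, 2],
                pos[ja, 0], pos[ja, 1], pos[ja, 2],
                qb0[0], qb0[1], qb0[2], qb1[0], qb1[1], qb1[2])
            dists.append(d)
        if chis[0] != 0 and chis[1] != 0 and chis[0] != chis[1] \
                and max(dists) < proximity:
            count += 1
    return count
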