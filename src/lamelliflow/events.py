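"""Stochastic network remodeling.

Filament insertion near the leading edge, permanent/dynamic crosslink
creation and expiry, age-based bond severing with filament splitting,
focal-adhesion binding kinetics and branch nucleation.  All randomness
flows through ``state.rng`` in a fixed order per call, so a run is a
deterministic function of the seed.

Filament insertion uses a deterministic fractional accumulator rather than
Poisson arrivals: the insertion rate is a fixed model input and the
accumulator makes the number of insertions over any interval exactly
rate * interval (up to the residue), which greatly helps reproducibility.
"""
from __future__ import annotations

import math
from typing import List, Optional

import numpy as np

from . import _kernels as K
from .params import Parameters
from .state import (NetworkState, CL_PERMANENT, CL_LONG_LIVED, CL_DYNAMIC,
                    CL_BRANCH)

INFINITE = np.inf


def schedule_segment_lifetime(params: Parameters,
                              rng: np.random.Generator,
                              n: int = 1) -> np.ndarray:
    """Sample actin bond lifetimes tau = tau_age - ln(u)/r_age.

    Bonds live at least ``tau_age`` and then decay exponentially at rate
    ``r_age``; the mean lifetime is tau_age + 1/r_age.
    """
    u = rng.random(n)
    # guard u=0 (log(0)); rng.random is in [0,1)
    u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)
    return params.tau_age - np.log(u) / params.r_age


def _fil_of_bead(state: NetworkState) -> np.ndarray:
    out = np.full(state.n_beads, -1, dtype=np.int64)
    for f, beads in enumerate(state.filaments):
        out[beads] = f
    return out


def _insert_one_filament(state: NetworkState, direction: np.ndarray,
                         pointed: np.ndarray) -> int:
    prm = state.params
    n = prm.beads_per_filament
    offsets = np.arange(n)[:, None] * prm.l0 * direction[None, :]
    positions = pointed[None, :] + offsets
    beads = state.add_beads(positions, birth=state.t)
    tau = state.t + schedule_segment_lifetime(prm, state.rng, n - 1)
    fid = state.add_filament(beads, tau)
    state.spawn_count += 1
    return fid


def _fan_direction(state: NetworkState) -> np.ndarray:
    """Insertion axis: in-plane angle uniform in [-70, 70] deg about -y,
    out-of-plane (yz) angle uniform in [-10, 10] deg."""
    phi = np.deg2rad(state.rng.uniform(-70.0, 70.0))
    psi = np.deg2rad(state.rng.uniform(-10.0, 10.0))
    return np.array([math.sin(phi),
                     -math.cos(phi) * math.cos(psi),
                     math.cos(phi) * math.sin(psi)])


def spawn_filaments(state: NetworkState, dt: float,
                    seed_crosslinks: bool = True) -> List[int]:
    """Insert filaments at the configured fixed rate.

    Each filament has its pointed end at y = 0.5 um (x, z uniform in the
    box) and extends toward the leading edge; new filaments immediately
    receive up to ``max_permanent_per_filament`` permanent crosslinks.
    """
    prm = state.params
    state.spawn_residue += prm.filament_add_rate * dt
    new_ids: List[int] = []
    while state.spawn_residue >= 1.0:
        state.spawn_residue -= 1.0
        pointed = np.array([state.rng.uniform(0.0, prm.box_width), 0.5,
                            state.rng.uniform(0.0, prm.box_height)])
        fid = _insert_one_filament(state, _fan_direction(state), pointed)
        new_ids.append(fid)
        if seed_crosslinks:
            seed_permanent_crosslinks(state, state.filaments[-1])
    return new_ids


def spawn_vertical_filaments(state: NetworkState, dt: float,
                             submode: str = "near_existing") -> List[int]:
    """Microspike-style insertion: every other filament is vertical.

    Vertical filaments have their axis exactly along +y (pointed end
    toward the cell interior is still index 0 at y = 0.5, barbed end
    toward the leading edge, axis along -y like the fan filaments but with
    zero in-plane angle).  In ``near_existing`` mode the pointed end's x
    is placed 35 nm to a random side of a randomly chosen existing bead
    with y < 1 um; in ``random_x`` mode x is uniform.
    """
    if submode not in ("near_existing", "random_x"):
        raise ValueError(f"unknown submode {submode!r}")
    prm = state.params
    state.spawn_residue += prm.filament_add_rate * dt
    new_ids: List[int] = []
    while state.spawn_residue >= 1.0:
        state.spawn_residue -= 1.0
        vertical = state.spawn_count % 2 == 1   # deterministic alternation
        z = state.rng.uniform(0.0, prm.box_height)
        if not vertical:
            pointed = np.array([state.rng.uniform(0.0, prm.box_width), 0.5, z])
            direction = _fan_direction(state)
        else:
            direction = np.array([0.0, -1.0, 0.0])
            mode = submode
            if mode == "near_existing":
                front = np.flatnonzero(state.pos[:, 1] < 1.0)
                if front.size == 0:
                    mode = "random_x"   # empty network fallback
            if mode == "near_existing":
                anchor = front[state.rng.integers(front.size)]
                side = 1.0 if state.rng.random() < 0.5 else -1.0
                x = (state.pos[anchor, 0] + side * 0.035) % prm.box_width
            else:
                x = state.rng.uniform(0.0, prm.box_width)
            pointed = np.array([x, 0.5, z])
        fid = _insert_one_filament(state, direction, pointed)
        new_ids.append(fid)
        seed_permanent_crosslinks(state, state.filaments[-1])
    return new_ids


def seed_permanent_crosslinks(state: NetworkState,
                              new_filament: np.ndarray) -> int:
    """Attach up to five permanent crosslinks between a just-inserted
    filament and pre-existing beads separated by 0.03-0.04 um.

    When ``longlived_lifetime`` is configured the links are created as
    long-lived instead, with exponentially distributed removal times.
    Candidates in the window are chosen uniformly at random without
    replacement (no nearest-neighbor preference).
    """
    prm = state.params
    others = np.setdiff1d(np.arange(state.n_beads), new_filament,
                          assume_unique=False)
    if others.size == 0:
        return 0
    lo, hi = prm.crosslink_window
    cands = []
    for b in new_filament:
        d = state.pos[others] - state.pos[b][None, :]
        dx = np.mod(d[:, 0], prm.box_width)
        d[:, 0] = np.where(dx > prm.box_width / 2, dx - prm.box_width, dx)
        dist = np.linalg.norm(d, axis=1)
        for o in others[(dist >= lo) & (dist <= hi)]:
            cands.append((int(b), int(o)))
    if not cands:
        return 0
    n_pick = min(prm.max_permanent_per_filament, len(cands))
    picks = state.rng.choice(len(cands), size=n_pick, replace=False)
    for p in np.sort(picks):
        i, j = cands[p]
        if prm.longlived_lifetime is None:
            tau, cl_type = INFINITE, CL_PERMANENT
        else:
            tau = state.t + state.rng.exponential(prm.longlived_lifetime)
            cl_type = CL_LONG_LIVED
        state.add_crosslink(i, j, prm.k_crosslink, prm.l0_crosslink,
                            tau, cl_type)
    return n_pick


def replenish_dynamic_crosslinks(state: NetworkState,
                                 max_candidates: int = 1 << 20) -> int:
    """Top up dynamic crosslinks to the concentration-derived cap.

    Called at the 0.025 s cadence; candidate pairs are inter-filament bead
    pairs at separation 0.03-0.04 um not already bonded to each other,
    sampled uniformly without replacement.  Each new link draws an
    exponential lifetime with rate ``k_dynamic_off``.
    """
    prm = state.params
    cap = prm.n_dynamic_total
    current = int(np.sum(state.cl_type == CL_DYNAMIC))
    room = cap - current
    if room <= 0 or state.n_beads < 2:
        return 0
    fil_of = _fil_of_bead(state)
    buf = np.empty((max_candidates, 2), dtype=np.int64)
    lo, hi = prm.crosslink_window
    found = K.bead_pair_candidates(state.pos, fil_of, prm.box_width,
                                   lo, hi, buf)
    if found < 0:
        raise MemoryError("crosslink candidate buffer overflow")
    if found == 0:
        return 0
    cands = buf[:found]
    bonded = set()
    for i, j in zip(state.cl_i, state.cl_j):
        bonded.add((min(i, j), max(i, j)))
    keep = np.array([(min(i, j), max(i, j)) not in bonded
                     for i, j in cands], dtype=bool)
    cands = cands[keep]
    if cands.shape[0] == 0:
        return 0
    n_pick = min(room, cands.shape[0])
    picks = state.rng.choice(cands.shape[0], size=n_pick, replace=False)
    made = 0
    for p in np.sort(picks):
        i, j = int(cands[p, 0]), int(cands[p, 1])
        key = (min(i, j), max(i, j))
        if key in bonded:
            continue
        bonded.add(key)
        tau = state.t + state.rng.exponential(1.0 / prm.k_dynamic_off)
        state.add_crosslink(i, j, prm.k_crosslink, prm.l0_crosslink,
                            tau, CL_DYNAMIC)
        made += 1
    return made


def expire_bonds(state: NetworkState) -> dict:
    """Remove actin bonds and crosslinks whose scheduled removal time has
    passed; mid-chain removals split filaments, then singleton beads are
    pruned.  Returns counters."""
    t = state.t
    n_cl = 0
    expired_cl = np.flatnonzero(state.cl_tau <= t)
    if expired_cl.size:
        # branch-crosslink removal also drops the angular triplet
        for idx in expired_cl:
            if state.cl_type[idx] == CL_BRANCH:
                i, j = state.cl_i[idx], state.cl_j[idx]
                keep = ~((state.br_j == i) | (state.br_k == j)
                         | (state.br_j == j) | (state.br_k == i))
                state.br_i = state.br_i[keep]
                state.br_j = state.br_j[keep]
                state.br_k = state.br_k[keep]
        state.remove_crosslinks(expired_cl)
        n_cl = expired_cl.size

    n_bonds = 0
    f = 0
    while f < len(state.filaments):
        tau = state.fil_bond_tau[f]
        expired = np.flatnonzero(tau <= t)
        if expired.size == 0:
            f += 1
            continue
        state.split_filament(f, int(expired[0]))
        n_bonds += 1
        # revisit same slot: the barbed fragment stayed there (or was
        # removed); remaining expired bonds are found on the next pass
    n_pruned = prune_singletons(state)
    return {"crosslinks": n_cl, "bonds": n_bonds, "beads_pruned": n_pruned}


def prune_singletons(state: NetworkState) -> int:
    """Delete 1-bead filaments together with every crosslink touching
    them, repeating until a fixed point is reached."""
    total = 0
    while True:
        single = [f for f, beads in enumerate(state.filaments)
                  if beads.size < 2]
        if not single:
            return total
        beads_to_drop = np.concatenate([state.filaments[f] for f in single])
        for f in sorted(single, reverse=True):
            del state.filaments[f]
            del state.fil_bond_tau[f]
            del state.fil_bond_rest[f]
            del state.fil_ids[f]
        # drop branch triplets touching the beads first (remove_beads only
        # drops dangling references)
        keep = np.ones(state.n_beads, dtype=bool)
        keep[beads_to_drop] = False
        br_keep = keep[state.br_i] & keep[state.br_j] & keep[state.br_k]
        state.br_i = state.br_i[br_keep]
        state.br_j = state.br_j[br_keep]
        state.br_k = state.br_k[br_keep]
        state.remove_beads(beads_to_drop)
        total += beads_to_drop.size


def fa_binding_update(state: NetworkState, dt: float) -> dict:
    """Discrete-time binding/unbinding of beads to the FA region.

    Beads inside the capsule convert with exact first-order probabilities
    1 - exp(-k dt); beads that left the capsule are forcibly unbound.
    """
    fa = state.fa
    inside = fa.contains(state.pos, state.params.box_width)
    left = state.fa_bound & ~inside
    state.fa_bound[left] = False
    n_bind = n_unbind = 0
    idx = np.flatnonzero(inside)
    if idx.size:
        u = state.rng.random(idx.size)
        bound = state.fa_bound[idx]
        p_bind = 1.0 - math.exp(-fa.k_bind * dt)
        p_unbind = 1.0 - math.exp(-fa.k_unbind * dt)
        to_bind = idx[(~bound) & (u < p_bind)]
        to_unbind = idx[bound & (u < p_unbind)]
        state.fa_bound[to_bind] = True
        state.fa_bound[to_unbind] = False
        n_bind, n_unbind = to_bind.size, to_unbind.size
    return {"bind": n_bind, "unbind": int(n_unbind + left.sum())}


def spawn_branches(state: NetworkState, dt: float) -> List[int]:
    """Branch nucleation: at the filament-addition rate, grow an 11-bead
    daughter at 70 deg off a random mother bead in the nucleation window.

    The daughter's pointed end sits one excluded-volume diameter from the
    mother bead along the daughter axis (in the xy plane, side random) and
    is tethered to it by a stiff branch bond; the mother-neighbor /
    mother / daughter triplet is registered for the angular restraint.
    """
    prm = state.params
    state.spawn_residue += prm.filament_add_rate * dt
    new_ids: List[int] = []
    while state.spawn_residue >= 1.0:
        state.spawn_residue -= 1.0
        lo, hi = prm.branch_window
        eligible = np.flatnonzero((state.pos[:, 1] >= lo)
                                  & (state.pos[:, 1] <= hi))
        if eligible.size == 0:
            continue    # no eligible mother bead: insertion skipped
        j = int(eligible[state.rng.integers(eligible.size)])
        fil_of = _fil_of_bead(state)
        fil = state.filaments[fil_of[j]]
        m = int(np.flatnonzero(fil == j)[0])
        if m == 0:
            continue    # pointed-end bead: no mother segment on the
            # pointed side to define the branch angle; skipped
        i = int(fil[m - 1])
        u = state.pos[j] - state.pos[i]   # local pointed-to-barbed axis
        dx = u[0] % prm.box_width
        u[0] = dx - prm.box_width if dx > prm.box_width / 2 else dx
        # project the mother direction to xy and rotate by +-theta_0
        ux, uy = u[0], u[1]
        norm = math.hypot(ux, uy)
        if norm < 1e-12:
            continue
        ux, uy = ux / norm, uy / norm
        th = np.deg2rad(prm.theta_0)
        if state.rng.random() < 0.5:
            th = -th
        axis = np.array([ux * math.cos(th) - uy * math.sin(th),
                         ux * math.sin(th) + uy * math.cos(th), 0.0])
        pointed = state.pos[j] + prm.d_excluded * axis
        fid = _insert_one_filament(state, axis, pointed)
        new_ids.append(fid)
        daughter = state.filaments[-1]
        state.add_crosslink(j, int(daughter[0]), prm.k_actin,
                            prm.d_excluded, INFINITE, CL_BRANCH)
        state.add_branch_triplet(i, j, int(daughter[1]))
    return new_ids
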