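"""Network data model and periodic-boundary geometry.

The simulation box is periodic along x (width ``box_width``), unbounded in y
(retrograde flow direction, leading edge at y = 0) and confined to
[0, box_height] in z by soft walls.  Beads are stored in a struct-of-arrays
layout (one numpy array per field) so that the force kernels can operate on
them directly; filaments are ordered lists of bead indices with the pointed
end first.

Beads store wrapped x coordinates plus an integer wrap counter so that
trajectories (and hence flow velocities) remain continuous across the
periodic boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .params import Parameters

# crosslink type codes
CL_PERMANENT = 0
CL_LONG_LIVED = 1
CL_DYNAMIC = 2
CL_BRANCH = 3

CL_TYPE_NAMES = {CL_PERMANENT: "permanent", CL_LONG_LIVED: "long_lived",
                 CL_DYNAMIC: "dynamic", CL_BRANCH: "branch"}


class IntegrityError(RuntimeError):
    """Raised when a referential-integrity audit of the network fails."""


# ---------------------------------------------------------------------------
# periodic-boundary arithmetic
# ---------------------------------------------------------------------------

def wrap_x(point: np.ndarray, box_width: float) -> np.ndarray:
    """Wrap the x component of one or many points into [0, box_width)."""
    out = np.array(point, dtype=float, copy=True)
    x = np.mod(out[..., 0], box_width)
    # np.mod(-tiny, w) rounds to w: fold the half-open boundary back
    out[..., 0] = np.where(x >= box_width, 0.0, x)
    return out


def min_image_disp(a: np.ndarray, b: np.ndarray, box_width: float) -> np.ndarray:
    """Displacement a - b with the x component mapped into (-w/2, w/2]."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    dx = np.mod(d[..., 0], box_width)
    d = np.array(d, copy=True)
    d[..., 0] = np.where(dx > box_width / 2.0, dx - box_width, dx)
    return d


# ---------------------------------------------------------------------------
# focal adhesion region
# ---------------------------------------------------------------------------

@dataclass
class FocalAdhesionRegion:
    """Capsule-shaped friction zone attached to the substrate.

    The capsule is defined in the xy plane by a center-line segment from
    ``p0`` to ``p1`` and a width; it extends from z = 0 up to ``height``.
    Beads inside bind/unbind with first-order kinetics and, while bound,
    feel a drag elevated by the viscosity ratio ``kappa_FA``.
    """
    p0: np.ndarray            # xy endpoint of center line [um]
    p1: np.ndarray            # xy endpoint of center line [um]
    width: float = 0.25       # [um]
    height: float = 0.1       # [um]
    kappa_FA: float = 1.0
    k_bind: float = 10.0      # [1/s]
    k_unbind: float = 1.0     # [1/s]

    def __post_init__(self):
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        if self.kappa_FA < 1:
            raise ValueError("kappa_FA must be >= 1")

    @classmethod
    def from_params(cls, params: Parameters,
                    front_y: Optional[float] = None) -> "FocalAdhesionRegion":
        """Default placement: long axis along x (parallel to the leading
        edge), centered in the box, front edge at ``params.fa_front_y``."""
        front = params.fa_front_y if front_y is None else front_y
        cy = front + params.fa_width / 2.0
        seg = params.fa_length - params.fa_width   # center-line length
        cx = params.box_width / 2.0
        return cls(p0=np.array([cx - seg / 2.0, cy]),
                   p1=np.array([cx + seg / 2.0, cy]),
                   width=params.fa_width, height=params.fa_height,
                   kappa_FA=params.kappa_FA, k_bind=params.k_FA_bind,
                   k_unbind=params.k_FA_unbind)

    def xy_distance(self, points: np.ndarray, box_width: float) -> np.ndarray:
        """Distance in the xy plane from point(s) to the center-line segment,
        using the minimum image along x."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))[:, :2]
        ab = self.p1 - self.p0
        ab_len2 = float(ab @ ab)
        # minimum image relative to the segment midpoint, so the whole
        # capsule sits in one image (capsule length < box width)
        mid = self.p0 + 0.5 * ab
        d = pts - mid[None, :]
        dx = np.mod(d[:, 0], box_width)
        d[:, 0] = np.where(dx > box_width / 2.0, dx - box_width, dx)
        d = d + 0.5 * ab[None, :]       # displacement from p0
        if ab_len2 == 0.0:
            closest = np.zeros_like(d)
        else:
            s = np.clip((d @ ab) / ab_len2, 0.0, 1.0)
            closest = s[:, None] * ab[None, :]
        return np.linalg.norm(d - closest, axis=1)

    def contains(self, points: np.ndarray, box_width: float) -> np.ndarray:
        """True for points inside the capsule (closed region)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        in_z = (pts[:, 2] >= 0.0) & (pts[:, 2] <= self.height)
        in_xy = self.xy_distance(pts, box_width) <= self.width / 2.0
        return in_z & in_xy


def point_in_fa(point: np.ndarray, fa: FocalAdhesionRegion,
                box_width: float) -> bool:
    """Whether a single (wrapped) point lies inside the FA capsule."""
    return bool(fa.contains(np.asarray(point, dtype=float)[None, :],
                            box_width)[0])


# ---------------------------------------------------------------------------
# network state
# ---------------------------------------------------------------------------

class NetworkState:
    """All beads, filaments and crosslinks of an evolving network.

    Filaments are lists of bead indices ordered pointed -> barbed; actin
    bonds connect consecutive entries and carry a scheduled removal time and
    a rest length.  Crosslinks are typed spring bonds between beads of
    (normally) different filaments.  Branch attachments additionally carry
    an angular-restraint triplet (mother neighbor, mother attach bead,
    daughter bead).
    """

    def __init__(self, params: Parameters,
                 fa: Optional[FocalAdhesionRegion] = None,
                 rng: Optional[np.random.Generator] = None):
        self.params = params
        self.fa = fa if fa is not None else FocalAdhesionRegion.from_params(params)
        self.rng = rng if rng is not None else np.random.default_rng()
        self.t = 0.0

        # bead arrays (struct of arrays)
        self.pos = np.zeros((0, 3), dtype=np.float64)
        self.uid = np.zeros(0, dtype=np.int64)
        self.birth = np.zeros(0, dtype=np.float64)
        self.fa_bound = np.zeros(0, dtype=bool)
        self.x_wraps = np.zeros(0, dtype=np.int64)

        # filaments
        self.filaments: List[np.ndarray] = []       # bead index arrays
        self.fil_ids: List[int] = []                # persistent filament ids
        self.fil_bond_tau: List[np.ndarray] = []    # removal times, len n-1
        self.fil_bond_rest: List[np.ndarray] = []   # rest lengths, len n-1

        # crosslinks
        self.cl_i = np.zeros(0, dtype=np.int64)
        self.cl_j = np.zeros(0, dtype=np.int64)
        self.cl_k = np.zeros(0, dtype=np.float64)
        self.cl_rest = np.zeros(0, dtype=np.float64)
        self.cl_tau = np.zeros(0, dtype=np.float64)
        self.cl_type = np.zeros(0, dtype=np.int64)

        # branch angular triplets (i: mother neighbor, j: mother attach
        # bead, k: daughter bead defining the daughter axis)
        self.br_i = np.zeros(0, dtype=np.int64)
        self.br_j = np.zeros(0, dtype=np.int64)
        self.br_k = np.zeros(0, dtype=np.int64)

        # event accumulators
        self.spawn_residue = 0.0
        self.next_refresh_time = params.crosslink_refresh_interval
        self.spawn_count = 0          # total filaments ever inserted
        self._next_uid = 0
        self._next_fil_id = 0

        self._packed = None           # cached packed topology

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    @property
    def n_filaments(self) -> int:
        return len(self.filaments)

    @property
    def n_crosslinks(self) -> int:
        return self.cl_i.shape[0]

    def invalidate(self) -> None:
        self._packed = None

    def add_beads(self, positions: np.ndarray, birth: float) -> np.ndarray:
        """Append beads; returns their indices."""
        positions = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
        n_new = positions.shape[0]
        start = self.n_beads
        wrapped = positions.copy()
        wraps = np.floor_divide(wrapped[:, 0], self.params.box_width).astype(np.int64)
        wrapped[:, 0] -= wraps * self.params.box_width
        over = wrapped[:, 0] >= self.params.box_width
        wrapped[over, 0] -= self.params.box_width
        wraps[over] += 1
        self.pos = np.vstack([self.pos, wrapped])
        self.uid = np.concatenate([self.uid,
                                   np.arange(self._next_uid,
                                             self._next_uid + n_new)])
        self._next_uid += n_new
        self.birth = np.concatenate([self.birth, np.full(n_new, birth)])
        self.fa_bound = np.concatenate([self.fa_bound,
                                        np.zeros(n_new, dtype=bool)])
        self.x_wraps = np.concatenate([self.x_wraps, wraps])
        self.invalidate()
        return np.arange(start, start + n_new)

    def add_filament(self, bead_idx: np.ndarray, bond_tau: np.ndarray,
                     rest: Optional[np.ndarray] = None) -> int:
        bead_idx = np.asarray(bead_idx, dtype=np.int64)
        if bead_idx.size < 2:
            raise ValueError("a filament needs at least two beads")
        if rest is None:
            rest = np.full(bead_idx.size - 1, self.params.l0)
        self.filaments.append(bead_idx)
        self.fil_bond_tau.append(np.asarray(bond_tau, dtype=np.float64))
        self.fil_bond_rest.append(np.asarray(rest, dtype=np.float64))
        fid = self._next_fil_id
        self.fil_ids.append(fid)
        self._next_fil_id += 1
        self.invalidate()
        return fid

    def add_crosslink(self, i: int, j: int, k: float, rest: float,
                      tau: float, cl_type: int) -> None:
        if i == j:
            raise ValueError("crosslink endpoints must be distinct beads")
        self.cl_i = np.append(self.cl_i, i)
        self.cl_j = np.append(self.cl_j, j)
        self.cl_k = np.append(self.cl_k, k)
        self.cl_rest = np.append(self.cl_rest, rest)
        self.cl_tau = np.append(self.cl_tau, tau)
        self.cl_type = np.append(self.cl_type, cl_type)
        self.invalidate()

    def add_branch_triplet(self, i: int, j: int, k: int) -> None:
        self.br_i = np.append(self.br_i, i)
        self.br_j = np.append(self.br_j, j)
        self.br_k = np.append(self.br_k, k)
        self.invalidate()

    # -- topology edits ----------------------------------------------------

    def split_filament(self, fil_index: int, bond_pos: int) -> None:
        """Remove bond ``bond_pos`` (between beads bond_pos, bond_pos+1) of
        filament ``fil_index``; mid-chain removal splits the filament.

        The barbed-side fragment keeps the original filament id (the pushing
        direction is defined from the pointed end, which must remain
        identifiable); the pointed-side fragment gets a fresh id.
        """
        beads = self.filaments[fil_index]
        tau = self.fil_bond_tau[fil_index]
        rest = self.fil_bond_rest[fil_index]
        n = beads.size
        if not (0 <= bond_pos < n - 1):
            raise IndexError("bond position out of range")
        pointed = beads[:bond_pos + 1]
        barbed = beads[bond_pos + 1:]
        # barbed side keeps the slot (original id)
        self.filaments[fil_index] = barbed
        self.fil_bond_tau[fil_index] = tau[bond_pos + 1:]
        self.fil_bond_rest[fil_index] = rest[bond_pos + 1:]
        if pointed.size >= 2:
            self.filaments.append(pointed)
            self.fil_bond_tau.append(tau[:bond_pos])
            self.fil_bond_rest.append(rest[:bond_pos])
            self.fil_ids.append(self._next_fil_id)
            self._next_fil_id += 1
        elif pointed.size == 1:
            # single stray bead becomes a 1-bead "filament"; the pruning
            # pass removes it together with its crosslinks
            self.filaments.append(pointed)
            self.fil_bond_tau.append(np.zeros(0))
            self.fil_bond_rest.append(np.zeros(0))
            self.fil_ids.append(self._next_fil_id)
            self._next_fil_id += 1
        if barbed.size == 0:
            del self.filaments[fil_index]
            del self.fil_bond_tau[fil_index]
            del self.fil_bond_rest[fil_index]
            del self.fil_ids[fil_index]
        self.invalidate()

    def remove_beads(self, bead_idx: np.ndarray) -> None:
        """Delete beads (by index) and renumber every reference.

        Any crosslink or branch triplet touching a removed bead is dropped;
        filaments containing removed beads must have been handled first
        (this method asserts they were).
        """
        bead_idx = np.asarray(bead_idx, dtype=np.int64)
        if bead_idx.size == 0:
            return
        keep = np.ones(self.n_beads, dtype=bool)
        keep[bead_idx] = False
        new_index = np.cumsum(keep) - 1      # old -> new, junk where removed
        self.pos = self.pos[keep]
        self.uid = self.uid[keep]
        self.birth = self.birth[keep]
        self.fa_bound = self.fa_bound[keep]
        self.x_wraps = self.x_wraps[keep]

        for f, beads in enumerate(self.filaments):
            if not keep[beads].all():
                raise IntegrityError(
                    "removing beads still referenced by a filament")
            self.filaments[f] = new_index[beads]

        cl_keep = keep[self.cl_i] & keep[self.cl_j]
        self.cl_i = new_index[self.cl_i[cl_keep]]
        self.cl_j = new_index[self.cl_j[cl_keep]]
        self.cl_k = self.cl_k[cl_keep]
        self.cl_rest = self.cl_rest[cl_keep]
        self.cl_tau = self.cl_tau[cl_keep]
        self.cl_type = self.cl_type[cl_keep]

        br_keep = keep[self.br_i] & keep[self.br_j] & keep[self.br_k]
        self.br_i = new_index[self.br_i[br_keep]]
        self.br_j = new_index[self.br_j[br_keep]]
        self.br_k = new_index[self.br_k[br_keep]]
        self.invalidate()

    def remove_crosslinks(self, cl_idx: np.ndarray) -> None:
        keep = np.ones(self.n_crosslinks, dtype=bool)
        keep[np.asarray(cl_idx, dtype=np.int64)] = False
        self.cl_i = self.cl_i[keep]
        self.cl_j = self.cl_j[keep]
        self.cl_k = self.cl_k[keep]
        self.cl_rest = self.cl_rest[keep]
        self.cl_tau = self.cl_tau[keep]
        self.cl_type = self.cl_type[keep]
        self.invalidate()

    # -- packed topology for the kernels ------------------------------------

    def packed(self) -> dict:
        """Packed (CSR + flat bond/triplet arrays) view of the topology.

        Cached; invalidated by any topology edit.  Bond b corresponds to
        filament ``bond_fil[b]`` and joins beads ``bond_i[b]``/``bond_j[b]``
        (pointed side first).
        """
        if self._packed is not None:
            return self._packed
        nf = len(self.filaments)
        lengths = np.array([f.size for f in self.filaments], dtype=np.int64)
        fil_ptr = np.zeros(nf + 1, dtype=np.int64)
        np.cumsum(lengths, out=fil_ptr[1:])
        fil_beads = (np.concatenate(self.filaments).astype(np.int64)
                     if nf else np.zeros(0, dtype=np.int64))
        bond_i, bond_j, bond_fil = [], [], []
        trip_i, trip_j, trip_k = [], [], []
        for f, beads in enumerate(self.filaments):
            bond_i.append(beads[:-1])
            bond_j.append(beads[1:])
            bond_fil.append(np.full(beads.size - 1, f, dtype=np.int64))
            if beads.size >= 3:
                trip_i.append(beads[:-2])
                trip_j.append(beads[1:-1])
                trip_k.append(beads[2:])
        cat = (lambda lst: np.concatenate(lst).astype(np.int64)
               if lst else np.zeros(0, dtype=np.int64))
        packed = dict(
            fil_ptr=fil_ptr, fil_beads=fil_beads,
            bond_i=cat(bond_i), bond_j=cat(bond_j), bond_fil=cat(bond_fil),
            bond_rest=(np.concatenate(self.fil_bond_rest)
                       if nf else np.zeros(0)),
            bond_tau=(np.concatenate(self.fil_bond_tau)
                      if nf else np.zeros(0)),
            trip_i=cat(trip_i), trip_j=cat(trip_j), trip_k=cat(trip_k),
        )
        self._packed = packed
        return packed

    # -- audits ------------------------------------------------------------

    def audit(self) -> None:
        """Full referential-integrity audit; raises on any violation."""
        n = self.n_beads
        seen = np.zeros(n, dtype=np.int64)
        if len(self.filaments) != len(self.fil_ids):
            raise IntegrityError("filament id bookkeeping out of sync")
        for f, beads in enumerate(self.filaments):
            if beads.size >= 1 and (beads.min() < 0 or beads.max() >= n):
                raise IntegrityError("dangling bead id in filament")
            if np.unique(beads).size != beads.size:
                raise IntegrityError("repeated bead in filament")
            if self.fil_bond_tau[f].size != max(beads.size - 1, 0):
                raise IntegrityError("bond lifetime table out of sync")
            seen[beads] += 1
        if (seen != 1).any():
            raise IntegrityError("every bead must belong to exactly one filament")
        for arr in (self.cl_i, self.cl_j):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise IntegrityError("dangling bead id in crosslink")
        if (self.cl_i == self.cl_j).any():
            raise IntegrityError("degenerate crosslink")
        for arr in (self.br_i, self.br_j, self.br_k):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise IntegrityError("orphan branch triplet")
        if not np.isfinite(self.pos).all():
            raise IntegrityError("non-finite bead position")
        if (self.pos[:, 0] < 0).any() or \
                (self.pos[:, 0] >= self.params.box_width).any():
            raise IntegrityError("unwrapped x coordinate")

    def unwrapped_x(self) -> np.ndarray:
        return self.pos[:, 0] + self.x_wraps * self.params.box_width

    def copy(self) -> "NetworkState":
        import copy as _copy
        new = NetworkState(self.params, fa=_copy.deepcopy(self.fa))
        new.rng = np.random.Generator(np.random.PCG64())
        new.rng.bit_generator.state = self.rng.bit_generator.state
        new.t = self.t
        for name in ("pos", "uid", "birth", "fa_bound", "x_wraps",
                     "cl_i", "cl_j", "cl_k", "cl_rest", "cl_tau", "cl_type",
                     "br_i", "br_j", "br_k"):
            setattr(new, name, getattr(self, name).copy())
        new.filaments = [f.copy() for f in self.filaments]
        new.fil_ids = list(self.fil_ids)
        new.fil_bond_tau = [a.copy() for a in self.fil_bond_tau]
        new.fil_bond_rest = [a.copy() for a in self.fil_bond_rest]
        new.spawn_residue = self.spawn_residue
        new.next_refresh_time = self.next_refresh_time
        new.spawn_count = self.spawn_count
        new._next_uid = self._next_uid
        new._next_fil_id = self._next_fil_id
        return new
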