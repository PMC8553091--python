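"""Scenario drivers: steady-state retrograde-flow runs, the clutch-strength
sweep, polymerization inhibition, arc and microspike formation, and the
mechanical characterization rig (patch extraction, uniaxial tests,
elastic moduli).

Reference-scale runs (hundreds of seconds of simulated time over a
~10 um lamellipodium) are cluster-scale computations; the ``desk``
preset shortens the filament lifetime and the run durations
proportionally so that the same protocols produce a short lamellipodium
that reaches turnover steady state within a couple of minutes of wall
time, at the cost of noisier observables.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import events as ev
from . import observables as obs
from .params import Parameters
from .state import NetworkState, FocalAdhesionRegion, CL_DYNAMIC
from .integrator import Simulation

SCENARIOS = ("clutch_sweep", "cytochalasin", "arc", "microspike",
             "branching", "mechtest")


@dataclass
class ScenarioConfig:
    """Configuration of one in-silico experiment."""
    scenario: str = "clutch_sweep"
    kappa_list: Sequence[float] = (1.0, 100.0, 500.0)
    pull_mode: str = "uniform"
    fa_front_y: float = 1.0
    c_dynamic: float = 1.0
    longlived_lifetime: Optional[float] = None
    equilibration: float = 300.0       # [s]
    measurement: float = 30.0          # [s]
    seed: int = 0
    frame_interval: float = 0.5        # [s]
    velocity_lag: float = 1.0          # [s]
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.equilibration <= 0 or self.measurement <= 0:
            raise ValueError("durations must be positive")

    def make_params(self, kappa: float) -> Parameters:
        kw = dict(kappa_FA=kappa, pull_mode=self.pull_mode,
                  fa_front_y=self.fa_front_y, c_dynamic=self.c_dynamic,
                  longlived_lifetime=self.longlived_lifetime)
        kw.update(self.overrides)
        return Parameters(**kw)


#: desk-preset mean bond lifetime: tau_age + 1/r_age = 7 s (vs 130 s at
#: reference scale); every protocol duration scales with this ratio
DESK_LIFETIME = 7.0
REFERENCE_LIFETIME = 130.0


def desk_config(scenario: str = "clutch_sweep", seed: int = 0,
                **kwargs) -> ScenarioConfig:
    """Scaled-down preset.

    The mean bond lifetime is cut from 130 s to 7 s (tau_age 6 s, aging
    rate 1/s), which shortens the lamellipodium from ~10 um to ~1.5 um and
    the steady-state bead count by the same factor; the adhesion capsule
    moves forward (front edge at y = 0.6 um) so it stays inside the short
    lamellipodium, and equilibration/measurement windows shrink to a
    couple of turnover times.  Because total motor pulling scales with the
    bead count while the leading-edge push does not, the per-bead uniform
    pull is raised 4x (0.008 pN) so pulling keeps roughly its
    reference-scale share (~1/3-1/2) of the total drive; without this the
    polymerization-inhibition response degenerates to zero.  Same
    qualitative physics, minutes instead of cluster-days.
    """
    overrides = {"tau_age": 6.0, "r_age": 1.0, "fa_front_y": 0.6,
                 "F_pull_uniform": 0.008}
    overrides.update(kwargs.pop("overrides", {}))
    defaults = dict(scenario=scenario, equilibration=6.0, measurement=3.0,
                    frame_interval=0.5, velocity_lag=1.0, seed=seed,
                    overrides=overrides)
    defaults.update(kwargs)
    return ScenarioConfig(**defaults)


def desk_cyto_window() -> tuple:
    """Post-inhibition measurement window for the desk preset: the same
    fraction of the mean bond lifetime as the reference protocol's
    30-35 s out of 130 s."""
    lo = 30.0 / REFERENCE_LIFETIME * DESK_LIFETIME
    hi = 35.0 / REFERENCE_LIFETIME * DESK_LIFETIME
    return (lo, hi)


def detect_plateau(series: Sequence[float], window: int,
                   tol: float = 0.02) -> bool:
    """True when the means of the last two non-overlapping windows agree
    to a relative tolerance (steady-state criterion)."""
    s = np.asarray(series, dtype=float)
    if s.size < 2 * window:
        return False
    a = s[-2 * window:-window].mean()
    b = s[-window:].mean()
    denom = max(abs(a), abs(b), 1e-12)
    return abs(b - a) / denom < tol


@dataclass
class SteadyStateResult:
    """Output of one steady-state run."""
    kappa: float
    state: NetworkState
    frames: list
    mean_speed: float                   # [um/s]
    flow_profile: obs.Profile1D
    density: obs.Profile1D
    force_balance: dict
    bending: Tuple[obs.Profile1D, obs.Profile1D]


def _new_state(params: Parameters, seed: int) -> NetworkState:
    rng = np.random.default_rng(seed)
    return NetworkState(params, rng=rng)


def run_steady_state(config: ScenarioConfig, kappa: float,
                     spawn_mode: str = "fan") -> SteadyStateResult:
    """Grow a network from scratch, evolve past turnover steady state and
    measure flow/density/tension/bending/force-balance observables.

    The branching mode bootstraps with ordinary pointed-end insertion for
    the first quarter of the equilibration (branch nucleation needs
    mother beads) and runs with the pushing force reduced to 30%.
    """
    params = config.make_params(kappa)
    if spawn_mode == "branch":
        params = params.replace(F_push_total=0.3 * params.F_push_total)
    state = _new_state(params, config.seed)
    sim = Simulation(state,
                     spawn_mode=("fan" if spawn_mode == "branch"
                                 else spawn_mode),
                     record_interval=config.frame_interval)
    if spawn_mode == "branch":
        bootstrap = config.equilibration / 4.0
        sim.advance(bootstrap)
        sim.spawn_mode = "branch"
        sim.advance(config.equilibration - bootstrap)
    else:
        sim.advance(config.equilibration)
    sim.frames.clear()
    sim.reset_accumulators()
    bend_samples = []

    t_end = state.t + config.measurement
    while state.t < t_end - 1e-9:
        sim.advance(min(1.0, t_end - state.t))
        bend_samples.append(obs.bending_angle_samples(state))

    y_max = float(state.pos[:, 1].max()) if state.n_beads else 1.0
    edges = np.arange(-0.5, y_max + 0.25, 0.25)
    flow = obs.retrograde_flow_profile(sim.frames, edges,
                                       lag=config.velocity_lag)
    dens = obs.density_profile(sim.frames, edges, params.box_width,
                               params.box_height)
    fb = obs.force_balance_summary(sim.accum, sim.drag_accum,
                                   params.box_width)
    speed = obs.mean_retrograde_speed(sim.frames, lag=config.velocity_lag)
    bend = obs.bending_angle_profile(bend_samples, edges)
    return SteadyStateResult(kappa, state, sim.frames, speed, flow, dens,
                             fb, bend)


def run_clutch_sweep(config: ScenarioConfig) -> Dict[float, SteadyStateResult]:
    """Steady-state observables for each adhesion strength in
    ``config.kappa_list`` (the molecular-clutch sweep)."""
    return {kappa: run_steady_state(config, kappa)
            for kappa in config.kappa_list}


# ---------------------------------------------------------------------------
# cytochalasin D
# ---------------------------------------------------------------------------

@dataclass
class CytochalasinResult:
    v_before: float
    v_after: float
    ratio: float


def cytochalasin_protocol(result: SteadyStateResult,
                          config: ScenarioConfig,
                          measure_window: Tuple[float, float] = (30.0, 35.0),
                          ) -> CytochalasinResult:
    """Polymerization inhibition: from a steady state, stop filament
    addition and leading-edge pushing, keep pulling, and compare the
    all-bead retrograde speed measured inside ``measure_window`` seconds
    after the stop with the pre-stop speed."""
    state = result.state.copy()
    sim = Simulation(state, enable_spawn=False, enable_push=False)
    sim.advance(measure_window[0])
    if state.n_beads == 0:
        raise RuntimeError("network fully disassembled before the "
                           "measurement window")
    f0 = obs.frame_from_state(state)
    sim.advance(measure_window[1] - measure_window[0])
    f1 = obs.frame_from_state(state)
    _, vy = obs.bead_velocities(f0, f1)
    if vy.size == 0:
        raise RuntimeError("no beads survived the measurement window")
    v_after = float(vy.mean())
    v_before = result.mean_speed
    return CytochalasinResult(v_before, v_after, v_after / v_before)


# ---------------------------------------------------------------------------
# arcs and microspikes
# ---------------------------------------------------------------------------

@dataclass
class BundleResult:
    c_dynamic: float
    state: NetworkState
    density: obs.Profile1D
    order_at_fa: float
    peak_y: float                 # y of the density maximum behind the
    # insertion zone


def arc_scenario(config: ScenarioConfig,
                 c_dynamic_list: Sequence[float] = (1.0, 10.0, 30.0),
                 ) -> Dict[float, BundleResult]:
    """Rear-placed strong adhesion (transverse-arc geometry): sweep the
    dynamic crosslinker concentration and record density and alignment
    diagnostics.  Long-lived (finite-lifetime) crosslinkers are enabled by
    setting ``config.longlived_lifetime``."""
    out = {}
    for c in c_dynamic_list:
        cfg = ScenarioConfig(
            scenario="arc", kappa_list=(config.kappa_list[0],),
            pull_mode=config.pull_mode, fa_front_y=config.fa_front_y,
            c_dynamic=c, longlived_lifetime=config.longlived_lifetime,
            equilibration=config.equilibration,
            measurement=config.measurement, seed=config.seed,
            frame_interval=config.frame_interval,
            velocity_lag=config.velocity_lag, overrides=config.overrides)
        res = run_steady_state(cfg, cfg.kappa_list[0])
        fa_y = (cfg.fa_front_y, cfg.fa_front_y + res.state.params.fa_width)
        order = obs.nematic_order(res.state, (fa_y[0] - 0.5, fa_y[1]))
        dens = res.density
        sel = dens.centers > 0.75   # past the insertion/compaction zone
        vals = np.where(np.isnan(dens.value), -np.inf, dens.value)
        peak_y = float(dens.centers[sel][np.argmax(vals[sel])]) \
            if sel.any() else np.nan
        out[c] = BundleResult(c, res.state, dens, order, peak_y)
    return out


@dataclass
class MicrospikeResult:
    submode: str
    state: NetworkState
    x_histogram: np.ndarray
    x_edges: np.ndarray
    peak_contrast: float          # max/mean of the x histogram


def microspike_scenario(config: ScenarioConfig,
                        submodes: Sequence[str] = ("near_existing",
                                                   "random_x"),
                        ) -> Dict[str, MicrospikeResult]:
    """Vertical-filament insertion (microspike formation): half of the
    inserted filaments are vertical, placed either near existing
    filaments or at random x."""
    out = {}
    for submode in submodes:
        mode = {"near_existing": "vertical_near",
                "random_x": "vertical_random"}[submode]
        res = run_steady_state(config, config.kappa_list[0],
                               spawn_mode=mode)
        prm = res.state.params
        edges = np.linspace(0.0, prm.box_width, 21)
        y_hi = float(res.state.pos[:, 1].max()) if res.state.n_beads else 1.0
        hist = obs.x_density_histogram(res.state, edges, (0.5, y_hi))
        contrast = float(hist.max() / max(hist.mean(), 1e-12))
        out[submode] = MicrospikeResult(submode, res.state, hist, edges,
                                        contrast)
    return out


# ---------------------------------------------------------------------------
# mechanical characterization
# ---------------------------------------------------------------------------

@dataclass
class StressStrainCurve:
    """sigma_T versus engineering strain; compression curves store the
    compressive stress -sigma_T so both modes read positive for a
    resisting network."""
    strain: np.ndarray
    stress: np.ndarray            # [Pa]
    mode: str                     # extension | compression
    wall: bool = True

    def __post_init__(self):
        if np.any(np.diff(self.strain) < 0):
            raise ValueError("strain samples must be nondecreasing")


def modulus_at_strain(curve: StressStrainCurve, strain: float = 0.2) -> float:
    """Secant elastic modulus: stress at the given strain divided by the
    strain (linear interpolation between samples)."""
    s = curve.strain
    if strain < s[0] or strain > s[-1]:
        raise ValueError("curve does not cover the requested strain")
    return float(np.interp(strain, s, curve.stress) / strain)


def tile_x(state: NetworkState, copies: int = 2) -> NetworkState:
    """Append periodic images along x and reconnect bonds across the seam,
    producing a wider non-periodic patch (the new box width is made large
    enough that the minimum image never wraps)."""
    prm = state.params
    w = prm.box_width
    new_params = prm.replace(box_width=copies * w + 4.0)
    new = NetworkState(new_params, fa=state.fa, rng=state.rng)
    new.t = state.t
    # continuous per-filament x lift
    lifted_x = state.unwrapped_x().copy()
    for beads in state.filaments:
        x0 = state.pos[beads[0], 0]
        acc = x0
        lifted_x[beads[0]] = x0
        for a, b in zip(beads[:-1], beads[1:]):
            dx = (state.pos[b, 0] - state.pos[a, 0]) % w
            if dx > w / 2:
                dx -= w
            acc += dx
            lifted_x[b] = acc
    n = state.n_beads
    for c in range(copies):
        pos = state.pos.copy()
        pos[:, 0] = lifted_x + c * w
        new.add_beads(pos, birth=state.t)
        for f, beads in enumerate(state.filaments):
            new.add_filament(beads + c * n,
                             state.fil_bond_tau[f].copy(),
                             state.fil_bond_rest[f].copy())
    # crosslinks: copy-to-copy connections follow the image shift of the
    # original link; links that would leave the tiling are dropped (they
    # become the cut boundary)
    for i, j, k, rest, tau, t_ in zip(state.cl_i, state.cl_j, state.cl_k,
                                      state.cl_rest, state.cl_tau,
                                      state.cl_type):
        shift = int(np.rint((lifted_x[i] - lifted_x[j]) / w))
        for c in range(copies):
            cj = c + shift
            if 0 <= cj < copies:
                new.add_crosslink(int(i) + c * n, int(j) + cj * n,
                                  float(k), float(rest), float(tau),
                                  int(t_))
    for i, j, kk in zip(state.br_i, state.br_j, state.br_k):
        for c in range(copies):
            new.add_branch_triplet(int(i) + c * n, int(j) + c * n,
                                   int(kk) + c * n)
    return new


def cut_network(state: NetworkState, x_range: Tuple[float, float],
                y_range: Tuple[float, float]) -> NetworkState:
    """Cut a rectangular patch: beads outside the window are removed and
    bonds to them severed (splitting filaments); crosslinks and branch
    triplets survive only if all their beads survive."""
    keep = ((state.pos[:, 0] >= x_range[0])
            & (state.pos[:, 0] <= x_range[1])
            & (state.pos[:, 1] >= y_range[0])
            & (state.pos[:, 1] <= y_range[1]))
    new = NetworkState(state.params, fa=state.fa, rng=state.rng)
    new.t = state.t
    idx_map = np.full(state.n_beads, -1, dtype=np.int64)
    kept = np.flatnonzero(keep)
    new.add_beads(state.pos[kept], birth=state.t)
    new.birth[:] = state.birth[kept]
    idx_map[kept] = np.arange(kept.size)
    for f, beads in enumerate(state.filaments):
        inside = keep[beads]
        # maximal runs of consecutive inside beads
        start = None
        for m in range(beads.size + 1):
            if m < beads.size and inside[m]:
                if start is None:
                    start = m
            else:
                if start is not None and m - start >= 2:
                    seg = beads[start:m]
                    new.add_filament(idx_map[seg],
                                     state.fil_bond_tau[f][start:m - 1],
                                     state.fil_bond_rest[f][start:m - 1])
                start = None
    ok = keep[state.cl_i] & keep[state.cl_j]
    for i, j, k, rest, tau, t_ in zip(
            state.cl_i[ok], state.cl_j[ok], state.cl_k[ok],
            state.cl_rest[ok], state.cl_tau[ok], state.cl_type[ok]):
        new.add_crosslink(int(idx_map[i]), int(idx_map[j]), float(k),
                          float(rest), float(tau), int(t_))
    okb = keep[state.br_i] & keep[state.br_j] & keep[state.br_k]
    for i, j, kk in zip(state.br_i[okb], state.br_j[okb],
                        state.br_k[okb]):
        new.add_branch_triplet(int(idx_map[i]), int(idx_map[j]),
                               int(idx_map[kk]))
    # drop beads that ended up in no filament (isolated by the cut)
    in_fil = np.zeros(new.n_beads, dtype=bool)
    for beads in new.filaments:
        in_fil[beads] = True
    new.remove_beads(np.flatnonzero(~in_fil))
    return new


def connected_components(state: NetworkState) -> np.ndarray:
    """Component label per bead over bonds + crosslinks (detects fragments
    disconnected by cutting)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components as _cc
    p = state.packed()
    i = np.concatenate([p["bond_i"], state.cl_i])
    j = np.concatenate([p["bond_j"], state.cl_j])
    n = state.n_beads
    m = coo_matrix((np.ones(i.size), (i, j)), shape=(n, n))
    _, labels = _cc(m, directed=False)
    return labels


def extract_mechanical_patch(state: NetworkState, equilibrate: float = 50.0,
                             y_range: Tuple[float, float] = (-0.5, 3.5),
                             ) -> NetworkState:
    """Prepare the mechanical-test patch from a steady-state network:
    freeze turnover/crosslink changes and external forces, equilibrate,
    tile once along x and cut to a rectangular patch."""
    st = state.copy()
    st.params = st.params.replace(F_pull_uniform=0.0, F_pull_back=0.0,
                                  F_pull_membrane=0.0)
    sim = Simulation(st, enable_spawn=False, enable_turnover=False,
                     enable_dynamic=False, enable_push=False,
                     enable_fa_kinetics=False)
    if equilibrate > 0:
        sim.advance(equilibrate)
    tiled = tile_x(st, copies=2)
    w = state.params.box_width
    patch = cut_network(tiled, (0.0, 2.0 * w), y_range)
    return patch


def uniaxial_test(patch: NetworkState, mode: str = "extension",
                  wall: bool = True, clamp_depth: float = 0.25,
                  strain_rate: float = 0.05, max_strain: float = 0.5,
                  samples: int = 26,
                  allow_dynamic_rebinding: bool = True,
                  ) -> StressStrainCurve:
    """Clamp-and-strain rig.

    Beads initially within ``clamp_depth`` of the patch's y extremes are
    driven apart (extension) or together (compression) at a relative
    speed of ``strain_rate`` times the gauge length, up to ``max_strain``
    engineering strain.  Thermal forces and excluded volume stay on;
    actin turnover is frozen but dynamic crosslinks may unbind and rebind.
    The tensile stress sigma_T is sampled from the virial over the
    non-clamped beads (compression curves report -sigma_T).
    ``wall=False`` removes the top z confinement (buckling variant).
    """
    if mode not in ("extension", "compression"):
        raise ValueError(f"unknown mode {mode!r}")
    st = patch.copy()
    if not wall:
        st.params = st.params.replace(top_wall=False)
    # freeze actin aging entirely; optionally keep dynamic-link turnover,
    # capped at the link count present when testing starts
    for f in range(len(st.fil_bond_tau)):
        st.fil_bond_tau[f] = np.full_like(st.fil_bond_tau[f], np.inf)
    if allow_dynamic_rebinding:
        n_dyn = int(np.sum(st.cl_type == CL_DYNAMIC))
        from .params import AVOGADRO_UM3
        c_eq = n_dyn / (AVOGADRO_UM3 * st.params.box_width * 9.5
                        * st.params.box_height)
        st.params = st.params.replace(c_dynamic=c_eq)
    else:
        st.cl_tau[:] = np.inf
    st.invalidate()
    sim = Simulation(st, enable_spawn=False,
                     enable_turnover=allow_dynamic_rebinding,
                     enable_dynamic=allow_dynamic_rebinding,
                     enable_push=False, enable_fa_kinetics=False)
    y = st.pos[:, 1]
    y_lo, y_hi = float(y.min()), float(y.max())
    gauge = y_hi - y_lo
    lower = y <= y_lo + clamp_depth
    upper = y >= y_hi - clamp_depth
    if not lower.any() or not upper.any():
        raise ValueError("empty clamp set")
    sign = 1.0 if mode == "extension" else -1.0
    v = strain_rate * gauge / 2.0
    sim.clamp_mask = lower | upper
    sim.clamp_vel = np.zeros((st.n_beads, 3))
    sim.clamp_vel[upper, 1] = sign * v
    sim.clamp_vel[lower, 1] = -sign * v
    interior = ~sim.clamp_mask
    prm = st.params
    volume = prm.box_height * gauge * (st.pos[:, 0].max()
                                       - st.pos[:, 0].min())
    strains = np.linspace(0.0, max_strain, samples)
    stresses = np.empty(samples)
    stresses[0] = obs.virial_stress(st, volume, interior).sigma_T
    t0 = st.t
    for m in range(1, samples):
        target_t = t0 + strains[m] / strain_rate
        sim.advance(target_t - st.t)
        stresses[m] = obs.virial_stress(st, volume, interior).sigma_T
    if mode == "compression":
        stresses = -stresses
    return StressStrainCurve(strains, stresses, mode, wall)


def synthetic_patch(seed: int = 0, n_filaments: int = 90,
                    lx: float = 2.0, ly: float = 2.0,
                    params: Optional[Parameters] = None) -> NetworkState:
    """Small synthetic crosslinked patch for desk-scale mechanical tests.

    Random 1 um filaments (near-planar orientations) are scattered over
    [0, lx] x [0, ly] x [0, 0.2] and permanently crosslinked where
    filament pairs pass within crosslinking distance; the density is far
    below the reference lamellipodium (which would need thousands of
    filaments) but the patch percolates and shows the same qualitative
    mechanics.  This is a synthetic stand-in, not a network grown by the
    retrograde-flow protocol.
    """
    if params is None:
        params = Parameters(box_width=lx + 4.0)   # non-periodic in effect
    rng = np.random.default_rng(seed)
    st = NetworkState(params, rng=np.random.default_rng(seed + 1))
    n_beads = params.beads_per_filament
    for _ in range(n_filaments):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        psi = rng.uniform(-0.15, 0.15)
        d = np.array([np.cos(phi) * np.cos(psi), np.sin(phi) * np.cos(psi),
                      np.sin(psi)])
        length = (n_beads - 1) * params.l0
        ok = False
        for _attempt in range(200):
            start = np.array([rng.uniform(0, lx), rng.uniform(0, ly),
                              rng.uniform(0.02, 0.18)])
            end = start + length * d
            if (0 <= end[0] <= lx and 0 <= end[1] <= ly
                    and 0.0 <= end[2] <= 0.2):
                ok = True
                break
        if not ok:
            continue
        pts = start[None, :] + np.arange(n_beads)[:, None] * params.l0 * d
        beads = st.add_beads(pts, birth=0.0)
        st.add_filament(beads, np.full(n_beads - 1, np.inf))
    # crosslink close passes between different filaments
    from .forces import segment_closest_approach
    fil_of = np.full(st.n_beads, -1)
    for f, beads in enumerate(st.filaments):
        fil_of[beads] = f
    p = st.packed()
    bi, bj = p["bond_i"], p["bond_j"]
    linked = set()
    for a in range(bi.size):
        for b in range(a + 1, bi.size):
            if fil_of[bi[a]] == fil_of[bi[b]]:
                continue
            d, pa, pb, (s, t) = segment_closest_approach(
                st.pos[[bi[a], bj[a]]], st.pos[[bi[b], bj[b]]])
            if d > 0.06:
                continue
            i = bi[a] if s < 0.5 else bj[a]
            j = bi[b] if t < 0.5 else bj[b]
            key = (min(fil_of[i], fil_of[j]), max(fil_of[i], fil_of[j]),
                   i, j)
            pair = (int(i), int(j))
            if pair in linked:
                continue
            linked.add(pair)
            dd = st.pos[int(i)] - st.pos[int(j)]
            rest = float(np.clip(np.linalg.norm(dd), 0.02,
                                 2.0 * params.l0_crosslink))
            st.add_crosslink(int(i), int(j), params.k_crosslink, rest,
                             np.inf, 0)
    return st
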