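import numpy as np
import pytest

from lamelliflow import forces
from lamelliflow.params import Parameters
from conftest import make_state, straight_filament, random_bent_state


def numerical_gradient(state, channel_fn, h=1e-7):
    """Central finite differences of the channel's potential energy."""
    grad = np.zeros((state.n_beads, 3))
    for b in range(state.n_beads):
        for c in range(3):
            orig = state.pos[b, c]
            state.pos[b, c] = orig + h
            ep = channel_fn(state)
            state.pos[b, c] = orig - h
            em = channel_fn(state)
            state.pos[b, c] = orig
            grad[b, c] = (ep - em) / (2 * h)
    return grad


def spring_energy(state):
    p = state.packed()
    d = state.pos[p["bond_i"]] - state.pos[p["bond_j"]]
    w = state.params.box_width
    dx = np.mod(d[:, 0], w)
    d[:, 0] = np.where(dx > w / 2, dx - w, dx)
    dist = np.linalg.norm(d, axis=1)
    return 0.5 * state.params.k_actin * np.sum((dist - p["bond_rest"]) ** 2)


def bend_energy(state):
    p = state.packed()
    e = 0.0
    for i, j, k in zip(p["trip_i"], p["trip_j"], p["trip_k"]):
        u = state.pos[j] - state.pos[i]
        v = state.pos[k] - state.pos[j]
        c = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
        e += state.params.kappa_bend / state.params.l0 * (1 - c)
    return e


def crosslink_energy(state):
    e = 0.0
    for i, j, kk, rest in zip(state.cl_i, state.cl_j, state.cl_k,
                              state.cl_rest):
        d = np.linalg.norm(state.pos[i] - state.pos[j])
        e += 0.5 * kk * (d - rest) ** 2
    return e


def branch_energy(state):
    e = 0.0
    c0 = np.cos(np.deg2rad(state.params.theta_0))
    for i, j, k in zip(state.br_i, state.br_j, state.br_k):
        u = state.pos[j] - state.pos[i]
        v = state.pos[k] - state.pos[j]
        c = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
        e += state.params.eps_angle * (c - c0) ** 2
    return e


class TestSpringForces:
    def test_rest_length_zero_force(self):
        st = make_state()
        straight_filament(st, n=3)
        assert np.allclose(forces.spring_forces(st), 0.0, atol=1e-12)

    def test_stretched_bond_magnitude(self):
        st = make_state()
        beads = straight_filament(st, n=2)
        st.pos[beads[1], 1] -= 0.01     # bond length 0.11
        F = forces.spring_forces(st)
        # 1000 pN/um * 0.01 um = 10 pN pulling the beads together
        assert np.linalg.norm(F[beads[0]]) == pytest.approx(10.0, rel=1e-9)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-9)


class TestBendingForces:
    def test_collinear_zero(self):
        st = make_state()
        straight_filament(st, n=5)
        assert np.allclose(forces.bending_forces(st), 0.0, atol=1e-10)

    def test_torque_free(self):
        st = random_bent_state(seed=3, n_filaments=1)
        F = forces.bending_forces(st)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-9)
        torque = np.cross(st.pos, F).sum(axis=0)
        assert np.allclose(torque, 0.0, atol=1e-9)


class TestCrosslinkForces:
    def test_rest_and_stretched(self):
        st = make_state()
        straight_filament(st, n=2, pointed=(0.5, 0.5, 0.1))
        straight_filament(st, n=2, pointed=(0.5, 0.5 - 0.045, 0.1))
        st.add_crosslink(0, 2, st.params.k_crosslink,
                         st.params.l0_crosslink, np.inf, 0)
        F = forces.crosslink_forces(st)
        # separation 0.045, rest 0.035 -> 1.0 pN attractive
        assert np.linalg.norm(F[0]) == pytest.approx(1.0, rel=1e-9)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-12)


class TestGradientOracles:
    """Every potential-derived channel matches central finite differences
    on randomized bent fixtures."""

    @pytest.mark.parametrize("seed", range(10))
    def test_channels_match_finite_differences(self, seed):
        st = random_bent_state(seed=seed)
        cases = [
            (forces.spring_forces, spring_energy),
            (forces.bending_forces, bend_energy),
            (forces.crosslink_forces, crosslink_energy),
            (forces.branch_angle_forces, branch_energy),
        ]
        for force_fn, energy_fn in cases:
            F = force_fn(st)
            G = numerical_gradient(st, energy_fn)
            scale = max(np.abs(F).max(), 1.0)
            assert np.allclose(F, -G, atol=2e-5 * scale), force_fn.__name__


class TestSegmentClosestApproach:
    def test_parallel_offset(self):
        a = np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0]])
        b = a + np.array([0.0, 0.005, 0.0])
        d, pa, pb, (s, t) = forces.segment_closest_approach(a, b)
        assert d == pytest.approx(0.005, abs=1e-12)
        assert s == pytest.approx(0.5)   # midpoint tie rule
        assert t == pytest.approx(0.5)

    def test_perpendicular_crossing(self):
        a = np.array([[-0.05, 0.0, 0.0], [0.05, 0.0, 0.0]])
        b = np.array([[0.0, -0.05, 0.0], [0.0, 0.05, 0.0]])
        d, *_ = forces.segment_closest_approach(a, b)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_zero_length_rejected(self):
        a = np.zeros((2, 3))
        b = np.array([[0.0, 1.0, 0.0], [0.0, 2.0, 0.0]])
        with pytest.raises(ValueError):
            forces.segment_closest_approach(a, b)

    def test_matches_brute_force_sampling(self):
        """Random segment pairs against a dense two-parameter grid."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = rng.uniform(-0.2, 0.2, (2, 3))
            b = rng.uniform(-0.2, 0.2, (2, 3))
            if min(np.linalg.norm(a[1] - a[0]),
                   np.linalg.norm(b[1] - b[0])) < 1e-3:
                continue
            d, *_ = forces.segment_closest_approach(a, b)
            s = np.linspace(0, 1, 101)
            pa = a[0] + s[:, None] * (a[1] - a[0])
            pb = b[0] + s[:, None] * (b[1] - b[0])
            brute = np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :],
                                          axis=2))
            assert d <= brute + 1e-9
            assert d >= brute - 5e-3     # grid resolution limit


class TestExcludedVolume:
    def _overlapping_pair_state(self, gap):
        st = make_state()
        straight_filament(st, n=2, pointed=(0.5, 0.5, 0.1),
                          direction=(0, -1, 0))
        straight_filament(st, n=2, pointed=(0.45, 0.45 - 0.0, 0.1 + gap),
                          direction=(1, 0, 0))
        return st

    def test_no_force_beyond_cutoff(self):
        st = self._overlapping_pair_state(gap=0.008)
        F = forces.excluded_volume_forces(st)
        assert np.allclose(F, 0.0)

    def test_overlap_magnitude_and_balance(self):
        st = self._overlapping_pair_state(gap=0.005)
        F = forces.excluded_volume_forces(st)
        # 1690 * (0.007 - 0.005) = 3.38 pN total on each segment
        seg_a = F[:2].sum(axis=0)
        seg_b = F[2:].sum(axis=0)
        assert np.linalg.norm(seg_a) == pytest.approx(3.38, rel=1e-6)
        assert np.allclose(seg_a, -seg_b, atol=1e-9)

    def test_endpoint_witness_gets_full_share(self):
        st = make_state()
        straight_filament(st, n=2, pointed=(0.5, 0.5, 0.1),
                          direction=(0, -1, 0))
        # second segment starts just beyond the first one's pointed end,
        # so the closest approach is endpoint-to-endpoint
        straight_filament(st, n=2, pointed=(0.5, 0.503, 0.105),
                          direction=(0, 1, 0))
        F = forces.excluded_volume_forces(st)
        # each segment's witness is an endpoint: the far beads get nothing
        assert np.linalg.norm(F[1]) == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(F[3]) == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(F[0]) > 0
        assert np.linalg.norm(F[2]) > 0


class TestLeadingEdgeForces:
    def test_filament_above_zero_gets_nothing(self):
        st = make_state()
        straight_filament(st, n=11, pointed=(1.0, 1.6, 0.1))
        assert np.allclose(forces.leading_edge_forces(st), 0.0)

    def test_per_bead_share_and_direction(self):
        st = make_state()
        beads = straight_filament(st, n=11, pointed=(1.0, 0.5, 0.1),
                                  direction=(0, -1, 0))
        F = forces.leading_edge_forces(st)
        # 1.5 pN / 11 beads = 0.136 pN each, along +y (retrograde)
        assert F[beads, 1] == pytest.approx(1.5 / 11, rel=1e-9)
        assert np.allclose(F[beads, 0], 0.0)

    def test_short_fragment_share(self):
        st = make_state()
        beads = straight_filament(st, n=5, pointed=(1.0, 0.3, 0.1),
                                  direction=(0, -1, 0))
        F = forces.leading_edge_forces(st)
        assert F[beads, 1] == pytest.approx(1.5 / 5, rel=1e-9)


class TestMotorForces:
    def test_uniform_sum(self):
        st = random_bent_state(seed=1)
        F = forces.motor_forces(st, "uniform")
        assert F[:, 1].sum() == pytest.approx(0.002 * st.n_beads, rel=1e-9)
        assert np.allclose(F[:, [0, 2]], 0.0)

    def test_back_mode_inactive_in_front(self):
        st = random_bent_state(seed=1)   # all beads near the front
        assert np.allclose(forces.motor_forces(st, "back"), 0.0)

    def test_membrane_mode_skips_fa_and_high_beads(self):
        st = make_state()
        prm = st.params
        fa_center_y = prm.fa_front_y + prm.fa_width / 2
        straight_filament(st, n=3, pointed=(0.9, fa_center_y, 0.01),
                          direction=(1, 0, 0))           # inside FA, low z
        straight_filament(st, n=3, pointed=(0.2, 2.5, 0.01),
                          direction=(0, -1, 0))          # outside FA, low z
        straight_filament(st, n=3, pointed=(0.2, 3.5, 0.1),
                          direction=(0, -1, 0))          # z above layer
        F = forces.motor_forces(st, "membrane")
        assert np.allclose(F[:3], 0.0)                   # FA-shielded
        assert np.linalg.norm(F[3:6], axis=1) == \
            pytest.approx(0.02, rel=1e-9)
        assert np.allclose(F[6:], 0.0)

    def test_unknown_mode_rejected(self):
        st = random_bent_state(seed=1)
        with pytest.raises(ValueError):
            forces.motor_forces(st, "sideways")


class TestConfinement:
    def test_interior_zero_walls_push_back(self):
        st = make_state()
        beads = straight_filament(st, n=3, pointed=(1.0, 0.5, 0.1),
                                  direction=(0, -1, 0))
        st.pos[beads[0], 2] = 0.1
        st.pos[beads[1], 2] = -0.01
        st.pos[beads[2], 2] = 0.3
        F = forces.confinement_forces(st)
        assert F[beads[0], 2] == 0.0
        assert F[beads[1], 2] == pytest.approx(1.0)
        assert F[beads[2], 2] == pytest.approx(-1.0)
        st.params = st.params.replace(top_wall=False)
        F2 = forces.confinement_forces(st)
        assert F2[beads[2], 2] == 0.0


class TestBranchAngle:
    def test_at_rest_angle_zero_force(self):
        st = make_state()
        straight_filament(st, n=3, pointed=(1.0, 1.0, 0.1),
                          direction=(0, -1, 0))
        th = np.deg2rad(70.0)
        d = np.array([np.sin(th), -np.cos(th), 0.0])
        pts = st.pos[1] + np.array([0.007 * d, (0.007 + 0.1) * d])
        beads = st.add_beads(pts, birth=0.0)
        st.add_filament(beads, np.array([np.inf]))
        st.add_branch_triplet(0, 1, int(beads[1]))
        F = forces.branch_angle_forces(st)
        assert np.allclose(F, 0.0, atol=1e-9)

    def test_off_angle_torque_free(self):
        st = random_bent_state(seed=5)
        F = forces.branch_angle_forces(st)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-10)


class TestThermalForces:
    def test_variance_matches_fluctuation_dissipation(self):
        """Per-component variance is 2 kBT zeta / dt (checked to 1%)."""
        st = make_state(seed=42)
        straight_filament(st, n=11)
        prm = st.params
        samples = np.concatenate(
            [forces.thermal_forces(st).ravel() for _ in range(3500)])
        expected = 2 * prm.kBT * prm.zeta_b / prm.dt
        assert samples.var() == pytest.approx(expected, rel=0.01)
        # mean within 4 standard errors of zero
        se = np.sqrt(expected / samples.size)
        assert abs(samples.mean()) < 4 * se

    def test_bound_beads_use_elevated_drag(self):
        st = make_state(seed=1)
        st.params = st.params.replace(kappa_FA=100.0)
        st.fa.kappa_FA = 100.0
        straight_filament(st, n=2)
        st.fa_bound[0] = True
        rng = np.random.default_rng(0)
        draws = np.array([forces.thermal_forces(st, rng=rng)
                          for _ in range(4000)])
        v_bound = draws[:, 0, :].var()
        v_free = draws[:, 1, :].var()
        assert v_bound / v_free == pytest.approx(100.0, rel=0.15)


class TestChannelMomentum:
    def test_internal_channels_sum_to_zero(self):
        st = random_bent_state(seed=11)
        fb = forces.force_breakdown(st)
        for name in ("spring", "bend", "crosslink", "excluded",
                     "branch_angle"):
            assert np.allclose(getattr(fb, name).sum(axis=0), 0.0,
                               atol=1e-9), name
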