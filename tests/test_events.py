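import numpy as np
import pytest
from scipy import stats

from lamelliflow import events as ev
from lamelliflow.params import Parameters
from lamelliflow.state import (CL_PERMANENT, CL_LONG_LIVED, CL_DYNAMIC,
                               CL_BRANCH)
from conftest import make_state, straight_filament


class TestSegmentLifetime:
    def test_minimum_and_mean(self, params, rng):
        """tau = tau_age - ln(u)/r_age: min 125 s, mean 125 + 1/0.2."""
        taus = ev.schedule_segment_lifetime(params, rng, n=100_000)
        assert taus.min() >= params.tau_age
        expected_mean = params.tau_age + 1.0 / params.r_age
        assert taus.mean() == pytest.approx(expected_mean, rel=0.01)


class TestSpawnFilaments:
    def test_deterministic_accumulator(self):
        st = make_state()
        # rate 23.4/s over 10 s -> 234 insertions (the count is exact up
        # to the fractional residue; rate*interval = 234 sits exactly on
        # the accumulator boundary)
        total = 0
        for _ in range(400):
            total += len(ev.spawn_filaments(st, 0.025,
                                            seed_crosslinks=False))
        assert total + st.spawn_residue == pytest.approx(234.0, abs=1e-6)
        assert total in (233, 234)
        # a second identical pass gives the identical count
        st2 = make_state()
        total2 = sum(len(ev.spawn_filaments(st2, 0.025,
                                            seed_crosslinks=False))
                     for _ in range(400))
        assert total2 == total

    def test_geometry_of_inserted_filaments(self):
        st = make_state(seed=7)
        for _ in range(50):
            ev.spawn_filaments(st, 1 / 23.4, seed_crosslinks=False)
        for beads in st.filaments:
            assert beads.size == 11
            # pointed end exactly at y = 0.5
            assert st.pos[beads[0], 1] == pytest.approx(0.5)
            # bead spacing l0 along a straight axis
            d = np.diff(st.pos[beads], axis=0)
            w = st.params.box_width
            dx = np.mod(d[:, 0], w)
            d[:, 0] = np.where(dx > w / 2, dx - w, dx)
            assert np.linalg.norm(d, axis=1) == pytest.approx(0.1, abs=1e-9)
            # axis points toward the leading edge, angle within the fan
            axis = d[0] / np.linalg.norm(d[0])
            assert axis[1] < 0
            in_plane = np.degrees(np.arctan2(abs(axis[0]), -axis[1]))
            assert in_plane <= 70.0 + 1e-6

    def test_in_plane_angle_distribution_uniform(self):
        """KS test of the insertion-angle histogram against U(-70, 70)."""
        st = make_state(seed=11)
        angles = []
        for _ in range(4000):
            ev.spawn_filaments(st, 1 / 23.4, seed_crosslinks=False)
            beads = st.filaments[-1]
            d = st.pos[beads[1]] - st.pos[beads[0]]
            angles.append(np.degrees(np.arctan2(d[0], -d[1])))
            # keep the state small
            if len(st.filaments) > 50:
                drop = np.concatenate(
                    [st.filaments[f] for f in range(40)])
                del st.filaments[:40], st.fil_bond_tau[:40]
                del st.fil_bond_rest[:40], st.fil_ids[:40]
                st.remove_beads(drop)
        u = (np.asarray(angles) + 70.0) / 140.0
        assert stats.kstest(u, "uniform").pvalue > 1e-3


class TestVerticalSpawn:
    def test_alternation_and_vertical_axis(self):
        st = make_state(seed=5)
        for _ in range(40):
            ev.spawn_vertical_filaments(st, 1 / 23.4, "random_x")
        vertical = 0
        for beads in st.filaments:
            xs = st.pos[beads, 0]
            if np.allclose(xs, xs[0]):
                vertical += 1
        assert vertical == len(st.filaments) // 2

    def test_near_existing_offset(self):
        st = make_state(seed=6)
        anchor = straight_filament(st, n=11, pointed=(1.0, 0.5, 0.1))
        st.spawn_count = 1    # next insertion is vertical
        ev.spawn_vertical_filaments(st, 1 / 23.4, "near_existing")
        new = st.filaments[-1]
        x_new = st.pos[new[0], 0]
        dx = np.abs((st.pos[anchor, 0] - x_new + 1.0) % 2.0 - 1.0)
        assert dx.min() == pytest.approx(0.035, abs=1e-9)


class TestPermanentCrosslinks:
    def _state_with_candidates(self, n_candidates):
        st = make_state(seed=2)
        host = straight_filament(st, n=11, pointed=(1.0, 0.5, 0.1))
        # scatter beads of a second filament exactly 0.035 um away in x
        pts = [st.pos[host[k]] + np.array([0.035, 0.0, 0.0])
               for k in range(n_candidates)]
        pts = np.array(pts) if pts else np.zeros((0, 3))
        if n_candidates:
            beads = st.add_beads(pts, birth=0.0)
            st.add_filament(beads, np.full(max(n_candidates - 1, 1), np.inf)
                            [:n_candidates - 1])
        return st

    def test_isolated_filament_gets_none(self):
        st = make_state(seed=2)
        straight_filament(st, n=11)
        assert ev.seed_permanent_crosslinks(st, st.filaments[0]) == 0

    def test_capped_at_five(self):
        st = self._state_with_candidates(7)
        made = ev.seed_permanent_crosslinks(st, st.filaments[1])
        assert made == 5
        assert np.all(st.cl_type == CL_PERMANENT)
        assert np.all(np.isinf(st.cl_tau))

    def test_created_links_within_window(self):
        st = self._state_with_candidates(4)
        ev.seed_permanent_crosslinks(st, st.filaments[1])
        for i, j in zip(st.cl_i, st.cl_j):
            d = np.linalg.norm(st.pos[i] - st.pos[j])
            assert 0.03 <= d <= 0.04

    def test_longlived_mode_draws_finite_lifetimes(self):
        st = self._state_with_candidates(5)
        st.params = st.params.replace(longlived_lifetime=20.0)
        ev.seed_permanent_crosslinks(st, st.filaments[1])
        assert np.all(st.cl_type == CL_LONG_LIVED)
        assert np.all(np.isfinite(st.cl_tau))


class TestDynamicCrosslinks:
    def test_cap_respected_and_lifetimes_exponential(self):
        st = make_state(seed=3)
        st.params = st.params.replace(c_dynamic=30.0)
        for k in range(12):
            straight_filament(st, n=11,
                              pointed=(0.05 + 0.17 * k, 0.5, 0.1))
        made = ev.replenish_dynamic_crosslinks(st)
        n_dyn = int(np.sum(st.cl_type == CL_DYNAMIC))
        assert made == n_dyn
        assert n_dyn <= st.params.n_dynamic_total
        again = ev.replenish_dynamic_crosslinks(st)
        assert again == 0     # candidates exhausted or already bonded

    def test_lifetime_mean(self, params, rng):
        draws = rng.exponential(1.0 / params.k_dynamic_off, 10_000)
        assert draws.mean() == pytest.approx(1.0, rel=0.05)


class TestExpiryAndPruning:
    def test_no_expiry_is_noop(self):
        st = make_state()
        straight_filament(st, n=5)
        before = [f.copy() for f in st.filaments]
        ev.expire_bonds(st)
        assert len(st.filaments) == len(before)

    def test_end_bond_expiry_trims(self):
        st = make_state()
        straight_filament(st, n=3)
        st.fil_bond_tau[0][0] = -1.0      # pointed-end bond expired
        st.t = 0.5
        ev.expire_bonds(st)
        assert st.n_filaments == 1
        assert st.filaments[0].size == 2
        assert st.n_beads == 2            # singleton pruned
        st.audit()

    def test_mid_bond_expiry_splits_and_preserves_links(self):
        st = make_state()
        straight_filament(st, n=11)
        straight_filament(st, n=11, pointed=(1.06, 0.5, 0.12))
        st.add_crosslink(2, 13, 100.0, 0.035, np.inf, CL_PERMANENT)
        st.add_crosslink(8, 19, 100.0, 0.035, np.inf, CL_PERMANENT)
        st.fil_bond_tau[0][4] = -1.0
        st.t = 1.0
        ev.expire_bonds(st)
        sizes = sorted(f.size for f in st.filaments)
        assert sizes == [5, 6, 11]
        assert st.n_crosslinks == 2       # both links survive on live beads
        st.audit()

    def test_prune_cascade_reaches_fixed_point(self):
        st = make_state()
        straight_filament(st, n=2)
        straight_filament(st, n=2, pointed=(1.1, 0.5, 0.1))
        st.add_crosslink(0, 2, 100.0, 0.035, np.inf, CL_PERMANENT)
        st.fil_bond_tau[0][0] = -1.0
        st.fil_bond_tau[1][0] = -1.0
        st.t = 1.0
        ev.expire_bonds(st)
        assert st.n_beads == 0
        assert st.n_crosslinks == 0
        st.audit()

    def test_network_empties_without_addition(self):
        st = make_state(seed=4)
        for _ in range(10):
            ev.spawn_filaments(st, 1 / 23.4, seed_crosslinks=True)
        for f in range(len(st.fil_bond_tau)):
            st.fil_bond_tau[f] = st.fil_bond_tau[f] * 0 + 0.5
        st.cl_tau[:] = 0.5
        st.t = 1.0
        ev.expire_bonds(st)
        assert st.n_beads == 0


class TestFABinding:
    def test_outside_never_binds(self):
        st = make_state(seed=8)
        straight_filament(st, n=5, pointed=(1.0, 4.0, 0.05))
        for _ in range(100):
            ev.fa_binding_update(st, 0.01)
        assert not st.fa_bound.any()

    def test_two_state_equilibrium(self):
        """Beads held in the capsule approach bound fraction
        k_bind/(k_bind+k_unbind) = 10/11."""
        st = make_state(seed=9)
        prm = st.params
        center_y = prm.fa_front_y + prm.fa_width / 2
        pts = np.column_stack([np.linspace(0.6, 1.4, 200),
                               np.full(200, center_y),
                               np.full(200, 0.05)])
        beads = st.add_beads(pts, birth=0.0)
        for k in range(0, 200, 2):
            st.add_filament(beads[k:k + 2], np.array([np.inf]))
        dt = 0.01
        frac = []
        for step in range(30_000):
            ev.fa_binding_update(st, dt)
            if step > 3_000:
                frac.append(st.fa_bound.mean())
        assert np.mean(frac) == pytest.approx(10 / 11, rel=0.02)


class TestBranching:
    def _mother_state(self):
        st = make_state(seed=10)
        straight_filament(st, n=11, pointed=(1.0, 1.22, 0.1),
                          direction=(0, -1, 0))
        return st

    def test_daughter_created_at_rest_angle(self):
        st = self._mother_state()
        st.spawn_residue = 0.999
        new = ev.spawn_branches(st, 1 / 23.4)
        assert len(new) == 1
        assert st.n_crosslinks == 1
        assert st.cl_type[0] == CL_BRANCH
        i, j, k = st.br_i[0], st.br_j[0], st.br_k[0]
        u = st.pos[j] - st.pos[i]
        v = st.pos[k] - st.pos[j]
        ang = np.degrees(np.arccos(
            (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))))
        assert ang == pytest.approx(70.0, abs=1.0)
        # daughter axis lies in the xy plane
        daughter = st.filaments[-1]
        dz = np.diff(st.pos[daughter, 2])
        assert np.allclose(dz, 0.0, atol=1e-9)
        # mother bead in the nucleation window
        assert 0.20 <= st.pos[j, 1] <= 0.25

    def test_no_eligible_mother_skips(self):
        st = make_state(seed=10)
        straight_filament(st, n=5, pointed=(1.0, 3.0, 0.1))
        st.spawn_residue = 0.999
        assert ev.spawn_branches(st, 1 / 23.4) == []
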