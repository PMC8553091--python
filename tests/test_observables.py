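import numpy as np
import pytest

from lamelliflow import observables as obs
from lamelliflow.integrator import Frame
from lamelliflow.params import AVOGADRO_UM3
from conftest import make_state, straight_filament


def toy_frame(t, pos, uid=None, monomers=None):
    pos = np.asarray(pos, dtype=float)
    n = pos.shape[0]
    uid = np.arange(n) if uid is None else np.asarray(uid)
    monomers = (np.full(n, 37.0) if monomers is None
                else np.asarray(monomers, dtype=float))
    return Frame(t=t, uid=uid, pos=pos, x_unwrapped=pos[:, 0].copy(),
                 fa_bound=np.zeros(n, dtype=bool), monomers=monomers)


class TestFlowProfile:
    def test_rigid_translation_recovered(self):
        rng = np.random.default_rng(0)
        pos0 = rng.uniform([0, 0, 0], [2, 3, 0.2], size=(50, 3))
        frames = [toy_frame(t, pos0 + [0, 0.03 * t, 0])
                  for t in (0.0, 0.5, 1.0, 1.5, 2.0)]
        prof = obs.retrograde_flow_profile(frames, np.arange(0, 3.5, 0.5),
                                           lag=1.0)
        filled = prof.count > 0
        assert np.allclose(prof.value[filled], 0.03, atol=1e-12)
        assert obs.mean_retrograde_speed(frames) == \
            pytest.approx(0.03, abs=1e-12)

    def test_static_network_zero(self):
        pos0 = np.array([[1.0, 1.0, 0.1], [1.0, 2.0, 0.1]])
        frames = [toy_frame(t, pos0) for t in (0.0, 1.0, 2.0)]
        prof = obs.retrograde_flow_profile(frames, np.array([0.5, 1.5, 2.5]))
        assert np.allclose(prof.value[prof.count > 0], 0.0)

    def test_two_zone_velocity_field(self):
        """Bead velocities differing by y-zone land in the right bins."""
        pos0 = np.array([[1.0, 0.5, 0.1]] * 30 + [[1.0, 2.5, 0.1]] * 30)
        v = np.array([0.01] * 30 + [0.05] * 30)
        frames = [toy_frame(t, pos0 + np.outer(v * t, [0, 1, 0]))
                  for t in (0.0, 0.5, 1.0)]
        prof = obs.retrograde_flow_profile(frames,
                                           np.array([0.0, 1.5, 3.0]),
                                           lag=1.0)
        assert prof.value[0] == pytest.approx(0.01, abs=1e-12)
        assert prof.value[1] == pytest.approx(0.05, abs=1e-12)

    def test_beads_matched_by_uid_across_turnover(self):
        f0 = toy_frame(0.0, [[1, 1.0, 0.1], [1, 2.0, 0.1]], uid=[5, 9])
        # bead 5 died; a new bead uid=12 appeared
        f1 = toy_frame(1.0, [[1, 2.1, 0.1], [1, 0.4, 0.1]], uid=[9, 12])
        y, vy = obs.bead_velocities(f0, f1)
        assert vy.size == 1
        assert vy[0] == pytest.approx(0.1)


class TestDensityProfile:
    def test_single_filament_concentration(self):
        """11 beads / 10 bonds = 370 monomers in one bin."""
        st = make_state()
        straight_filament(st, n=11, pointed=(1.0, 1.0, 0.1),
                          direction=(1, 0, 0))
        frame = obs.frame_from_state(st)
        edges = np.array([0.0, 2.0])
        prof = obs.density_profile(frame, edges, box_width=2.0,
                                   box_height=0.2)
        vol = 2.0 * 2.0 * 0.2
        assert prof.value[0] == pytest.approx(370 / (AVOGADRO_UM3 * vol),
                                              rel=1e-12)

    def test_empty_region_zero_and_conservation(self):
        st = make_state()
        straight_filament(st, n=11, pointed=(1.0, 1.0, 0.1),
                          direction=(1, 0, 0))
        frame = obs.frame_from_state(st)
        edges = np.arange(0.0, 4.5, 0.5)
        prof = obs.density_profile(frame, edges, 2.0, 0.2)
        total = np.nansum(prof.value * 2.0 * np.diff(edges) * 0.2
                          * AVOGADRO_UM3)
        assert total == pytest.approx(370.0, rel=1e-9)
        assert prof.value[-1] == 0.0


class TestBondTension:
    def test_rest_zero_stretched_negative(self):
        st = make_state()
        beads = straight_filament(st, n=3, pointed=(1.0, 1.0, 0.1),
                                  direction=(0, 1, 0))
        _, tension = obs.bond_tensions(st)
        assert np.allclose(tension, 0.0, atol=1e-9)
        st.pos[beads[2], 1] += 0.02     # stretch the far bond
        _, tension = obs.bond_tensions(st)
        assert tension[1] == pytest.approx(-20.0, rel=1e-9)  # extension < 0
        st.pos[beads[2], 1] -= 0.05     # now compressed
        _, tension = obs.bond_tensions(st)
        assert tension[1] > 0

    def test_map_averages_onto_grid(self):
        st = make_state()
        straight_filament(st, n=3, pointed=(0.5, 1.0, 0.1),
                          direction=(0, -1, 0))
        m = obs.bond_tension_map(st, np.array([0.0, 1.0, 2.0]),
                                 np.array([0.5, 1.5]))
        assert m.count[0, 0] == 2
        assert m.count[1, 0] == 0


class TestBendingAngles:
    def test_straight_and_right_angle(self):
        st = make_state()
        straight_filament(st, n=11, pointed=(1.0, 1.0, 0.1))
        ys, angles = obs.bending_angle_samples(st)
        assert angles[0] == pytest.approx(0.0, abs=1e-9)
        # bend the second half by 90 degrees
        beads = st.filaments[0]
        mid = st.pos[beads[5]].copy()
        for k in range(6, 11):
            st.pos[beads[k]] = mid + [(k - 5) * 0.1, 0.0, 0.0]
        ys, angles = obs.bending_angle_samples(st)
        assert angles[0] == pytest.approx(90.0, abs=1e-9)

    def test_fragments_skipped(self):
        st = make_state()
        straight_filament(st, n=7, pointed=(1.0, 1.0, 0.1))
        ys, angles = obs.bending_angle_samples(st)
        assert angles.size == 0

    def test_profile_aggregation(self):
        samples = [(np.array([0.5, 1.5]), np.array([10.0, 30.0])),
                   (np.array([0.5]), np.array([20.0]))]
        mean, uq = obs.bending_angle_profile(samples,
                                             np.array([0.0, 1.0, 2.0]))
        assert mean.value[0] == pytest.approx(15.0)
        assert mean.value[1] == pytest.approx(30.0)


class TestVirialStress:
    def test_single_stretched_bond_closed_form(self):
        st = make_state()
        beads = straight_filament(st, n=2, pointed=(1.0, 1.0, 0.1),
                                  direction=(0, 1, 0))
        delta = 0.01
        st.pos[beads[1], 1] += delta    # stretch along y
        vol = 1.0
        s = obs.virial_stress(st, vol)
        k, l0 = st.params.k_actin, st.params.l0
        assert s.sigma[1, 1] == pytest.approx(k * delta * (l0 + delta) / vol,
                                              rel=1e-9)
        assert s.sigma[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert s.sigma[2, 2] == pytest.approx(0.0, abs=1e-12)
        assert s.sigma_T == pytest.approx(k * delta * (l0 + delta) / vol,
                                          rel=1e-9)

    def test_isotropic_ensemble_sigma_T_near_zero(self):
        """Randomly oriented stretched bonds give sigma_T ~ 0 by symmetry
        (Monte-Carlo oracle)."""
        st = make_state(seed=1)
        rng = np.random.default_rng(2)
        centers = rng.uniform([0.2, 0.2, -5], [1.8, 5.0, 5], (400, 3))
        for c in centers:
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            half = 0.055 * d            # bond length 0.11: stretched
            pts = np.array([c - half, c + half])
            beads = st.add_beads(pts, birth=0.0)
            st.add_filament(beads, np.array([np.inf]))
        s = obs.virial_stress(st, volume=10.0)
        scale = abs(s.sigma[0, 0]) + abs(s.sigma[1, 1]) + abs(s.sigma[2, 2])
        assert abs(s.sigma_T) < 0.05 * scale

    def test_selection_excludes_clamped_beads(self):
        st = make_state()
        beads = straight_filament(st, n=2, pointed=(1.0, 1.0, 0.1),
                                  direction=(0, 1, 0))
        st.pos[beads[1], 1] += 0.01
        sel = np.zeros(st.n_beads, dtype=bool)
        full = obs.virial_stress(st, 1.0).sigma_T
        none = obs.virial_stress(st, 1.0, selection=sel).sigma_T
        assert none == pytest.approx(0.0, abs=1e-12)
        sel[0] = True
        half = obs.virial_stress(st, 1.0, selection=sel).sigma_T
        assert half == pytest.approx(full / 2, rel=1e-9)

    def test_zero_volume_rejected(self):
        st = make_state()
        straight_filament(st, n=2)
        with pytest.raises(ValueError):
            obs.virial_stress(st, 0.0)


class TestBundlingDiagnostics:
    def test_nematic_order_limits(self):
        st = make_state()
        for k in range(5):
            straight_filament(st, n=5, pointed=(0.2 + 0.3 * k, 2.0, 0.1),
                              direction=(0, -1, 0))
        assert obs.nematic_order(st, (1.0, 2.5)) == pytest.approx(1.0,
                                                                  abs=1e-9)
        st2 = make_state(seed=3)
        rng = np.random.default_rng(4)
        for k in range(40):
            straight_filament(st2, n=3,
                              pointed=rng.uniform([0, 1, 0.05],
                                                  [2, 2, 0.15]),
                              direction=rng.standard_normal(3))
        assert obs.nematic_order(st2, (0.0, 4.0)) < 0.4

    def test_x_histogram_peaks_at_bundle(self):
        st = make_state()
        for _ in range(4):
            straight_filament(st, n=11, pointed=(1.0, 2.0, 0.1),
                              direction=(0, -1, 0))
        hist = obs.x_density_histogram(st, np.linspace(0, 2, 11),
                                       (0.0, 3.0))
        assert hist.argmax() == 5       # the bin holding x = 1.0
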