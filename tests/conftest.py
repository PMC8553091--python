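import numpy as np
import pytest

from lamelliflow import Parameters, NetworkState


@pytest.fixture
def params():
    return Parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(params=None, seed=0):
    params = params or Parameters()
    return NetworkState(params, rng=np.random.default_rng(seed))


def straight_filament(state, n=11, pointed=(1.0, 0.5, 0.1),
                      direction=(0.0, -1.0, 0.0), spacing=None):
    """Insert one straight filament; returns its bead indices."""
    spacing = spacing or state.params.l0
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    pts = np.asarray(pointed)[None, :] + np.arange(n)[:, None] * spacing * d
    beads = state.add_beads(pts, birth=state.t)
    state.add_filament(beads, np.full(n - 1, np.inf))
    return beads


@pytest.fixture
def two_filament_state():
    """Two crossing filaments, no crosslinks."""
    st = make_state()
    straight_filament(st, pointed=(0.5, 0.5, 0.1), direction=(0, -1, 0))
    straight_filament(st, pointed=(0.2, 0.2, 0.11), direction=(1, 0, 0))
    return st


def random_bent_state(seed=0, n_filaments=3, jitter=0.02):
    """Small network with thermally-jittered filaments, a crosslink and a
    branch triplet, for gradient oracles."""
    rng = np.random.default_rng(seed)
    st = make_state(seed=seed)
    for k in range(n_filaments):
        beads = straight_filament(
            st, n=6, pointed=(0.3 + 0.5 * k, 0.8, 0.05 + 0.03 * k),
            direction=(0.3 * rng.standard_normal(), -1.0,
                       0.1 * rng.standard_normal()))
        st.pos[beads] += jitter * rng.standard_normal((beads.size, 3))
    st.pos[:, 0] %= st.params.box_width
    if n_filaments >= 2:
        st.add_crosslink(1, 7, st.params.k_crosslink,
                         st.params.l0_crosslink, np.inf, 0)
        f0 = st.filaments[0]
        f1 = st.filaments[1]
        st.add_branch_triplet(int(f0[1]), int(f0[2]), int(f1[3]))
    st.invalidate()
    return st
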