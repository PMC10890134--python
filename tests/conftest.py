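import numpy as np
import pytest

import helixscope as hx


@pytest.fixture(scope="session")
def helix26():
    """Ideal 26-residue α-helix Cα trace along +Z."""
    return hx.build_ideal_helix(26)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced synthetic system for fast unit tests."""
    return hx.SyntheticSystemSpec(frame_count=100,
                                  n_phosphates_per_leaflet=64, seed=7)


@pytest.fixture(scope="session")
def small_system(small_spec):
    return hx.build_system(small_spec)


@pytest.fixture(scope="session")
def small_traj(small_spec, small_system):
    return hx.generate_trajectory(small_system, small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
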