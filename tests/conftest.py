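import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from torsiondiff.data import make_ideal_secondary_fixture


@pytest.fixture(scope="session")
def helix_structure():
    return make_ideal_secondary_fixture("helix", 20)


@pytest.fixture(scope="session")
def strand_structure():
    return make_ideal_secondary_fixture("strand", 20)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_angle_matrix(rng: np.random.Generator, rows: int) -> np.ndarray:
    """A valid angle matrix: free dihedrals, bond angles away from 0/pi."""
    mat = np.empty((rows, 6))
    mat[:, :3] = rng.uniform(-np.pi, np.pi, size=(rows, 3))
    mat[:, 3:] = rng.uniform(0.5, np.pi - 0.5, size=(rows, 3))
    return mat
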