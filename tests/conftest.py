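import numpy as np
import pytest

from streamsem import presets
from streamsem.path_model import SampleMoments


@pytest.fixture(scope="session")
def refined_model():
    return presets.refined_model()


@pytest.fixture(scope="session")
def full_model():
    return presets.full_model()


@pytest.fixture(scope="session")
def population_model():
    return presets.refined_population_model()


@pytest.fixture(scope="session")
def implied_corr_moments() -> SampleMoments:
    return presets.refined_implied_correlation()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)


def random_pd_matrix(rng, p: int, jitter: float = 0.5) -> np.ndarray:
    """A random well-conditioned PD matrix (shared test helper)."""
    A = rng.standard_normal((p, p))
    S = A @ A.T / p + jitter * np.eye(p)
    return (S + S.T) / 2.0
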