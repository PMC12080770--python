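import numpy as np
import pytest

from opfatigue import ProtocolConfig, simulate_cohort
from opfatigue.cohort import zero_noise
from opfatigue.pipeline import extract_features, index_observations


@pytest.fixture(scope="session")
def default_cohort():
    """Default 6x7 cohort: (series, observations, latent)."""
    return simulate_cohort(ProtocolConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    series, _, _ = default_cohort
    return extract_features(series)


@pytest.fixture(scope="session")
def cohort_indexed(default_cohort):
    _, obs, _ = default_cohort
    indexed, record = index_observations(obs)
    return indexed, record


@pytest.fixture(scope="session")
def noiseless_cohort():
    return simulate_cohort(zero_noise(ProtocolConfig(seed=3)))


@pytest.fixture(scope="session")
def noiseless_features(noiseless_cohort):
    series, _, _ = noiseless_cohort
    return extract_features(series)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
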