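import numpy as np
import pytest

from trackcloud import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_birds_per_group=4, n_years=2, days=40, n_replicates=3,
                     n_returners=3, seed=11)


@pytest.fixture(scope="session")
def small_population(small_config):
    return simulate_population(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
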