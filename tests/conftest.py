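import numpy as np
import pytest

from silentdropout import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    return simulate_cohort(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
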