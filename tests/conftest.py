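import numpy as np
import pytest

from lncuncert.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale cohort small enough for fast end-to-end tests."""
    return SimulationConfig(n_coding=300, n_lnc=204, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
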