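import numpy as np
import pytest

from evocross import SimulationConfig
from evocross.config import MutationRates


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    cfg = SimulationConfig()
    cfg.ecology.width = cfg.ecology.height = 8
    return cfg


@pytest.fixture
def tiny_config():
    cfg = SimulationConfig()
    cfg.ecology.width = cfg.ecology.height = 4
    return cfg


@pytest.fixture
def zero_rates():
    return MutationRates.zero()
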