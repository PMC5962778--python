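import numpy as np
import pytest

from handregard import config as cfgmod


@pytest.fixture(scope="session")
def full_cfg():
    return cfgmod.validate(cfgmod.full_preset())


@pytest.fixture(scope="session")
def scaled_cfg():
    return cfgmod.validate(cfgmod.scaled_preset())


@pytest.fixture
def geometry(full_cfg):
    return full_cfg.geometry


@pytest.fixture
def layout(full_cfg):
    return full_cfg.layout


@pytest.fixture
def rng():
    return np.random.default_rng(20240515)
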