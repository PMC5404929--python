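import numpy as np
import pytest

from snarepore import ModelParams, free_energy_profile


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def profile_n0(params):
    return free_energy_profile(None, 0, params)


@pytest.fixture(scope="session")
def profile_n15(params):
    return free_energy_profile(None, 15, params)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
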