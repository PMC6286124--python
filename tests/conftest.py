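import numpy as np
import pytest

from camkii_switch.params import Parameters, SystemConfig


@pytest.fixture(scope="session")
def params():
    return Parameters()


@pytest.fixture(scope="session")
def cfg():
    return SystemConfig(N_CaMKII=12, N_PP1=60, volume=0.0183)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
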