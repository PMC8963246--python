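import numpy as np
import pytest

import rtdcca as rt


@pytest.fixture(scope="session")
def mc_pair_1024():
    """One default mc-ARFIMA pair of length 1024, shared across tests."""
    x, y = rt.simulate_mc_arfima(rt.DEFAULT_MC_ARFIMA, 1024, seed=12345)
    return x, y


@pytest.fixture(scope="session")
def scales_1024():
    """Standard scale preset for N=1024 with whole-signal analysis window."""
    return rt.preset_for_length(1024)


@pytest.fixture
def rng():
    return np.random.default_rng(987)
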