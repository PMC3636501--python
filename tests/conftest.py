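import numpy as np
import pytest

import ca3metric as cm


@pytest.fixture(scope="session")
def env():
    return cm.TorusEnvironment()


@pytest.fixture(scope="session")
def small_system(env):
    """A small DG + CA3 system shared by dynamics tests."""
    pop = cm.sample_dg_population(1000, seed=2, env=env)
    net = cm.default_network(1000, 100, c_mf=50, c_rc=60, seed=3)
    return pop, net


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
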