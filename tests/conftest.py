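import numpy as np
import pytest

from ctransit import CompartmentalSystem, emanuel_system


@pytest.fixture(scope="session")
def emanuel():
    return emanuel_system()


@pytest.fixture
def one_pool():
    # single pool with loss rate k = 0.5 /yr: age = transit time = Exp(0.5)
    return CompartmentalSystem(B=[[-0.5]], u=[2.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
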