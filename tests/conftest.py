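import numpy as np
import pytest

from adapts import CARDIAC_PROTOCOL, LIVER_PROTOCOL, DecaySignal


@pytest.fixture
def cardiac():
    return CARDIAC_PROTOCOL


@pytest.fixture
def liver():
    return LIVER_PROTOCOL


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def monoexp_signal(protocol, pd=100.0, t2=10.0):
    return DecaySignal(protocol, pd * np.exp(-protocol.te_array / t2))


@pytest.fixture
def noiseless_cardiac():
    return monoexp_signal(CARDIAC_PROTOCOL, 100.0, 10.0)
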