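import numpy as np
import pytest

from misinfogame import GameConfig, ReceiverStrategy, TransmitterStrategy
from misinfogame.ensemble import _sample_params


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def noiseless_config():
    """No execution or perception errors."""
    return GameConfig(epsilon=0.0, eta=0.0)


@pytest.fixture
def memory_receiver():
    """A pure-memory receiver with a truth-leaning behavioral profile."""
    return ReceiverStrategy(a1=1.0, p_ct=0.9, p_cf=0.2, p_nt=0.6, p_nf=0.3)


def random_pair(rng, a0_max=0.9):
    """A random viable linear transmitter and a random receiver."""
    a, b, g, t = _sample_params(1, True, rng)[0]
    transmitter = TransmitterStrategy.linear(alpha=a, beta=b, gamma=g, theta=t)
    receiver = ReceiverStrategy(
        a0=rng.random() * a0_max,
        a1=rng.random(),
        p0=rng.random(),
        p_ct=rng.random(),
        p_cf=rng.random(),
        p_nt=rng.random(),
        p_nf=rng.random(),
    )
    return transmitter, receiver
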