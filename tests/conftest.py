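import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_one_hot(rng, n, m_label):
    y = np.zeros((n, m_label))
    y[np.arange(n), rng.integers(0, m_label, n)] = 1.0
    return y
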