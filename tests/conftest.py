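import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_instance(rng):
    """A random 20x6 nonnegative matrix with two classes of three samples."""
    V = rng.uniform(0.5, 10.0, size=(20, 6))
    labels = np.array([0, 0, 0, 1, 1, 1])
    return V, labels


def random_factors(rng, n, K, L):
    W = rng.uniform(0.1, 1.0, size=(n, K))
    W /= W.sum(axis=0, keepdims=True)
    H = rng.uniform(0.1, 5.0, size=(K, L))
    return W, H
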