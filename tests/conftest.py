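import numpy as np
import pytest

from loopferret.contacts import ContactMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric_matrix(rng, n=50, chrom="test", bin_size=10_000):
    """Dense random nonnegative symmetric counts with a decaying diagonal."""
    a = rng.exponential(scale=2.0, size=(n, n))
    counts = np.triu(a) + np.triu(a, 1).T
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    counts += 10.0 / (d + 1.0)
    return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=counts)


@pytest.fixture
def random_matrix(rng):
    return random_symmetric_matrix(rng)
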