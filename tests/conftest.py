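import numpy as np
import pytest

from schicab import ContactMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_symmetric_counts(rng, n, lam=5.0):
    """Random symmetric non-negative integer matrix."""
    m = rng.poisson(lam, (n, n)).astype(float)
    return np.triu(m) + np.triu(m, 1).T


@pytest.fixture
def small_matrix(rng):
    return ContactMatrix(values=random_symmetric_counts(rng, 8))


def two_block_matrix(n=6, hi=10.0, lo=1.0, split=None):
    """Noise-free checkerboard matrix with one change point."""
    split = split if split is not None else n // 2
    v = np.full((n, n), lo)
    v[:split, :split] = hi
    v[split:, split:] = hi
    return ContactMatrix(values=v)
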