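import numpy as np
import pytest

from zipfbias.rankfreq import RankFrequencyCounts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """The six-event demo dataset used throughout the likelihood tests."""
    return RankFrequencyCounts(np.array([10, 3, 3, 2, 1, 1]))


def random_counts(rng, W_max=7, n_max=6):
    """A random small rank-frequency vector (counts in 1..n_max)."""
    W = int(rng.integers(2, W_max + 1))
    c = np.sort(rng.integers(1, n_max + 1, size=W))[::-1]
    return RankFrequencyCounts(c)
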