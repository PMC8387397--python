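import numpy as np
import pytest

from sdpop.popgen import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(data, positions=None, **kwargs):
    data = np.asarray(data, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, data.shape[1] + 1)
    return HaplotypeMatrix(data, positions, **kwargs)


@pytest.fixture
def small_matrix():
    # 6 haplotypes × 5 segregating sites
    return make_matrix([
        [1, 0, 0, 1, 0],
        [1, 0, 0, 1, 0],
        [1, 1, 0, 0, 0],
        [0, 1, 0, 0, 1],
        [0, 1, 1, 0, 1],
        [0, 0, 1, 0, 1],
    ])
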