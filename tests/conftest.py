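import numpy as np
import pytest

from octad.backbone import RegionGrid
from octad.bank import NominalBank, build_bank


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_grid(rng, h=3, w=3, d=4, source_id="g"):
    return RegionGrid(grid=rng.normal(size=(h, w, d)), source_id=source_id, grid_stride=8.0)


def make_bank(rng, n=50, d=4, grid_shape=(1, 1)):
    vectors = rng.normal(size=(n, d))
    positions = np.zeros((n, 2), dtype=np.int64)
    return NominalBank(vectors=vectors, positions=positions, grid_shape=grid_shape)


@pytest.fixture()
def small_bank(rng):
    return make_bank(rng)


def brute_knn_mean(query, vectors, k):
    """Independent exhaustive oracle: sort all distances, average the k smallest."""
    d = np.sort(np.sqrt(((np.asarray(vectors) - np.asarray(query)) ** 2).sum(axis=1)))
    return d[:k].mean()
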