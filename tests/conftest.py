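import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from bidcg.distances import DistanceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_pair_distances():
    """Four points in two tight, well-separated pairs."""
    pos = np.array([[0.0], [0.1], [10.0], [10.1]])
    return DistanceMatrix(list("abcd"), squareform(pdist(pos)))


@pytest.fixture
def two_scale_distances():
    """Four tight pairs forming two super-groups (nested structure)."""
    pos = np.array([0.0, 0.05, 1.0, 1.05, 20.0, 20.05, 21.0, 21.05])
    return DistanceMatrix(list("abcdefgh"),
                          np.abs(np.subtract.outer(pos, pos)))


def planted_blobs(n_clusters: int, per_cluster: int, seed: int,
                  dim: int = 4, spread: float = 0.25,
                  min_ratio: float = 10.0):
    """Gaussian blobs with guaranteed between/within separation ratio."""
    r = np.random.default_rng(seed)
    while True:
        centers = r.normal(0, 10, size=(n_clusters, dim))
        if n_clusters == 1:
            break
        cd = squareform(pdist(centers))
        np.fill_diagonal(cd, np.inf)
        # within scale ~ spread * sqrt(2 dim); demand a 10x margin
        if cd.min() >= min_ratio * spread * np.sqrt(2 * dim):
            break
    X = np.vstack([c + r.normal(0, spread, size=(per_cluster, dim))
                   for c in centers])
    items = [f"x{i}" for i in range(len(X))]
    truth = [list(range(per_cluster * k, per_cluster * (k + 1)))
             for k in range(n_clusters)]
    return DistanceMatrix(items, squareform(pdist(X))), truth
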