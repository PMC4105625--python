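"""Distance measures between expression vectors.

Euclidean distance is the default for synthetic benchmark matrices; the
Spearman-based distance (1 - rank Pearson correlation) is preferred for real
expression data, where only the monotone shape of a profile matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .core import ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "rank_transform",
    "spearman_distance",
    "euclidean_distance",
    "pairwise_distances",
]

METRICS = ("euclidean", "spearman")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances d(i, j) over an ordered identifier set."""

    items: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.items = [str(x) for x in self.items]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match item count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distance")
        if np.any(self.values < 0):
            raise ValueError("negative distance")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        # exact symmetry / zero diagonal for downstream code
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.items)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.items, columns=self.items).to_csv(
            path, sep="\t", float_format="%.10g"
        )


def rank_transform(v) -> np.ndarray:
    """Average ranks in [1, n]; ties get the mean of their covered ranks."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("rank_transform expects a nonempty 1-D vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite value in vector")
    return rankdata(v, method="average")


def spearman_distance(u, v) -> float:
    """1 - rho_s, the Pearson correlation of the two rank vectors; in [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("length mismatch")
    if u.size < 3:
        raise ValueError("spearman_distance needs vectors of length >= 3")
    ru, rv = rank_transform(u), rank_transform(v)
    su, sv = ru.std(), rv.std()
    if su == 0 or sv == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho = float(np.dot(ru - ru.mean(), rv - rv.mean()) / (u.size * su * sv))
    return float(np.clip(1.0 - rho, 0.0, 2.0))


def euclidean_distance(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("length mismatch")
    return float(np.linalg.norm(u - v))


def _spearman_pairwise(profiles: np.ndarray, items) -> np.ndarray:
    # rank each row, then 1 - Pearson correlation of ranks
    n, p = profiles.shape
    if p < 3:
        raise ValueError("spearman needs >= 3 features")
    ranks = np.apply_along_axis(rankdata, 1, profiles)
    sd = ranks.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"constant restricted profile for item {items[bad[0]]!r}: "
            "Spearman correlation undefined"
        )
    z = (ranks - ranks.mean(axis=1, keepdims=True)) / sd[:, None]
    rho = z @ z.T / p
    d = 1.0 - np.clip(rho, -1.0, 1.0)
    return np.clip(d, 0.0, 2.0)


def pairwise_distances(
    m: ExpressionMatrix,
    axis: str,
    metric: str = "euclidean",
    feature_subset=None,
) -> DistanceMatrix:
    """Pairwise distances between all items of one axis of an expression matrix.

    Parameters
    ----------
    axis : {"genes", "samples"}
        Which axis provides the items being compared.
    metric : {"euclidean", "spearman"}
    feature_subset : iterable of identifiers, optional
        Restrict the feature axis (the opposite axis) to this subset; the
        items themselves are never restricted. Defaults to all features.
    """
    if axis not in ("genes", "samples"):
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if axis == "genes":
        items = m.gene_ids
        profiles = m.values
        if feature_subset is not None:
            idx = m.sample_index(list(feature_subset))
            if idx.size == 0:
                raise ValueError("empty feature subset")
            profiles = profiles[:, idx]
    else:
        items = m.sample_ids
        profiles = m.values.T
        if feature_subset is not None:
            idx = m.gene_index(list(feature_subset))
            if idx.size == 0:
                raise ValueError("empty feature subset")
            profiles = profiles[:, idx]
    if metric == "euclidean":
        d = squareform(pdist(profiles, metric="euclidean"))
    else:
        d = _spearman_pairwise(profiles, items)
    return DistanceMatrix(list(items), d)
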