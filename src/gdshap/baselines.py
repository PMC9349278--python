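"""Baseline-distribution construction and selection.

The attribution contrast is defined by a distribution of baseline rows —
typically the training data, a seeded subsample of it, or an interpretable
subpopulation.  For the latter, training rows are clustered by k-means on a
small, human-meaningful subset of features (age and sex, say), and each
explicand is explained against the full-width rows of its nearest cluster:
"compared to people like you".

The k-means fit is a plain Lloyd iteration with k-means++ seeding and
multiple restarts; the within-cluster sum of squares is asserted
non-increasing across iterations on every fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import kmeans_plusplus

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineDistribution",
    "ClusterModel",
    "fit_clusters",
    "select_baselines",
    "subsample",
]


@dataclass
class BaselineDistribution:
    """Uniformly weighted set of baseline rows."""

    rows: np.ndarray
    provenance: str = "manual"

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.shape[0] < 1:
            raise ValueError("baseline distribution needs at least one row")

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def mean_row(self) -> np.ndarray:
        return self.rows.mean(axis=0)


@dataclass
class ClusterModel:
    reduced_features: np.ndarray  # indices of the clustering feature subset
    means: np.ndarray  # (k, |reduced|) cluster means in reduced space
    labels: np.ndarray  # training-row assignments
    inertia: float  # within-cluster sum of squares at convergence

    @property
    def k(self) -> int:
        return self.means.shape[0]

    def nearest(self, x: np.ndarray) -> int:
        """Index of the nearest cluster mean in reduced space; ties -> lowest."""
        x = np.asarray(x, dtype=float).reshape(-1)
        xr = x[self.reduced_features]
        d2 = ((self.means - xr) ** 2).sum(axis=1)
        return int(np.argmin(d2))  # argmin returns the first (lowest) index on ties


def _lloyd(Xr: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300, tol: float = 1e-10):
    means, _ = kmeans_plusplus(Xr, n_clusters=k, random_state=int(rng.integers(2**31 - 1)))
    prev_obj = np.inf
    for _ in range(max_iter):
        d2 = ((Xr[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        obj = float(d2[np.arange(Xr.shape[0]), labels].sum())
        assert obj <= prev_obj + 1e-9 * max(1.0, abs(prev_obj)), (
            "k-means objective increased across a Lloyd iteration"
        )
        if prev_obj - obj <= tol * max(1.0, obj):
            prev_obj = obj
            break
        prev_obj = obj
        for j in range(k):
            members = Xr[labels == j]
            if members.shape[0]:
                means[j] = members.mean(axis=0)
            else:
                # re-seed an empty cluster at the point farthest from its mean
                means[j] = Xr[d2.min(axis=1).argmax()]
    return means, labels, prev_obj


def fit_clusters(
    X_train: np.ndarray,
    reduced_features,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterModel:
    """K-means over the reduced feature columns of the training data.

    Runs ``n_restarts`` independent Lloyd fits with k-means++ seeding and
    keeps the lowest within-cluster sum of squares; deterministic given
    ``seed``.  Features outside ``reduced_features`` never influence the
    clustering.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    reduced = np.asarray(reduced_features, dtype=int).reshape(-1)
    if reduced.size == 0:
        raise ValueError("reduced feature set is empty")
    if k < 1 or k > X_train.shape[0]:
        raise ValueError(f"k={k} must be in [1, n_rows={X_train.shape[0]}]")
    Xr = X_train[:, reduced]
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        means, labels, obj = _lloyd(Xr, k, rng)
        if best is None or obj < best[2]:
            best = (means, labels, obj)
    means, labels, obj = best
    return ClusterModel(reduced_features=reduced, means=means, labels=labels, inertia=obj)


def select_baselines(
    x_e: np.ndarray,
    clusters: ClusterModel,
    X_train: np.ndarray,
    exclude_explicand: bool = False,
) -> BaselineDistribution:
    """Training rows of the cluster nearest the explicand (full width).

    Distances use only the reduced clustering features; ties go to the
    lowest cluster index.  ``exclude_explicand`` drops rows identical to the
    explicand from the returned distribution.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    j = clusters.nearest(x_e)
    rows = X_train[clusters.labels == j]
    if exclude_explicand:
        keep = ~np.all(rows == np.asarray(x_e, dtype=float).reshape(1, -1), axis=1)
        if keep.any():
            rows = rows[keep]
    logger.debug("select_baselines: cluster %d with %d rows", j, rows.shape[0])
    return BaselineDistribution(rows, provenance=f"cluster {j}")


def subsample(D, n_b: int, seed: int | None = None) -> BaselineDistribution:
    """Seeded uniform subsample of baseline rows.

    Without replacement when ``n_b <= |D|``; with replacement (and a logged
    warning) otherwise.  The conventional size for stable attributions is
    n_b = 1000.
    """
    rows = np.atleast_2d(np.asarray(getattr(D, "rows", D), dtype=float))
    if n_b < 1:
        raise ValueError("n_b must be >= 1")
    rng = np.random.default_rng(seed)
    replace = n_b > rows.shape[0]
    if replace:
        logger.warning(
            "subsample: requested %d baselines from %d rows; sampling with replacement",
            n_b,
            rows.shape[0],
        )
    idx = rng.choice(rows.shape[0], size=n_b, replace=replace)
    return BaselineDistribution(rows[idx], provenance=f"subsample({n_b})")
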