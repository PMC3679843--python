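"""Pairwise distances and the sorted training neighbour table.

The neighbour table is the n × (n−1) matrix holding, in row i, the distances
of training sample i to every other training sample ranked in increasing
order; every threshold in the kNN applicability-domain construction is read
off this table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io import _as_matrix

__all__ = [
    "MetricSpec",
    "NeighbourTable",
    "VALID_METRICS",
    "resolve_metric",
    "pairwise_distances",
    "build_neighbour_table",
]

VALID_METRICS = ("euclidean", "manhattan", "mahalanobis")

# cdist condition-number guard: beyond this the covariance is treated as singular
_MAX_COND = 1e12


@dataclass
class MetricSpec:
    """A distance metric: name plus, for Mahalanobis, the inverse covariance."""

    name: str = "euclidean"
    inv_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.name not in VALID_METRICS:
            raise ValueError(f"unknown metric {self.name!r}; choose from {VALID_METRICS}")
        if self.inv_cov is not None:
            self.inv_cov = np.asarray(self.inv_cov, dtype=float)


def resolve_metric(metric, X_train=None) -> MetricSpec:
    """Normalise a metric name or spec, estimating the Mahalanobis inverse
    covariance from the (already pretreated) training matrix when needed.

    The covariance uses the n−1 denominator.  A singular or near-singular
    covariance (p ≥ n, collinear descriptors) is an error: AD membership
    under a pseudo-inverted metric would be ill-defined.  Regularize the
    descriptors or choose another metric instead.
    """
    spec = metric if isinstance(metric, MetricSpec) else MetricSpec(str(metric))
    if spec.name == "mahalanobis" and spec.inv_cov is None:
        if X_train is None:
            raise ValueError("mahalanobis metric needs training data or an inverse covariance")
        X = _as_matrix(X_train)
        if X.shape[0] < 2:
            raise ValueError("mahalanobis covariance needs at least two training samples")
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        if np.linalg.cond(cov) > _MAX_COND:
            raise ValueError(
                "training covariance is singular or near-singular; "
                "remove collinear descriptors, add samples, or use the euclidean metric"
            )
        spec = MetricSpec("mahalanobis", np.linalg.inv(cov))
    return spec


def pairwise_distances(A, B, metric: MetricSpec | str = "euclidean") -> np.ndarray:
    """Distance matrix between the rows of A (a×p) and B (b×p)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B must have the same number of columns")
    spec = metric if isinstance(metric, MetricSpec) else MetricSpec(str(metric))
    if spec.name == "euclidean":
        return cdist(A, B, metric="euclidean")
    if spec.name == "manhattan":
        return cdist(A, B, metric="cityblock")
    if spec.inv_cov is None:
        raise ValueError("mahalanobis metric requires a resolved inverse covariance")
    return cdist(A, B, metric="mahalanobis", VI=spec.inv_cov)


@dataclass
class NeighbourTable:
    """Row-sorted training distance table.

    ``D[i, j]`` is the distance of training sample i to its (j+1)-th nearest
    neighbour (self excluded), so each row is non-decreasing; ``idx[i, j]``
    is the training index attaining it.  Ties are broken by ascending
    training-sample index.
    """

    D: np.ndarray
    idx: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.idx = np.asarray(self.idx, dtype=int)
        if self.D.shape != self.idx.shape or self.D.ndim != 2:
            raise ValueError("D and idx must be 2-D arrays of equal shape")
        if self.D.shape[1] != self.D.shape[0] - 1:
            raise ValueError("neighbour table must be n x (n-1)")

    @property
    def n(self) -> int:
        return self.D.shape[0]


def build_neighbour_table(X_train, metric: MetricSpec | str = "euclidean") -> NeighbourTable:
    """Build the sorted neighbour table for a training matrix (n ≥ 2)."""
    X = _as_matrix(X_train)
    n = X.shape[0]
    if n < 2:
        raise ValueError("neighbour table needs at least two training samples")
    spec = resolve_metric(metric, X)
    full = pairwise_distances(X, X, spec)
    # enforce exact symmetry so the sort is independent of row/column roles
    full = 0.5 * (full + full.T)
    np.fill_diagonal(full, np.inf)
    order = np.argsort(full, axis=1, kind="stable")[:, : n - 1]
    D = np.take_along_axis(full, order, axis=1)
    return NeighbourTable(D=D, idx=order)
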