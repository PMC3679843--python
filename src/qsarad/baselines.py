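"""Classical applicability-domain methods used for comparison.

Bounding box (descriptor ranges), PCA bounding box (score ranges on retained
principal components), convex hull membership, centroid-distance with a
percentile threshold, and the classical kNN rule with a single general
threshold.  All range and threshold comparisons are inclusive.  Following
common practice, every method except the bounding box and the convex hull
autoscales the descriptors with training statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .io import _as_matrix, autoscale_apply, autoscale_fit
from .distances import build_neighbour_table, pairwise_distances, resolve_metric
from .knn_ad import _quantile, average_knn_distances

__all__ = [
    "BaselineADResult",
    "BoundingBoxAD",
    "PCABoundingBoxAD",
    "ConvexHullAD",
    "CentroidDistanceAD",
    "ClassicalKNNAD",
    "bounding_box_ad",
    "pca_bounding_box_ad",
    "convex_hull_ad",
    "centroid_distance_ad",
    "classical_knn_ad",
]


@dataclass
class BaselineADResult:
    """In/out verdicts of one comparison method over a query set."""

    method_name: str
    in_ad: np.ndarray
    threshold: float | None = None
    extras: dict = field(default_factory=dict)


class BoundingBoxAD(BaseEstimator):
    """Descriptor-range AD: a query is inside iff every descriptor lies within
    the training [min, max] interval (inclusive).  No pretreatment."""

    def fit(self, X, y=None):
        Xm = _as_matrix(X)
        self.n_features_in_ = Xm.shape[1]
        self.mins_ = Xm.min(axis=0)
        self.maxs_ = Xm.max(axis=0)
        return self

    def predict(self, X) -> np.ndarray:
        Xq = _as_matrix(X)
        if Xq.shape[1] != self.n_features_in_:
            raise ValueError("query descriptor count does not match training data")
        return np.all((Xq >= self.mins_) & (Xq <= self.maxs_), axis=1)


class PCABoundingBoxAD(BaseEstimator):
    """Bounding box in principal-component scores.

    Descriptors are autoscaled with training statistics, principal axes are
    fitted on the training scores, components are retained up to the
    requested cumulative explained variance, and the range check is applied
    to the retained score columns of the projected query.
    """

    def __init__(self, variance_retained: float = 0.95):
        self.variance_retained = variance_retained

    def fit(self, X, y=None):
        if not 0 < self.variance_retained <= 1:
            raise ValueError("variance_retained must be in (0, 1]")
        Xm = _as_matrix(X)
        self.n_features_in_ = Xm.shape[1]
        self.scaling_ = autoscale_fit(Xm)
        Xs = autoscale_apply(Xm, self.scaling_)
        self.pca_ = PCA(n_components=min(Xs.shape)).fit(Xs)
        cum = np.cumsum(self.pca_.explained_variance_ratio_)
        self.n_components_ = int(
            min(np.searchsorted(cum, self.variance_retained - 1e-12) + 1, cum.size)
        )
        scores = self.pca_.transform(Xs)[:, : self.n_components_]
        self.score_mins_ = scores.min(axis=0)
        self.score_maxs_ = scores.max(axis=0)
        return self

    def predict(self, X) -> np.ndarray:
        Xs = autoscale_apply(_as_matrix(X), self.scaling_)
        scores = self.pca_.transform(Xs)[:, : self.n_components_]
        return np.all((scores >= self.score_mins_) & (scores <= self.score_maxs_), axis=1)


class ConvexHullAD(BaseEstimator):
    """Convex-hull AD decided by linear feasibility.

    A query q is inside iff weights λ ≥ 0 with Σλ_i = 1 and Σλ_i x_i = q
    exist.  Feasibility (rather than facet enumeration) stays robust in the
    five-and-more-dimensional descriptor spaces typical of QSAR models.
    Boundary points are inside.  No pretreatment (the hull is affine
    equivariant, so scaling would not change the verdicts anyway).
    """

    def __init__(self, tol: float = 1e-9):
        self.tol = tol

    def fit(self, X, y=None):
        Xm = _as_matrix(X)
        self.n_features_in_ = Xm.shape[1]
        self.X_train_ = np.asarray(Xm, dtype=float)
        return self

    def predict(self, X) -> np.ndarray:
        Xq = _as_matrix(X)
        if Xq.shape[1] != self.n_features_in_:
            raise ValueError("query descriptor count does not match training data")
        n = self.X_train_.shape[0]
        A_eq = np.vstack([self.X_train_.T, np.ones(n)])
        c = np.zeros(n)
        out = np.empty(Xq.shape[0], dtype=bool)
        for j, q in enumerate(Xq):
            b_eq = np.append(q, 1.0)
            res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
            if res.status == 0 and res.x is not None:
                resid = np.abs(A_eq @ res.x - b_eq).max()
                out[j] = resid <= self.tol * (1.0 + np.abs(b_eq).max())
            elif res.status == 2:  # proven infeasible
                out[j] = False
            else:
                raise ArithmeticError(
                    f"convex-hull feasibility solve failed for query row {j}: {res.message}"
                )
        return out


class CentroidDistanceAD(BaseEstimator):
    """Distance-to-centroid AD with a percentile threshold.

    Descriptors are autoscaled, the distance of every training sample to the
    training centroid is computed (Euclidean or Mahalanobis), and the stated
    percentile of those distances becomes the inclusive threshold for queries.
    """

    def __init__(self, metric="euclidean", percentile: float = 95.0,
                 quantile_method: str = "linear"):
        self.metric = metric
        self.percentile = percentile
        self.quantile_method = quantile_method

    def fit(self, X, y=None):
        Xm = _as_matrix(X)
        self.n_features_in_ = Xm.shape[1]
        self.scaling_ = autoscale_fit(Xm)
        Xs = autoscale_apply(Xm, self.scaling_)
        spec = resolve_metric(self.metric, Xs)
        if spec.name == "manhattan":
            raise ValueError("centroid-distance AD supports euclidean or mahalanobis")
        self.metric_spec_ = spec
        self.centroid_ = Xs.mean(axis=0)
        self.train_distances_ = pairwise_distances(Xs, self.centroid_[None, :], spec).ravel()
        self.threshold_ = float(
            _quantile(self.train_distances_, self.percentile / 100.0, self.quantile_method)
        )
        return self

    def distances(self, X) -> np.ndarray:
        Xs = autoscale_apply(_as_matrix(X), self.scaling_)
        return pairwise_distances(Xs, self.centroid_[None, :], self.metric_spec_).ravel()

    def predict(self, X) -> np.ndarray:
        return self.distances(X) <= self.threshold_


class ClassicalKNNAD(BaseEstimator):
    """Classical kNN AD with one general threshold.

    The average distance of every training sample to its k nearest training
    neighbours is computed; the stated percentile of that vector is the
    single threshold.  A query is inside iff its average distance to its own
    k nearest training samples does not exceed it.  Defaults follow common
    usage: k = 5, 95th percentile, autoscaled Euclidean distances.
    """

    def __init__(self, k: int = 5, percentile: float = 95.0, metric="euclidean",
                 scale: bool = True, quantile_method: str = "linear"):
        self.k = k
        self.percentile = percentile
        self.metric = metric
        self.scale = scale
        self.quantile_method = quantile_method

    def fit(self, X, y=None):
        Xm = _as_matrix(X)
        n = Xm.shape[0]
        if not 1 <= self.k <= n - 1:
            raise ValueError(f"k must be in [1, {n - 1}], got {self.k}")
        self.n_features_in_ = Xm.shape[1]
        if self.scale:
            self.scaling_ = autoscale_fit(Xm)
            Xs = autoscale_apply(Xm, self.scaling_)
        else:
            self.scaling_ = None
            Xs = np.asarray(Xm, dtype=float)
        self.X_train_scaled_ = Xs
        self.metric_spec_ = resolve_metric(self.metric, Xs)
        table = build_neighbour_table(Xs, self.metric_spec_)
        self.train_avg_dists_ = average_knn_distances(table, self.k)
        self.threshold_ = float(
            _quantile(self.train_avg_dists_, self.percentile / 100.0, self.quantile_method)
        )
        return self

    def average_distances(self, X) -> np.ndarray:
        Xq = _as_matrix(X)
        if self.scaling_ is not None:
            Xq = autoscale_apply(Xq, self.scaling_)
        D = pairwise_distances(Xq, self.X_train_scaled_, self.metric_spec_)
        D.sort(axis=1)
        return D[:, : self.k].mean(axis=1)

    def predict(self, X) -> np.ndarray:
        return self.average_distances(X) <= self.threshold_


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------


def bounding_box_ad(train, query) -> BaselineADResult:
    est = BoundingBoxAD().fit(train)
    return BaselineADResult("Bounding box", est.predict(query))


def pca_bounding_box_ad(train, query, variance_retained: float = 0.95) -> BaselineADResult:
    est = PCABoundingBoxAD(variance_retained=variance_retained).fit(train)
    return BaselineADResult(
        "PCA bounding box", est.predict(query),
        extras={"n_components": est.n_components_},
    )


def convex_hull_ad(train, query, tol: float = 1e-9) -> BaselineADResult:
    est = ConvexHullAD(tol=tol).fit(train)
    return BaselineADResult("Convex hull", est.predict(query))


def centroid_distance_ad(train, query, metric="euclidean",
                         percentile: float = 95.0) -> BaselineADResult:
    est = CentroidDistanceAD(metric=metric, percentile=percentile).fit(train)
    name = f"{est.metric_spec_.name.capitalize()} dist ({percentile:g} percentile)"
    return BaselineADResult(
        name, est.predict(query), threshold=est.threshold_,
        extras={"distances": est.distances(query)},
    )


def classical_knn_ad(train, query, k: int = 5, percentile: float = 95.0,
                     metric="euclidean") -> BaselineADResult:
    est = ClassicalKNNAD(k=k, percentile=percentile, metric=metric).fit(train)
    return BaselineADResult(
        f"Classical kNN (k={k})", est.predict(query), threshold=est.threshold_,
        extras={"average_distances": est.average_distances(query)},
    )
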