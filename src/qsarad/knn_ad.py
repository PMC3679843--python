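"""kNN applicability domain with per-training-sample thresholds.

The construction proceeds in three steps on the (pretreated) training set:

1. For every training sample i, the average distance to its k nearest
   neighbours, d̄_i(k), is read off the sorted neighbour table.
2. A single reference value — the Tukey upper fence of the d̄_i(k) vector,
   Q3 + 1.5·(Q3 − Q1) — bounds how far a "neighbourhood" may reach.
3. Each sample keeps the neighbour distances not exceeding the reference
   value: their count K_i measures local density and their mean t_i is the
   sample's individual threshold.  A sample retaining none (an outlier,
   K_i = 0) inherits the smallest threshold in the training set, so it still
   contributes to the domain but only in its immediate vicinity.

A query j is inside the applicability domain iff its distance to at least
one training sample i satisfies D_ij ≤ t_i; the count K_j of such training
samples grades the reliability of the prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .io import DescriptorTable, ScalingParams, _as_matrix, autoscale_apply, autoscale_fit
from .distances import (
    MetricSpec,
    NeighbourTable,
    build_neighbour_table,
    pairwise_distances,
    resolve_metric,
)

__all__ = [
    "ADDecision",
    "KNNApplicabilityDomain",
    "average_knn_distances",
    "reference_value",
    "thresholds_from_refval",
    "fit_ad",
    "apply_ad",
]

_QUANTILE_METHODS = {"linear": "linear", "nearest_rank": "inverted_cdf"}


def _quantile(values: np.ndarray, q, method: str = "linear") -> np.ndarray:
    if method not in _QUANTILE_METHODS:
        raise ValueError(f"quantile method must be one of {sorted(_QUANTILE_METHODS)}")
    return np.quantile(np.asarray(values, dtype=float), q, method=_QUANTILE_METHODS[method])


@dataclass
class ADDecision:
    """Applicability-domain verdict for one query sample.

    ``K_j`` counts the training samples whose individual threshold the query
    satisfies; the query is inside the domain iff ``K_j >= 1``.
    """

    sample_id: str
    in_ad: bool
    K_j: int
    nearest_satisfying_distance: float | None = None


def average_knn_distances(table: NeighbourTable, k: int) -> np.ndarray:
    """d̄_i(k): mean of the first k sorted neighbour distances, per sample."""
    n = table.n
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    return table.D[:, :k].mean(axis=1)


def reference_value(avg_dists, quantile_method: str = "linear") -> float:
    """Tukey upper fence Q3 + 1.5·(Q3 − Q1) of the average-distance vector."""
    v = np.asarray(avg_dists, dtype=float)
    if v.size == 0:
        raise ValueError("cannot compute a reference value from an empty vector")
    q1, q3 = _quantile(v, [0.25, 0.75], quantile_method)
    return float(q3 + 1.5 * (q3 - q1))


def thresholds_from_refval(
    table: NeighbourTable, ref_val: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbourhood densities K_i, thresholds t_i and the fallback mask.

    K_i counts the row-i distances ≤ ref_val and t_i is their mean.  Samples
    with K_i = 0 take the minimum threshold among samples with K_i ≥ 1 and
    are flagged in the fallback mask.  If every sample has K_i = 0 no
    applicability domain can be defined and an error is raised.
    """
    if not np.isfinite(ref_val) or ref_val < 0:
        raise ValueError("ref_val must be finite and nonnegative")
    D = table.D
    K = (D <= ref_val).sum(axis=1).astype(int)
    has = K > 0
    if not has.any():
        raise ValueError(
            "every training sample has an empty neighbourhood (all K_i = 0); "
            "no threshold exists to fall back on and no AD can be defined"
        )
    t = np.zeros(table.n, dtype=float)
    cs = np.cumsum(D, axis=1)
    t[has] = cs[has, K[has] - 1] / K[has]
    fallback = ~has
    t[fallback] = t[has].min()
    return K, t, fallback


class KNNApplicabilityDomain(BaseEstimator):
    """Applicability-domain estimator with per-training-sample kNN thresholds.

    Parameters
    ----------
    k : int or "auto", default="auto"
        Smoothing parameter (number of nearest neighbours averaged when
        setting the distance scale).  ``"auto"`` uses the empirical
        round(n^(1/3)) rule; for a tuned value see
        :func:`qsarad.k_selection.optimize_k`.
    metric : str or MetricSpec, default="euclidean"
        One of ``euclidean``, ``manhattan``, ``mahalanobis`` (the latter with
        covariance estimated from the pretreated training data).
    scale : bool, default=True
        Autoscale descriptors using training statistics; queries are scaled
        with the same statistics.
    quantile_method : {"linear", "nearest_rank"}, default="linear"
        Quantile convention used for the Q1/Q3 in the reference value.

    Attributes
    ----------
    k_ : int
        The smoothing parameter actually used.
    avg_knn_dist_ : ndarray of shape (n,)
        Average distance of each training sample to its k nearest neighbours.
    ref_val_ : float
        Tukey upper fence of ``avg_knn_dist_``.
    K_ : ndarray of shape (n,)
        Neighbourhood density counts.
    thresholds_ : ndarray of shape (n,)
        Per-training-sample thresholds t_i.
    fallback_mask_ : ndarray of bool
        True where K_i = 0 and the minimum threshold was inherited.

    Examples
    --------
    >>> import numpy as np
    >>> ad = KNNApplicabilityDomain(k=2, scale=False).fit(np.array([[0.], [1.], [3.]]))
    >>> ad.predict(np.array([[2.0], [50.0]]))
    array([ True, False])
    """

    def __init__(self, k="auto", metric="euclidean", scale: bool = True,
                 quantile_method: str = "linear"):
        self.k = k
        self.metric = metric
        self.scale = scale
        self.quantile_method = quantile_method

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        """Fit thresholds on a training DescriptorTable or array."""
        ids = X.sample_ids if isinstance(X, DescriptorTable) else None
        Xm = _as_matrix(X)
        n = Xm.shape[0]
        if n < 3:
            raise ValueError("kNN AD fitting needs at least three training samples")
        self.n_features_in_ = Xm.shape[1]
        self.training_ids_ = list(ids) if ids is not None else None

        if self.scale:
            self.scaling_ = autoscale_fit(X if isinstance(X, DescriptorTable) else Xm)
            Xs = autoscale_apply(Xm, self.scaling_)
        else:
            self.scaling_ = None
            Xs = np.asarray(Xm, dtype=float)
        self.X_train_scaled_ = Xs

        if self.k == "auto":
            from .k_selection import default_k

            k = default_k(n)
        else:
            k = int(self.k)
        if not 1 <= k <= n - 1:
            raise ValueError(f"k must be in [1, {n - 1}], got {k}")
        self.k_ = k

        self.metric_spec_ = resolve_metric(self.metric, Xs)
        self.neighbour_table_ = build_neighbour_table(Xs, self.metric_spec_)
        self.avg_knn_dist_ = average_knn_distances(self.neighbour_table_, k)
        self.ref_val_ = reference_value(self.avg_knn_dist_, self.quantile_method)
        self.K_, self.thresholds_, self.fallback_mask_ = thresholds_from_refval(
            self.neighbour_table_, self.ref_val_
        )
        return self

    # -- prediction --------------------------------------------------------

    def _query_distances(self, X) -> np.ndarray:
        Xq = _as_matrix(X)
        if Xq.ndim == 1:
            Xq = Xq.reshape(1, -1)
        if self.scaling_ is not None:
            Xq = autoscale_apply(Xq, self.scaling_)
        elif Xq.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {Xq.shape[1]} descriptors, model expects {self.n_features_in_}"
            )
        return pairwise_distances(Xq, self.X_train_scaled_, self.metric_spec_)

    def reliability_counts(self, X) -> np.ndarray:
        """K_j per query: number of training thresholds the query satisfies."""
        D = self._query_distances(X)
        return (D <= self.thresholds_[None, :]).sum(axis=1).astype(int)

    def predict(self, X) -> np.ndarray:
        """Boolean in-domain flag per query (True = inside the AD)."""
        return self.reliability_counts(X) >= 1

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)

    def decisions(self, query) -> list[ADDecision]:
        """Full per-query verdicts, including the nearest satisfying distance."""
        ids = (
            query.sample_ids
            if isinstance(query, DescriptorTable)
            else [f"q{i}" for i in range(_as_matrix(query).reshape(-1, self.n_features_in_).shape[0])]
        )
        D = self._query_distances(query)
        sat = D <= self.thresholds_[None, :]
        out = []
        for j, sid in enumerate(ids):
            kj = int(sat[j].sum())
            nearest = float(D[j, sat[j]].min()) if kj else None
            out.append(ADDecision(sample_id=sid, in_ad=kj >= 1, K_j=kj,
                                  nearest_satisfying_distance=nearest))
        return out

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the fitted model to a JSON document (full double precision)."""
        if not hasattr(self, "thresholds_"):
            raise ValueError("model is not fitted")
        doc = {
            "format": "qsarad-knn-ad-model",
            "version": 1,
            "params": {
                "k": self.k_,
                "metric": self.metric_spec_.name,
                "scale": self.scale,
                "quantile_method": self.quantile_method,
            },
            "metric_inv_cov": None
            if self.metric_spec_.inv_cov is None
            else self.metric_spec_.inv_cov.tolist(),
            "scaling": None
            if self.scaling_ is None
            else {
                "means": self.scaling_.means.tolist(),
                "sds": self.scaling_.sds.tolist(),
            },
            "training_ids": self.training_ids_,
            "X_train_scaled": self.X_train_scaled_.tolist(),
            "avg_knn_dist": self.avg_knn_dist_.tolist(),
            "ref_val": self.ref_val_,
            "K": self.K_.tolist(),
            "thresholds": self.thresholds_.tolist(),
            "fallback_mask": self.fallback_mask_.astype(bool).tolist(),
        }
        text = json.dumps(doc, sort_keys=True, separators=(",", ":"))
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "KNNApplicabilityDomain":
        """Rebuild a fitted model from :meth:`to_json` output (text or path)."""
        text = source
        if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
            text = Path(source).read_text(encoding="utf-8")
        doc = json.loads(text)
        if doc.get("format") != "qsarad-knn-ad-model":
            raise ValueError("not a serialized kNN AD model")
        p = doc["params"]
        model = cls(k=p["k"], metric=p["metric"], scale=p["scale"],
                    quantile_method=p["quantile_method"])
        model.k_ = int(p["k"])
        inv_cov = doc["metric_inv_cov"]
        model.metric_spec_ = MetricSpec(
            p["metric"], None if inv_cov is None else np.asarray(inv_cov)
        )
        sc = doc["scaling"]
        model.scaling_ = (
            None if sc is None else ScalingParams(np.asarray(sc["means"]), np.asarray(sc["sds"]))
        )
        model.training_ids_ = doc["training_ids"]
        model.X_train_scaled_ = np.asarray(doc["X_train_scaled"], dtype=float)
        model.n_features_in_ = model.X_train_scaled_.shape[1]
        model.neighbour_table_ = build_neighbour_table(model.X_train_scaled_, model.metric_spec_)
        model.avg_knn_dist_ = np.asarray(doc["avg_knn_dist"], dtype=float)
        model.ref_val_ = float(doc["ref_val"])
        model.K_ = np.asarray(doc["K"], dtype=int)
        model.thresholds_ = np.asarray(doc["thresholds"], dtype=float)
        model.fallback_mask_ = np.asarray(doc["fallback_mask"], dtype=bool)
        return model


def fit_ad(train, k="auto", metric="euclidean", pretreat: bool = True,
           quantile_method: str = "linear") -> KNNApplicabilityDomain:
    """Fit the kNN applicability domain (thin wrapper over the estimator)."""
    return KNNApplicabilityDomain(
        k=k, metric=metric, scale=pretreat, quantile_method=quantile_method
    ).fit(train)


def apply_ad(model: KNNApplicabilityDomain, query) -> list[ADDecision]:
    """Evaluate the fitted domain on query samples (thin wrapper)."""
    return model.decisions(query)
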