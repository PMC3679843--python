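"""Probability-density-function applicability domains.

Five estimator families are provided on autoscaled descriptors: fixed-
bandwidth Gaussian kernel, leave-one-out-optimized Gaussian kernel, variable
Gaussian kernel (per-sample bandwidth scaled by the distance to the k-th
neighbour), adaptive Gaussian kernel (pilot-density local bandwidth factors
with sensitivity parameter α), a fixed-bandwidth Epanechnikov kernel, and
the nearest-neighbour density estimator k/(n·V_p·d_k(x)^p).

A density becomes an in/out rule through a percentile cutoff on the
leave-one-out training densities (default 5th percentile, mirroring the 95th
percentile convention of the distance-based methods); the cutoff convention
is a package choice exposed as a parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

from .io import DescriptorTable, ScalingParams, _as_matrix, autoscale_apply, autoscale_fit
from .distances import build_neighbour_table, pairwise_distances
from .knn_ad import _quantile

__all__ = [
    "DensityEstimator",
    "DensityADResult",
    "silverman_bandwidth",
    "fit_fixed_kde",
    "fit_variable_kde",
    "fit_adaptive_kde",
    "fit_nn_density",
    "kde_evaluate",
    "loo_densities",
    "loo_cv_bandwidth",
    "density_ad",
    "DensityApplicabilityDomain",
]

KINDS = ("gaussian_fixed", "gaussian_variable", "gaussian_adaptive",
         "epanechnikov_fixed", "nn_density")


@dataclass
class DensityEstimator:
    """A fitted density estimate over the scaled training data.

    ``h`` is the global bandwidth (scaled-descriptor units); ``local_factors``
    are per-training-sample multipliers λ_i (geometric mean 1 for the
    adaptive kind); ``k`` is the neighbour count for the variable and
    nearest-neighbour kinds; ``alpha`` the adaptive sensitivity.
    """

    kind: str
    X_train_scaled: np.ndarray
    h: float | None = None
    local_factors: np.ndarray | None = None
    alpha: float | None = None
    k: int | None = None
    scaling: ScalingParams | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown density kind {self.kind!r}")
        self.X_train_scaled = np.atleast_2d(np.asarray(self.X_train_scaled, dtype=float))
        if self.h is not None and self.h <= 0:
            raise ValueError("bandwidth h must be strictly positive")
        if self.local_factors is not None:
            self.local_factors = np.asarray(self.local_factors, dtype=float)
            if np.any(self.local_factors <= 0):
                raise ValueError("local bandwidth factors must be strictly positive")

    @property
    def n(self) -> int:
        return self.X_train_scaled.shape[0]

    @property
    def p(self) -> int:
        return self.X_train_scaled.shape[1]

    def bandwidths(self) -> np.ndarray:
        """Per-training-sample bandwidths h·λ_i (λ_i ≡ 1 when absent)."""
        if self.h is None:
            raise ValueError("estimator kind has no kernel bandwidth")
        lam = np.ones(self.n) if self.local_factors is None else self.local_factors
        return self.h * lam


@dataclass
class DensityADResult:
    """Density AD verdicts: in iff the query density reaches the cutoff."""

    in_ad: np.ndarray
    densities: np.ndarray
    cutoff: float


def silverman_bandwidth(n: int, p: int) -> float:
    """Rule-of-thumb Gaussian bandwidth (4/(p+2))^(1/(p+4)) · n^(−1/(p+4))
    for unit-variance (autoscaled) data."""
    return float((4.0 / (p + 2.0)) ** (1.0 / (p + 4.0)) * n ** (-1.0 / (p + 4.0)))


def unit_ball_volume(p: int) -> float:
    return float(math.exp(0.5 * p * math.log(math.pi) - gammaln(0.5 * p + 1.0)))


def _prepare(train, scale: bool):
    X = _as_matrix(train)
    if scale:
        params = autoscale_fit(train if isinstance(train, DescriptorTable) else X)
        return autoscale_apply(X, params), params
    return np.asarray(X, dtype=float), None


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_fixed_kde(train, h: float | None = None, kernel: str = "gaussian",
                  scale: bool = True) -> DensityEstimator:
    """Fixed-bandwidth kernel estimator (Gaussian or Epanechnikov).

    Without an explicit ``h``, the Silverman rule-of-thumb on the scaled data
    is used (multiplied by √5 for the Epanechnikov kernel to match the
    Gaussian's equivalent smoothing).
    """
    Xs, params = _prepare(train, scale)
    n, p = Xs.shape
    if h is None:
        h = silverman_bandwidth(n, p)
        if kernel == "epanechnikov":
            h *= math.sqrt(5.0)
    kind = {"gaussian": "gaussian_fixed", "epanechnikov": "epanechnikov_fixed"}.get(kernel)
    if kind is None:
        raise ValueError("kernel must be 'gaussian' or 'epanechnikov'")
    return DensityEstimator(kind=kind, X_train_scaled=Xs, h=float(h), scaling=params)


def fit_variable_kde(train, k: int = 15, h0: float | None = None, scale: bool = True,
                     bandwidth_mode: str = "proportional") -> DensityEstimator:
    """Variable Gaussian kernel: per-sample bandwidth from the Euclidean
    distance to the k-th neighbour.

    With the default ``proportional`` mode h_i = h0·d_{i,k}/g where g is the
    geometric mean of the d_{i,k} (so the geometric-mean bandwidth is h0);
    sparse regions get wide kernels.  ``inverse`` applies the literal inverse
    relation h_i = h0·g/d_{i,k}.  Zero k-th-neighbour distances (duplicate-
    heavy data) are floored at a small multiple of h0 with a warning.
    """
    Xs, params = _prepare(train, scale)
    n, p = Xs.shape
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    if h0 is None:
        h0 = silverman_bandwidth(n, p)
    table = build_neighbour_table(Xs, "euclidean")
    dk = table.D[:, k - 1].copy()
    zero = dk == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} training samples have zero distance to their "
            f"{k}-th neighbour; flooring their bandwidth", stacklevel=2,
        )
        floor = dk[~zero].min() * 1e-6 if (~zero).any() else 1e-12
        dk[zero] = floor
    g = math.exp(np.mean(np.log(dk)))
    if bandwidth_mode == "proportional":
        lam = dk / g
    elif bandwidth_mode == "inverse":
        lam = g / dk
    else:
        raise ValueError("bandwidth_mode must be 'proportional' or 'inverse'")
    return DensityEstimator(kind="gaussian_variable", X_train_scaled=Xs, h=float(h0),
                            local_factors=lam, k=k, scaling=params)


def fit_adaptive_kde(train, alpha: float = 0.5, h_pilot: float | None = None,
                     scale: bool = True) -> DensityEstimator:
    """Adaptive Gaussian kernel with a fixed-kernel pilot estimate.

    Pilot densities f̃(x_i) at the training points give local bandwidth
    factors λ_i = (f̃(x_i)/g)^(−α), g being their geometric mean, so the λ_i
    themselves have geometric mean 1; the kernel for sample i then uses
    bandwidth h_pilot·λ_i.  α = 0 recovers the fixed kernel; α = 0.5 is the
    conventional square-root sensitivity.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    pilot = fit_fixed_kde(train, h=h_pilot, kernel="gaussian", scale=scale)
    f_pilot = kde_evaluate(pilot, pilot.X_train_scaled, _already_scaled=True)
    if np.any(f_pilot <= 0):
        raise ValueError("pilot density vanished at a training point; increase the pilot bandwidth")
    log_f = np.log(f_pilot)
    lam = np.exp(-alpha * (log_f - log_f.mean()))
    return DensityEstimator(kind="gaussian_adaptive", X_train_scaled=pilot.X_train_scaled,
                            h=pilot.h, local_factors=lam, alpha=float(alpha),
                            scaling=pilot.scaling)


def fit_nn_density(train, k: int = 15, scale: bool = True) -> DensityEstimator:
    """Nearest-neighbour density estimator k/(n·V_p·d_k(x)^p)."""
    Xs, params = _prepare(train, scale)
    n = Xs.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    return DensityEstimator(kind="nn_density", X_train_scaled=Xs, k=k, scaling=params)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _scale_points(est: DensityEstimator, points, already_scaled: bool) -> np.ndarray:
    P = _as_matrix(points)
    if P.ndim == 1:
        P = P.reshape(1, -1)
    if not already_scaled and est.scaling is not None:
        P = autoscale_apply(P, est.scaling)
    if P.shape[1] != est.p:
        raise ValueError(f"query has {P.shape[1]} descriptors, estimator expects {est.p}")
    return P


def _gaussian_log_kernel_matrix(P: np.ndarray, X: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log K_{b_j}(p_i − x_j) for each evaluation point i and training sample j."""
    p = X.shape[1]
    sq = pairwise_distances(P, X, "euclidean") ** 2
    return -0.5 * sq / b[None, :] ** 2 - p * np.log(b)[None, :] - 0.5 * p * math.log(2 * math.pi)


def _epanechnikov_kernel_matrix(P: np.ndarray, X: np.ndarray, h: float) -> np.ndarray:
    """Product-form Epanechnikov kernel ∏_d (3/4h)(1 − (u_d/h)²)₊."""
    # (n_eval, n_train, p) is fine at the data sizes this package targets
    U = (P[:, None, :] - X[None, :, :]) / h
    inside = np.abs(U) <= 1.0
    vals = np.where(inside, 0.75 * (1.0 - U**2) / h, 0.0)
    return vals.prod(axis=2)


def kde_evaluate(est: DensityEstimator, points, _already_scaled: bool = False) -> np.ndarray:
    """Estimated density f̂ at each point (raw descriptor units in, the
    estimator applies its own scaling).

    For the nearest-neighbour kind, a point coincident with at least k
    training samples has d_k = 0 and is reported as +inf.
    """
    P = _scale_points(est, points, _already_scaled)
    X = est.X_train_scaled
    n = est.n
    if est.kind in ("gaussian_fixed", "gaussian_variable", "gaussian_adaptive"):
        logK = _gaussian_log_kernel_matrix(P, X, est.bandwidths())
        return np.exp(logsumexp(logK, axis=1)) / n
    if est.kind == "epanechnikov_fixed":
        return _epanechnikov_kernel_matrix(P, X, est.h).sum(axis=1) / n
    # nn_density
    D = pairwise_distances(P, X, "euclidean")
    D.sort(axis=1)
    dk = D[:, est.k - 1]
    with np.errstate(divide="ignore"):
        dens = est.k / (n * unit_ball_volume(est.p) * dk**est.p)
    dens[dk == 0] = np.inf
    return dens


def loo_densities(est: DensityEstimator) -> np.ndarray:
    """Leave-one-out density at each training point: the contribution of the
    point's own kernel (or of the point itself, for the nearest-neighbour
    kind) is excluded so its own mass cannot mask it."""
    X = est.X_train_scaled
    n = est.n
    if n < 2:
        raise ValueError("leave-one-out densities need at least two training samples")
    if est.kind in ("gaussian_fixed", "gaussian_variable", "gaussian_adaptive"):
        logK = _gaussian_log_kernel_matrix(X, X, est.bandwidths())
        np.fill_diagonal(logK, -np.inf)
        return np.exp(logsumexp(logK, axis=1)) / (n - 1)
    if est.kind == "epanechnikov_fixed":
        Kmat = _epanechnikov_kernel_matrix(X, X, est.h)
        np.fill_diagonal(Kmat, 0.0)
        return Kmat.sum(axis=1) / (n - 1)
    table = build_neighbour_table(X, "euclidean")
    dk = table.D[:, est.k - 1]
    with np.errstate(divide="ignore"):
        dens = est.k / ((n - 1) * unit_ball_volume(est.p) * dk**est.p)
    dens[dk == 0] = np.inf
    return dens


def loo_cv_bandwidth(train, h_grid, scale: bool = True) -> float:
    """Gaussian bandwidth maximizing the leave-one-out log-likelihood
    Σ_i log f̂_(−i)(x_i) over the candidate grid (ties go to the smaller h)."""
    Xs, _ = _prepare(train, scale)
    n, p = Xs.shape
    if n < 3:
        raise ValueError("leave-one-out bandwidth selection needs at least three samples")
    h_grid = sorted(float(h) for h in h_grid)
    if not h_grid or h_grid[0] <= 0:
        raise ValueError("h_grid must contain positive bandwidths")
    sq = pairwise_distances(Xs, Xs, "euclidean") ** 2
    np.fill_diagonal(sq, np.inf)  # excludes the own kernel from the logsumexp
    best_h, best_ll = None, -np.inf
    for h in h_grid:
        logK = -0.5 * sq / h**2 - p * math.log(h) - 0.5 * p * math.log(2 * math.pi)
        log_dens = logsumexp(logK, axis=1) - math.log(n - 1)
        if np.exp(log_dens).min() == 0.0:
            continue  # an LOO density underflows to zero: likelihood -inf, h too small
        ll = float(log_dens.sum())
        if ll > best_ll:
            best_h, best_ll = h, ll
    if best_h is None:
        raise ValueError(
            "all leave-one-out likelihoods are -inf; every candidate bandwidth is "
            "too small for the data spacing — extend h_grid upwards"
        )
    return best_h


def density_ad(est: DensityEstimator, train, query,
               cutoff_percentile: float = 5.0,
               quantile_method: str = "linear") -> DensityADResult:
    """Turn a fitted density estimate into an AD rule.

    The cutoff is the given percentile of the leave-one-out training
    densities; a query is inside iff its estimated density reaches it.
    """
    if not 0 <= cutoff_percentile <= 100:
        raise ValueError("cutoff_percentile must be in [0, 100]")
    train_dens = loo_densities(est)
    finite = train_dens[np.isfinite(train_dens)]
    if finite.size == 0:
        raise ValueError("all leave-one-out training densities are infinite")
    cutoff = float(_quantile(finite, cutoff_percentile / 100.0, quantile_method))
    dens = kde_evaluate(est, query)
    return DensityADResult(in_ad=dens >= cutoff, densities=dens, cutoff=cutoff)


class DensityApplicabilityDomain(BaseEstimator):
    """scikit-learn wrapper uniting the density kinds behind fit/predict.

    Parameters mirror the functional layer: ``kind`` picks the estimator
    family, ``h`` is a bandwidth, ``"loo"`` (Gaussian fixed kind only)
    selects it by leave-one-out likelihood over ``h_grid``, ``None`` uses the
    Silverman rule; ``k``, ``alpha`` and ``cutoff_percentile`` as documented
    in the fitting functions.
    """

    def __init__(self, kind: str = "gaussian_fixed", h=None, h_grid=None,
                 k: int = 15, alpha: float = 0.5, cutoff_percentile: float = 5.0,
                 scale: bool = True, bandwidth_mode: str = "proportional"):
        self.kind = kind
        self.h = h
        self.h_grid = h_grid
        self.k = k
        self.alpha = alpha
        self.cutoff_percentile = cutoff_percentile
        self.scale = scale
        self.bandwidth_mode = bandwidth_mode

    def fit(self, X, y=None):
        h = self.h
        if h == "loo":
            grid = self.h_grid if self.h_grid is not None else np.geomspace(0.05, 2.0, 40)
            h = loo_cv_bandwidth(X, grid, scale=self.scale)
        if self.kind == "gaussian_fixed":
            est = fit_fixed_kde(X, h=h, kernel="gaussian", scale=self.scale)
        elif self.kind == "epanechnikov_fixed":
            est = fit_fixed_kde(X, h=h, kernel="epanechnikov", scale=self.scale)
        elif self.kind == "gaussian_variable":
            est = fit_variable_kde(X, k=self.k, h0=h, scale=self.scale,
                                   bandwidth_mode=self.bandwidth_mode)
        elif self.kind == "gaussian_adaptive":
            est = fit_adaptive_kde(X, alpha=self.alpha, h_pilot=h, scale=self.scale)
        elif self.kind == "nn_density":
            est = fit_nn_density(X, k=self.k, scale=self.scale)
        else:
            raise ValueError(f"unknown density kind {self.kind!r}")
        self.estimator_ = est
        self.n_features_in_ = est.p
        train_dens = loo_densities(est)
        finite = train_dens[np.isfinite(train_dens)]
        if finite.size == 0:
            raise ValueError("all leave-one-out training densities are infinite")
        self.cutoff_ = float(_quantile(finite, self.cutoff_percentile / 100.0))
        return self

    def score_samples(self, X) -> np.ndarray:
        return kde_evaluate(self.estimator_, X)

    def predict(self, X) -> np.ndarray:
        return self.score_samples(X) >= self.cutoff_
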