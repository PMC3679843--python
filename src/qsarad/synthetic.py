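"""Synthetic datasets with the structure every AD method is exercised on.

Two generators are provided.  ``simulate_cluster_with_outliers`` emulates a
dense isotropic cluster plus a few far-detached extreme points — the
geometry under which per-sample thresholds show their characteristic
behaviour (outliers retain K_i = 0 and inherit the minimum threshold).
``simulate_qsar_dataset`` produces generic regression-style data: Gaussian
descriptors, a linear response with additive noise, idealized linear
predictions, and a fraction of test samples displaced off the training
support so genuine out-of-domain cases exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import DescriptorTable

__all__ = [
    "SimulationSpec",
    "simulate_cluster_with_outliers",
    "simulate_qsar_dataset",
]


@dataclass
class SimulationSpec:
    """Cluster-plus-outliers geometry.

    ``outlier_offset`` is the distance of each outlier from the cluster
    centroid in multiples of ``cluster_spread``; at 10 and above the outliers
    are guaranteed to exceed any plausible neighbourhood reference value of
    the cluster (verified after generation).
    """

    n_cluster: int = 48
    n_outliers: int = 2
    p: int = 2
    cluster_spread: float = 1.0
    outlier_offset: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cluster < 10:
            raise ValueError("n_cluster must be at least 10")
        if self.n_outliers < 0 or self.p < 1:
            raise ValueError("invalid simulation spec")
        if self.n_outliers > 0 and self.outlier_offset < 10:
            raise ValueError("outlier_offset must be >= 10 to guarantee detached outliers")
        if self.cluster_spread <= 0:
            raise ValueError("cluster_spread must be positive")


def _distinct_directions(m: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """m unit vectors in R^p, pairwise distinct (orthonormal when m <= p)."""
    if m <= p:
        G = rng.standard_normal((p, p))
        Q, _ = np.linalg.qr(G)
        return Q[:, :m].T
    dirs = rng.standard_normal((m, p))
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def simulate_cluster_with_outliers(spec: SimulationSpec) -> DescriptorTable:
    """Dense cluster with detached extreme points; outliers take the last ids."""
    rng = np.random.default_rng(spec.seed)
    centroid = np.zeros(spec.p)
    cluster = centroid + spec.cluster_spread * rng.standard_normal((spec.n_cluster, spec.p))
    rows = [cluster]
    if spec.n_outliers:
        dirs = _distinct_directions(spec.n_outliers, spec.p, rng)
        outliers = centroid + spec.outlier_offset * spec.cluster_spread * dirs
        rows.append(outliers)
    X = np.vstack(rows)
    if spec.n_outliers:
        d = np.linalg.norm(X[spec.n_cluster:] - centroid, axis=1)
        assert np.all(d >= spec.outlier_offset * spec.cluster_spread - 1e-9)
    n = X.shape[0]
    width = len(str(n))
    ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    names = [f"d{j + 1}" for j in range(spec.p)]
    return DescriptorTable(ids, X, names)


def simulate_qsar_dataset(
    n_train: int = 378,
    n_test: int = 95,
    p: int = 5,
    noise_sd: float = 1.0,
    test_shift: float = 6.0,
    displaced_fraction: float = 0.05,
    curvature: float = 0.05,
    seed: int = 0,
) -> tuple[DescriptorTable, DescriptorTable]:
    """Regression-style train/test tables for exercising Q² and SE reporting.

    Descriptors are standard normal.  The measured response is a fixed linear
    combination of the descriptors plus Gaussian noise, with an optional mild
    quadratic term (``curvature``·(‖x‖² − p)) representing the model misfit
    every real model accumulates away from its training support: it is
    negligible inside the support but grows quadratically outside, so
    displaced samples are genuinely mispredicted, not just far away.  The
    predictions ``y_hat`` are the idealized linear model.  The last
    ``ceil(displaced_fraction·n_test)`` test samples are translated by
    ``test_shift`` along random unit directions to create out-of-domain
    cases.  Set ``curvature=0`` for a perfectly specified model whose test
    error is exactly the injected noise.
    """
    if n_train < 3 or n_test < 1 or p < 1:
        raise ValueError("invalid dataset sizes")
    if noise_sd < 0 or test_shift < 0 or not 0 <= displaced_fraction <= 1:
        raise ValueError("invalid generator parameters")
    rng = np.random.default_rng(seed)
    beta = np.linspace(0.5, 1.5, p)

    def _make(n: int, prefix: str, X: np.ndarray) -> DescriptorTable:
        linear = X @ beta
        y = linear + curvature * ((X**2).sum(axis=1) - p) + noise_sd * rng.standard_normal(n)
        width = len(str(n))
        ids = [f"{prefix}{i + 1:0{width}d}" for i in range(n)]
        names = [f"d{j + 1}" for j in range(p)]
        return DescriptorTable(ids, X, names, y=y, y_hat=linear)

    X_train = rng.standard_normal((n_train, p))
    X_test = rng.standard_normal((n_test, p))
    n_disp = math.ceil(displaced_fraction * n_test)
    if n_disp and test_shift > 0:
        dirs = _distinct_directions(n_disp, p, rng)
        X_test[n_test - n_disp:] += test_shift * dirs
    train = _make(n_train, "TR", X_train)
    test = _make(n_test, "TS", X_test)
    return train, test
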