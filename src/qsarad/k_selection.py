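"""Monte Carlo selection of the smoothing parameter k.

The training set is repeatedly split at random (by default 20% held out,
1000 iterations); for each candidate k an applicability domain is fitted on
the inner-training part and the percentage of held-out samples retained
inside it is recorded.  The same split is reused across all k (paired
comparison), so per-iteration retention is non-decreasing in k by the
monotonicity of the threshold construction.  Box-plot summaries and the mean
retention curve support choosing the smallest k on the plateau; when
optimization is not worth the cost, the empirical round(n^(1/3)) rule gives
a reasonable fixed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DescriptorTable, _as_matrix, autoscale_apply, autoscale_fit
from .distances import build_neighbour_table, pairwise_distances, resolve_metric
from .knn_ad import _quantile, reference_value, thresholds_from_refval

__all__ = [
    "BoxSummary",
    "KOptimizationResult",
    "boxplot_summary",
    "optimize_k",
    "default_k",
    "suggest_k",
]


@dataclass
class BoxSummary:
    """Five-number box-plot summary with whisker factor w and fence outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]
    w: float = 1.5


def boxplot_summary(values, w: float = 1.5, quantile_method: str = "linear") -> BoxSummary:
    """Box-plot summary of a vector: quartiles, whiskers clipped to the data
    inside the Tukey fences Q1 − w·IQR and Q3 + w·IQR, and the outliers beyond."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty vector")
    q1, med, q3 = _quantile(v, [0.25, 0.5, 0.75], quantile_method)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - w * iqr, q3 + w * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    # fences always bracket the quartiles, so `inside` is never empty
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]),
        w=w,
    )


@dataclass
class KOptimizationResult:
    """Retention distributions per candidate k over Monte Carlo splits."""

    k_grid: list[int]
    retained_pct: np.ndarray  # shape (len(k_grid), iterations), values in [0, 100]
    summaries: list[BoxSummary]
    mean_curve: np.ndarray
    seed: int
    iterations: int
    test_fraction: float

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (k, iteration, retained_pct) table."""
        k = np.repeat(self.k_grid, self.iterations)
        it = np.tile(np.arange(self.iterations), len(self.k_grid))
        return pd.DataFrame(
            {"k": k, "iteration": it, "retained_pct": self.retained_pct.ravel()}
        )

    def summary_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, s, m in zip(self.k_grid, self.summaries, self.mean_curve):
            rows.append(
                {
                    "k": k, "median": s.median, "q1": s.q1, "q3": s.q3,
                    "whisker_low": s.whisker_low, "whisker_high": s.whisker_high,
                    "n_outliers": len(s.outliers), "mean": m,
                }
            )
        return pd.DataFrame(rows)


def default_k(n: int) -> int:
    """Empirical fixed smoothing parameter round(n^(1/3)), clipped to [1, n−1]."""
    if n < 3:
        raise ValueError("need at least three training samples")
    return int(np.clip(int(np.rint(n ** (1.0 / 3.0))), 1, n - 1))


def optimize_k(
    train,
    k_grid=None,
    test_fraction: float = 0.2,
    iterations: int = 1000,
    seed: int = 0,
    metric="euclidean",
    scale: bool = True,
    quantile_method: str = "linear",
) -> KOptimizationResult:
    """Monte Carlo k-optimization on the training set.

    Each iteration draws one uniform split without replacement; all candidate
    k values are evaluated on that same split.  Splits are drawn over a
    canonical id-sorted ordering of the samples, so the reported percentages
    do not depend on the row order of the input for a given seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if iterations < 1:
        raise ValueError("iterations must be positive")
    ids = (
        train.sample_ids
        if isinstance(train, DescriptorTable)
        else [str(i) for i in range(_as_matrix(train).shape[0])]
    )
    X = _as_matrix(train)
    n = X.shape[0]
    canonical = np.argsort(np.asarray(ids, dtype=object))
    Xc = X[canonical]

    n_inner = math.ceil((1 - test_fraction) * n)
    n_test = n - n_inner
    if n_test < 1 or n_inner < 3:
        raise ValueError("training set too small for the requested test fraction")
    if k_grid is None:
        k_grid = list(range(1, min(25, n_inner - 1) + 1))
    k_grid = sorted(int(k) for k in k_grid)
    if k_grid[0] < 1 or k_grid[-1] > n_inner - 1:
        raise ValueError(
            f"k_grid must lie within [1, {n_inner - 1}] for inner-training size {n_inner}"
        )

    rng = np.random.default_rng(seed)
    ret = np.empty((len(k_grid), iterations), dtype=float)
    for it in range(iterations):
        perm = rng.permutation(n)
        tr, te = perm[:n_inner], perm[n_inner:]
        Xtr, Xte = Xc[tr], Xc[te]
        if scale:
            params = autoscale_fit(Xtr)
            Xtr_s = autoscale_apply(Xtr, params)
            Xte_s = autoscale_apply(Xte, params)
        else:
            Xtr_s, Xte_s = Xtr, Xte
        spec = resolve_metric(metric, Xtr_s)
        table = build_neighbour_table(Xtr_s, spec)
        Dq = pairwise_distances(Xte_s, Xtr_s, spec)
        # average kNN distances for every k at once via cumulative means
        cummean = np.cumsum(table.D, axis=1) / np.arange(1, n_inner)
        for ki, k in enumerate(k_grid):
            rv = reference_value(cummean[:, k - 1], quantile_method)
            _, t, _ = thresholds_from_refval(table, rv)
            in_ad = (Dq <= t[None, :]).any(axis=1)
            ret[ki, it] = 100.0 * in_ad.mean()

    summaries = [boxplot_summary(ret[ki], quantile_method=quantile_method)
                 for ki in range(len(k_grid))]
    return KOptimizationResult(
        k_grid=list(k_grid),
        retained_pct=ret,
        summaries=summaries,
        mean_curve=ret.mean(axis=1),
        seed=int(seed),
        iterations=int(iterations),
        test_fraction=float(test_fraction),
    )


def suggest_k(result: KOptimizationResult, tolerance_pct: float = 2.0) -> int:
    """Plateau rule formalizing the by-eye choice of k.

    Returns the smallest k whose mean retention is within ``tolerance_pct``
    of the grid maximum and whose box summary flags no outliers; if no k
    satisfies both, the smallest k within tolerance of the maximum.
    """
    if not result.k_grid:
        raise ValueError("empty optimization result")
    target = result.mean_curve.max() - tolerance_pct
    within = [i for i, m in enumerate(result.mean_curve) if m >= target]
    for i in within:
        if not result.summaries[i].outliers:
            return result.k_grid[i]
    return result.k_grid[within[0]]


def plot_k_optimization(result: KOptimizationResult, path=None):
    """Box-and-whisker plot of retained percentages per k with the mean curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.boxplot(
        [result.retained_pct[i] for i in range(len(result.k_grid))],
        positions=result.k_grid,
        whis=result.summaries[0].w if result.summaries else 1.5,
        flierprops={"marker": "+", "markeredgecolor": "red"},
        medianprops={"color": "red"},
    )
    ax.plot(result.k_grid, result.mean_curve, "-o", color="tab:blue", ms=3, label="mean")
    ax.set_xlabel("k")
    ax.set_ylabel("test samples retained in AD (%)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
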