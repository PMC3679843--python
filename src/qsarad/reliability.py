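"""Reliability reporting for predictions filtered through an AD.

Once queries have been classified in or out of the applicability domain, the
report combines: the retained count, the predictive squared correlation
coefficient Q² computed on the retained samples only (samples outside the
domain are unreliably predicted and excluded from the statistic), each
sample's absolute standardized error SE_j = |y_j − ŷ_j| / s_Y with s_Y the
training standard error of estimate, its reliability count K_j, and the list
of samples whose SE exceeds the warning level (2 standardized units by
convention, 3 for a stricter rule) — response-domain outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DescriptorTable
from .knn_ad import ADDecision

__all__ = [
    "ReliabilityReport",
    "q_squared",
    "standardized_errors",
    "training_standard_error",
    "build_report",
]


def q_squared(y_test, yhat_test, y_train) -> float:
    """Predictive squared correlation coefficient.

    Q² = 1 − [Σ_j (ŷ_j − y_j)² / n_TS] / [Σ_i (y_i − ȳ_TR)² / n_TR], the
    test mean squared error relative to the training response variance about
    the training mean — each sum normalized by its own sample count.
    """
    y_test = np.asarray(y_test, dtype=float)
    yhat_test = np.asarray(yhat_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if y_test.shape != yhat_test.shape or y_test.ndim != 1 or y_test.size < 1:
        raise ValueError("y_test and yhat_test must be equal-length vectors of length >= 1")
    denom = np.mean((y_train - y_train.mean()) ** 2)
    if denom == 0:
        raise ValueError("training responses have zero variance; Q^2 is undefined")
    return float(1.0 - np.mean((yhat_test - y_test) ** 2) / denom)


def standardized_errors(y, yhat, s_Y: float) -> np.ndarray:
    """Absolute standardized errors SE_j = |y_j − ŷ_j| / s_Y."""
    if not s_Y > 0:
        raise ValueError("s_Y must be strictly positive")
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    return np.abs(y - yhat) / s_Y


def training_standard_error(y_train, yhat_train) -> float:
    """Standard error of estimate from the training set, as the root mean
    squared residual √(Σ(y_i − ŷ_i)²/n_TR)."""
    y = np.asarray(y_train, dtype=float)
    yh = np.asarray(yhat_train, dtype=float)
    if y.shape != yh.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("training responses and predictions must be equal-length, n >= 2")
    return float(np.sqrt(np.mean((y - yh) ** 2)))


@dataclass
class ReliabilityReport:
    """Per-sample and summary reliability information for a scored query set."""

    n_retained: int
    q2_retained: float  # NaN when no sample is retained
    excluded_ids: list[str]
    per_sample: pd.DataFrame  # sample_id, in_ad, K_j, SE, y, y_hat
    s_Y: float
    se_warning_ids: list[str]
    se_warning_threshold: float = 2.0

    def summary_line(self, method: str = "kNN AD") -> str:
        q2 = "undefined" if np.isnan(self.q2_retained) else f"{self.q2_retained:.3f}"
        excluded = " ".join(self.excluded_ids) if self.excluded_ids else "None"
        return f"{method}\tIN AD: {self.n_retained}\tQ2: {q2}\tOUTSIDE AD: {excluded}"


def build_report(
    decisions: list[ADDecision],
    query: DescriptorTable,
    y_train,
    yhat_train=None,
    s_Y_override: float | None = None,
    se_warning_threshold: float = 2.0,
) -> ReliabilityReport:
    """Assemble the reliability report for scored query samples.

    Q² uses retained (in-AD) samples only; SE_j and K_j are reported for
    every scored sample.  ``s_Y`` comes from the training residuals unless an
    external value is supplied (for instance the published RMSE of the model
    under study).  An empty retained set yields Q² = NaN, not an error, so
    batch comparisons never abort.
    """
    if query.y is None or query.y_hat is None:
        raise ValueError("reliability reporting needs measured and predicted query responses")
    if len(decisions) != query.n:
        raise ValueError("one decision per query sample is required")
    if s_Y_override is not None:
        s_Y = float(s_Y_override)
        if s_Y <= 0:
            raise ValueError("s_Y_override must be strictly positive")
    else:
        if yhat_train is None:
            raise ValueError("either training predictions or an s_Y override is required")
        s_Y = training_standard_error(y_train, yhat_train)
        if s_Y == 0:
            raise ValueError(
                "training residuals are all zero (s_Y = 0); standardized errors are undefined"
            )

    se = standardized_errors(query.y, query.y_hat, s_Y)
    in_ad = np.array([d.in_ad for d in decisions], dtype=bool)
    kj = np.array([d.K_j for d in decisions], dtype=int)
    per_sample = pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in decisions],
            "in_ad": in_ad,
            "K_j": kj,
            "SE": se,
            "y": query.y,
            "y_hat": query.y_hat,
        }
    )
    retained = int(in_ad.sum())
    q2 = (
        q_squared(query.y[in_ad], query.y_hat[in_ad], y_train)
        if retained
        else float("nan")
    )
    warn = [d.sample_id for d, s in zip(decisions, se) if s > se_warning_threshold]
    return ReliabilityReport(
        n_retained=retained,
        q2_retained=q2,
        excluded_ids=[d.sample_id for d in decisions if not d.in_ad],
        per_sample=per_sample,
        s_Y=s_Y,
        se_warning_ids=warn,
        se_warning_threshold=se_warning_threshold,
    )
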