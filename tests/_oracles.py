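"""Independent naive reimplementations used as test oracles.

Everything here is written with explicit loops and no sorting shortcuts, on
purpose: these functions must stay independent of the code paths they check.
"""

import numpy as np


def naive_distance(a, b, metric="euclidean", inv_cov=None):
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if metric == "euclidean":
        return float(np.sqrt(np.sum(d * d)))
    if metric == "manhattan":
        return float(np.sum(np.abs(d)))
    return float(np.sqrt(d @ inv_cov @ d))


def naive_distance_matrix(A, B, metric="euclidean", inv_cov=None):
    A, B = np.atleast_2d(A), np.atleast_2d(B)
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            out[i, j] = naive_distance(A[i], B[j], metric, inv_cov)
    return out


def naive_autoscale(X_train, X):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=1)
    return (X - mu) / sd


def naive_thresholds(X_train, k, metric="euclidean", inv_cov=None, scale=True):
    """Full threshold construction: returns (ref_val, K, t) by brute force."""
    X = naive_autoscale(X_train, X_train) if scale else np.asarray(X_train, float)
    n = X.shape[0]
    full = naive_distance_matrix(X, X, metric, inv_cov)
    rows = []
    for i in range(n):
        others = sorted(full[i, j] for j in range(n) if j != i)
        rows.append(others)
    avg = np.array([np.mean(r[:k]) for r in rows])
    q1, q3 = np.quantile(avg, [0.25, 0.75])
    ref_val = q3 + 1.5 * (q3 - q1)
    K = np.zeros(n, dtype=int)
    t = np.zeros(n)
    for i in range(n):
        kept = [d for d in rows[i] if d <= ref_val]
        K[i] = len(kept)
        t[i] = np.mean(kept) if kept else np.nan
    if np.all(np.isnan(t)):
        raise ValueError("no thresholds")
    fallback = np.nanmin(t)
    t = np.where(np.isnan(t), fallback, t)
    return ref_val, K, t


def naive_decide(X_train, X_query, k, metric="euclidean", inv_cov=None, scale=True):
    """Per-query (in_ad, K_j) by brute force."""
    _, _, t = naive_thresholds(X_train, k, metric, inv_cov, scale)
    Xtr = naive_autoscale(X_train, X_train) if scale else np.asarray(X_train, float)
    Xq = naive_autoscale(X_train, X_query) if scale else np.asarray(X_query, float)
    D = naive_distance_matrix(Xq, Xtr, metric, inv_cov)
    K_j = np.array([sum(D[j, i] <= t[i] for i in range(Xtr.shape[0]))
                    for j in range(Xq.shape[0])], dtype=int)
    return K_j >= 1, K_j
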