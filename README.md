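# qsarad

Applicability-domain (AD) estimation for QSAR models.

A QSAR model maps molecular descriptors **x** to a property y, but its
predictions are only trustworthy for molecules that resemble its training
set. The applicability domain is the region of descriptor space where that
holds; regulatory use of QSAR predictions (e.g. under REACH) requires it to
be defined explicitly. `qsarad` implements a kNN-based AD in which **every
training sample carries its own distance threshold**, together with the
classical and density-based AD methods usually used for comparison, Monte
Carlo selection of the smoothing parameter, and reliability reporting.

## The method

Given n pretreated (autoscaled) training samples and a neighbour count k:

1. Sort each sample's distances to the other n−1 samples into the
   neighbour table D (D_i1 ≤ … ≤ D_i,n−1) and average the first k:
   d̄_i(k) = (1/k) Σ_{j≤k} D_ij.
2. Set a single reference value as the Tukey upper fence of those averages:
   d̃(k) = Q3 + 1.5·(Q3 − Q1).
3. For each sample keep the neighbour distances ≤ d̃(k). Their count K_i
   measures local density; their mean t_i is the sample's individual
   threshold. A sample retaining none (K_i = 0, an outlier) inherits the
   smallest threshold of the training set, so it contributes to the domain
   only in its immediate vicinity.

A query j is **inside the AD** iff D_ij ≤ t_i for at least one training
sample i; the count K_j of such samples grades the reliability of its
prediction. Reporting combines the retained count, the predictive squared
correlation coefficient on retained samples,

    Q² = 1 − [Σ_j (ŷ_j − y_j)² / n_TS] / [Σ_i (y_i − ȳ_TR)² / n_TR],

and each sample's absolute standardized error SE_j = |y_j − ŷ_j| / s_Y
(values above 2 flag response-space outliers).

Comparison methods included: bounding box, PCA bounding box, convex hull
(linear-programming membership), Euclidean/Mahalanobis distance to centroid
at a percentile threshold, classical kNN with a single general threshold,
and density-based ADs (fixed / LOO-optimized / variable / adaptive Gaussian
kernels, Epanechnikov kernel, nearest-neighbour density estimator).

## Worked example

```python
import numpy as np
from qsarad import (SimulationSpec, simulate_cluster_with_outliers, fit_ad,
                    apply_ad, optimize_k, suggest_k, simulate_qsar_dataset,
                    build_report)

# 48 clustered samples plus 2 extreme outliers in 2-D
table = simulate_cluster_with_outliers(SimulationSpec(seed=7))
opt = optimize_k(table, k_grid=range(1, 26), iterations=200, seed=0)
print(f"suggested k = {suggest_k(opt)}")

model = fit_ad(table, k=12)
print(f"Ref Val = {model.ref_val_:.3f}")
print(f"samples with K_i = 0: {np.flatnonzero(model.fallback_mask_) + 1}")
print(f"their fallback threshold = {model.thresholds_[model.fallback_mask_][0]:.3f}")

# regression-style train/test tables with a few off-support test samples
train, test = simulate_qsar_dataset(seed=1)
ad = fit_ad(train, k=15)
report = build_report(apply_ad(ad, test), test, y_train=train.y,
                      yhat_train=train.y_hat)
print(report.summary_line("kNN AD (k=15)"))
```

prints

```
suggested k = 7
Ref Val = 0.714
samples with K_i = 0: [49 50]
their fallback threshold = 0.362
kNN AD (k=15)	IN AD: 89	Q2: 0.870	OUTSIDE AD: TS68 TS91 TS92 TS93 TS94 TS95
```

The two detached samples (49 and 50) retain no neighbour within the
reference value, so they fall back to the smallest cluster threshold
(0.362): a query must essentially coincide with them to be retained, and
then only with K_j = 1. On the regression data the six excluded test
samples are the displaced, off-support ones; Q² over the 89 retained
samples (0.870) is higher than over all 95 (0.855 here), because the
excluded samples are exactly the badly extrapolated ones.

The same workflow is available from the shell:

```
qsarad simulate --kind qsar --outdir data
qsarad fit data/train.csv --k 15 --outdir fit
qsarad apply fit/model.json data/test.csv --outdir decisions
qsarad optimize-k data/train.csv --iterations 1000 --outdir kopt
qsarad compare data/train.csv data/test.csv --response-column y \
    --prediction-column y_hat --outdir cmp
```

`compare` emits one row per AD method (name, retained count, Q² over
retained samples, excluded ids) plus a no-AD baseline row.

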