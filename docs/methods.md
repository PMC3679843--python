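# Methods

## Model and assumptions

`qsarad` defines a QSAR model's applicability domain purely in descriptor
space: a query is reliably predicted when it is close, in the chosen
metric, to at least one training sample — "close" meaning within that
sample's individual threshold. The construction assumes the descriptor
matrix is complete and numeric, that training statistics (means, standard
deviations, covariance for Mahalanobis) characterize the reference space,
and that distance in pretreated descriptor space is a meaningful proxy for
structural similarity. Nothing is assumed about the predictive model
itself; predictions enter only through the reliability report.

Per-sample thresholds make the domain adapt to local density: in dense
regions thresholds reflect short neighbour distances, in sparse regions
they widen, and genuinely detached samples (no neighbour within the
reference value, K_i = 0) are demoted to the minimum threshold so they
define the domain only in their immediate vicinity. Because the rule is a
finite set of distance comparisons, it remains usable in the
moderate-to-high dimensionality where grid- or volume-based density
arguments break down.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `k` (smoothing) | neighbours | `"auto"` = round(n^(1/3)) | controls locality; low k = strict, noisy domain; the cube-root rule is an empirical compromise when Monte Carlo tuning is not worth the cost |
| `metric` | — | euclidean | manhattan and mahalanobis (training covariance, n−1 denominator) available; singular covariance is an error, not a pseudo-inverse |
| `scale` / pretreatment | — | on | autoscaling with training means/sds (n−1); queries always scaled with training statistics — the only leak-free choice |
| `quantile_method` | — | linear | Q1/Q3 convention behind the Tukey fence; every downstream number depends on it, so it is pinned (with a nearest-rank alternative) |
| k-optimization | — | 20 % held out, 1000 iterations | Monte Carlo validation maximizing held-out retention; one split per iteration shared across all k (paired, lower variance) |
| `suggest_k` tolerance | % | 2 | plateau rule: smallest k within tolerance of the maximum mean retention and without box-plot outliers — a formalization of the usual by-eye choice |
| classical kNN | — | k = 5, 95th percentile | the conventional single-threshold comparator |
| centroid distance | — | 95th percentile | inclusive threshold on training-to-centroid distances |
| density cutoff | percentile | 5 | leave-one-out training densities define the cutoff; mirrors the 95th-percentile convention of the distance methods. The literature gives no canonical density-to-AD rule, so this is an explicit package convention |
| adaptive KDE `alpha` | — | 0.5 | conventional square-root sensitivity; pilot is the fixed Gaussian kernel, local factors normalized to geometric mean 1 |
| variable KDE | — | h_i ∝ d_{i,k}, k = 15 | per-sample bandwidth proportional to the k-th-neighbour distance (sparse regions smooth more). The literal inverse relation (`bandwidth_mode="inverse"`) is provided but contradicts the estimator's purpose |
| SE warning | standardized units | 2 | conventional response-outlier flag; 3 available for a stricter rule |

Bandwidth defaults are a Silverman-type rule of thumb on autoscaled data,
(4/(p+2))^(1/(p+4)) n^(−1/(p+4)); leave-one-out likelihood selection over a
grid is available where a tuned bandwidth is wanted. Published bandwidths
for specific datasets are inputs, not defaults.

## Numerical choices

- Distance ties in the neighbour table break by ascending training index
  (stable argsort), making tables and everything downstream deterministic.
- The pairwise distance matrix is symmetrized (averaged with its
  transpose) before sorting so row/column roles cannot disagree at the
  last ulp.
- All threshold and range comparisons are inclusive (≤).
- The K_i = 0 fallback uses the minimum over non-fallback thresholds only
  (order-independent); if every sample has K_i = 0 no domain exists and an
  error is raised rather than an all-zero AD.
- K_j scans all n training samples (no early exit) so the nearest
  satisfying distance is exact.
- Convex-hull membership is decided by linear feasibility (HiGHS) with a
  residual tolerance of 1e-9 — robust in the ~5-dimensional descriptor
  spaces where facet enumeration is fragile. PCA-box components are
  retained by cumulative explained variance (default 95 %).
- Zero-variance descriptors are a hard error at scaling time unless
  explicitly dropped; silently dropping would change the model space.
- Gaussian KDE computations run in log space (logsumexp); a candidate LOO
  bandwidth whose leave-one-out density underflows to zero at any training
  point is treated as likelihood −∞.
- Monte Carlo splits are drawn over a canonical id-sorted ordering, so
  results for a given seed do not depend on input row order.

## Monotonicity in k — what is and is not guaranteed

The average neighbour distances d̄_i(k) are non-decreasing in k by
construction, and **whenever** the reference value grows from k to k+1, so
do every K_i, every t_i and the membership of any fixed query set. But the
reference value itself, 2.5·Q3 − 1.5·Q1 of the d̄ vector, is not a
monotone functional of elementwise-nondecreasing inputs: when the first
quartile rises faster than the third (spread shrinking with k), it can
decrease — empirically it does on most generic Gaussian clouds. On
compact cluster-plus-outliers geometries the whole chain is monotone over
the practical k range, which is why retention curves there rise and
plateau. The domain should therefore be described as *tending* to expand
with k, not as nested.

## Synthetic data: what it emulates, what it does not

`simulate_cluster_with_outliers` draws an isotropic Gaussian cluster plus
detached points at ≥ `outlier_offset`·spread (default 15) in distinct
directions — the geometry in which per-sample thresholds differ most
visibly from a single global threshold. Real descriptor clouds are
anisotropic, multi-modal and correlated; passing tests on this fixture
demonstrates the mechanism (outlier demotion, vicinity behaviour,
retention plateaus), not performance on any particular chemical dataset.

`simulate_qsar_dataset` (defaults: 378 training / 95 test samples, 5
descriptors) uses standard-normal descriptors, a fixed linear response
with Gaussian noise (sd 1.0), and idealized linear predictions; 5 % of
test samples are displaced by 6 units along random directions to create
genuine out-of-domain cases. The measured response additionally carries a
small quadratic term, `curvature`·(‖x‖² − p) with curvature 0.05, absent
from the predictions. This term is the deliberate mechanism linking
geometry to error: it is negligible on the training support (so on-support
Q² is governed by the noise) but grows quadratically off-support, exactly
as real models degrade when extrapolating. Without some geometry-dependent
misfit, a homoscedastic perfectly-specified simulation would show no
relation between prediction error and domain membership, and AD filtering
would have nothing to detect. Setting `curvature=0` recovers the perfectly
specified model, for which test Q² converges to 1 − σ²/var(y_train) — the
closed form used as a limit check. Real QSAR errors are of course not
exactly quadratic in distance; the generator targets the qualitative
contract (larger standardized errors outside the domain, occasional
accurate low-reliability predictions), not any error law.

## Problem sizes

The test suite runs on n ≤ 100-sample instances (brute-force oracle
equivalence up to n = 50, p = 10 over all metrics) and the Monte Carlo
checks use 200 iterations on the 50-sample cluster; these sizes already
exercise every code path and keep the full suite in a few seconds. The
algorithms are O(n²p) and handle the hundreds-of-samples training sets
typical of regulatory QSAR models directly; no approximate neighbour
indexing is provided or needed at that scale.

## Known limitations

- The AD is defined in descriptor space only; it cannot detect
  response-space problems except through the SE report.
- Mahalanobis requires a well-conditioned covariance (n > p, no
  collinearity); there is deliberately no pseudo-inverse fallback.
- Density-based ADs inherit the curse of dimensionality; they are
  provided as comparators, not as the recommended method in p ≳ 10.
- The density-to-AD percentile cutoff is a convention; retained counts
  from the density methods are therefore convention-dependent.
- `suggest_k` formalizes a judgment call; the full retention table is
  always exported so users can override it.
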