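import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from qsarad import (
    KNNApplicabilityDomain,
    apply_ad,
    average_knn_distances,
    build_neighbour_table,
    fit_ad,
    reference_value,
    thresholds_from_refval,
)
from qsarad.distances import resolve_metric

from _oracles import naive_decide, naive_thresholds


@pytest.fixture
def toy_table():
    return build_neighbour_table(np.array([[0.0], [1.0], [3.0]]))


class TestAverageKnnDistances:
    def test_hand_arithmetic(self, toy_table):
        np.testing.assert_allclose(average_knn_distances(toy_table, 2), [2.0, 1.5, 2.5])

    def test_k1_is_first_column(self, toy_table):
        np.testing.assert_array_equal(average_knn_distances(toy_table, 1),
                                      toy_table.D[:, 0])

    def test_monotone_in_k(self):
        rng = np.random.default_rng(0)
        table = build_neighbour_table(rng.standard_normal((20, 3)))
        prev = average_knn_distances(table, 1)
        for k in range(2, 20):
            cur = average_knn_distances(table, k)
            assert np.all(cur >= prev - 1e-12)
            prev = cur

    def test_k_out_of_range(self, toy_table):
        with pytest.raises(ValueError):
            average_knn_distances(toy_table, 3)


class TestReferenceValue:
    @pytest.mark.parametrize(
        "vec, expected",
        [
            ([5.0, 5.0, 5.0], 5.0),
            ([1.0, 1.0, 2.0], 2.25),
            ([1.0, 1.0, 1.0, 98.0], 61.625),
        ],
    )
    def test_tukey_upper_fence(self, vec, expected):
        assert reference_value(vec) == pytest.approx(expected)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            reference_value([])


class TestThresholds:
    def test_outlier_inherits_minimum_threshold(self):
        table = build_neighbour_table(np.array([[0.0], [1.0], [2.0], [100.0]]))
        rv = reference_value(average_knn_distances(table, 1))
        assert rv == pytest.approx(61.625)
        K, t, fb = thresholds_from_refval(table, rv)
        np.testing.assert_array_equal(K, [2, 2, 2, 0])
        np.testing.assert_allclose(t, [1.5, 1.0, 1.5, 1.0])
        np.testing.assert_array_equal(fb, [False, False, False, True])

    def test_no_truncation_when_refval_large(self, toy_table):
        K, t, fb = thresholds_from_refval(toy_table, 1e9)
        np.testing.assert_array_equal(K, [2, 2, 2])
        np.testing.assert_allclose(t, toy_table.D.mean(axis=1))
        assert not fb.any()

    def test_refval_below_all_distances_is_error(self, toy_table):
        with pytest.raises(ValueError, match="K_i = 0"):
            thresholds_from_refval(toy_table, 0.5)


class TestFitApply:
    def test_chained_hand_values_toy(self, toy_1d):
        model = fit_ad(toy_1d, k=1, pretreat=False)
        assert model.ref_val_ == pytest.approx(2.25)
        np.testing.assert_allclose(model.thresholds_, [1.0, 1.5, 2.0])
        (d,) = apply_ad(model, np.array([[2.0]]))
        assert d.in_ad and d.K_j == 2
        assert d.nearest_satisfying_distance == pytest.approx(1.0)

    def test_query_identical_to_training_sample_is_inside(self, toy_1d):
        model = fit_ad(toy_1d, k=2, pretreat=False)
        assert model.predict(np.array([[0.0]]))[0]

    def test_far_query_is_outside(self, toy_1d):
        model = fit_ad(toy_1d, k=2, pretreat=False)
        (d,) = apply_ad(model, np.array([[1e6]]))
        assert not d.in_ad and d.K_j == 0 and d.nearest_satisfying_distance is None

    def test_cluster_outliers_get_fallback(self, cluster_fixture):
        model = fit_ad(cluster_fixture, k=12)
        assert np.array_equal(model.K_[-2:], [0, 0])
        assert model.fallback_mask_[-2:].all()
        non_fb = model.thresholds_[~model.fallback_mask_]
        assert np.allclose(model.thresholds_[-2:], non_fb.min())

    def test_deterministic_refit(self, cluster_fixture):
        m1 = fit_ad(cluster_fixture, k=12)
        m2 = fit_ad(cluster_fixture, k=12)
        assert m1.to_json() == m2.to_json()

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            fit_ad(np.zeros((2, 1)), k=1)

    def test_dimension_mismatch_on_apply(self, toy_1d):
        model = fit_ad(toy_1d, k=1, pretreat=False)
        with pytest.raises(ValueError):
            model.predict(np.zeros((1, 3)))

    def test_auto_k_uses_cube_root_rule(self, cluster_fixture):
        model = fit_ad(cluster_fixture, k="auto")
        assert model.k_ == round(50 ** (1 / 3))

    def test_sklearn_params_roundtrip(self):
        est = KNNApplicabilityDomain(k=4, metric="manhattan", scale=False)
        clone = KNNApplicabilityDomain(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestModelInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_bundle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(8, 30)), int(rng.integers(1, 5))
        X = rng.standard_normal((n, p))
        k = int(rng.integers(1, n - 1))
        model = KNNApplicabilityDomain(k=k, scale=False).fit(X)
        assert np.all((model.K_ >= 0) & (model.K_ <= n - 1))
        assert np.all(model.thresholds_ <= model.ref_val_ + 1e-12)
        if model.thresholds_.min() > 0:
            # training self-coverage: each training point queries as inside
            assert model.predict(X).all()

    def test_monotonicity_in_k_on_cluster_geometry(self, cluster_fixture):
        """On the cluster-plus-outliers geometry the whole chain — Ref Val,
        densities, thresholds and domain membership — grows with k.

        This holds for the fixture (and generally for compact-support
        training clouds) but is not a theorem: only the average neighbour
        distances are guaranteed monotone, and the Tukey fence 2.5·Q3 −
        1.5·Q1 built on them can decrease when Q1 rises faster than Q3.
        """
        rng = np.random.default_rng(1)
        grid = rng.standard_normal((60, 2)) * 4
        prev = None
        for k in range(1, 26):
            m = KNNApplicabilityDomain(k=k).fit(cluster_fixture)
            cur = (m.ref_val_, m.K_.copy(), m.thresholds_.copy(), m.predict(grid))
            if prev is not None:
                assert cur[0] >= prev[0] - 1e-12
                assert np.all(cur[1] >= prev[1])
                assert np.all(cur[2] >= prev[2] - 1e-12)
                assert np.all(cur[3] | ~prev[3])  # membership only grows
            prev = cur

    def test_thresholds_monotone_in_k_given_monotone_refval(self):
        """Whenever Ref Val does grow from k to k+1, so do every K_i, t_i and
        the membership of any fixed query set."""
        rng = np.random.default_rng(42)
        X = rng.standard_normal((25, 3))
        grid = rng.standard_normal((40, 3)) * 2
        prev = None
        for k in range(1, 25):
            m = KNNApplicabilityDomain(k=k, scale=False).fit(X)
            cur = (m.ref_val_, m.K_.copy(), m.thresholds_.copy(), m.predict(grid))
            if prev is not None and cur[0] >= prev[0]:
                assert np.all(cur[1] >= prev[1])
                assert np.all(cur[2] >= prev[2] - 1e-12)
                assert np.all(cur[3] | ~prev[3])
            prev = cur

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "mahalanobis"])
    @pytest.mark.parametrize("seed", range(4))
    def test_bruteforce_equivalence(self, metric, seed):
        rng = np.random.default_rng(
            1000 + 10 * seed + {"euclidean": 0, "manhattan": 1, "mahalanobis": 2}[metric]
        )
        n, p = int(rng.integers(6, 50)), int(rng.integers(2, 6))
        X = rng.standard_normal((n, p))
        Q = rng.standard_normal((15, p)) * 1.5
        k = int(rng.integers(1, n - 1))
        model = KNNApplicabilityDomain(k=k, metric=metric, scale=True).fit(X)
        spec = resolve_metric(metric, model.X_train_scaled_)
        rv, K, t = naive_thresholds(X, k, metric, spec.inv_cov, scale=True)
        assert model.ref_val_ == pytest.approx(rv, rel=1e-12)
        np.testing.assert_array_equal(model.K_, K)
        np.testing.assert_allclose(model.thresholds_, t, rtol=1e-9)
        in_ad, K_j = naive_decide(X, Q, k, metric, spec.inv_cov, scale=True)
        np.testing.assert_array_equal(model.predict(Q), in_ad)
        np.testing.assert_array_equal(model.reliability_counts(Q), K_j)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        X=arrays(np.float64, (8, 2), elements=st.floats(-50, 50)),
        c=st.floats(0.1, 100),
    )
    def test_metric_scale_equivariance(self, X, c):
        """Multiplying raw coordinates by c scales distances/thresholds by c
        and leaves counts and memberships unchanged (pretreatment off)."""
        if np.unique(X, axis=0).shape[0] < 8:
            return  # duplicate rows can zero out thresholds; not the property at issue
        m1 = KNNApplicabilityDomain(k=3, scale=False).fit(X)
        m2 = KNNApplicabilityDomain(k=3, scale=False).fit(X * c)
        assert m2.ref_val_ == pytest.approx(m1.ref_val_ * c, rel=1e-9)
        np.testing.assert_allclose(m2.avg_knn_dist_, m1.avg_knn_dist_ * c, rtol=1e-9)
        np.testing.assert_allclose(m2.thresholds_, m1.thresholds_ * c, rtol=1e-9)
        np.testing.assert_array_equal(m2.K_, m1.K_)
        Q = X.mean(axis=0, keepdims=True) + np.array([[0.5, -0.5]])
        np.testing.assert_array_equal(m2.reliability_counts(Q * c),
                                      m1.reliability_counts(Q))


class TestSerialization:
    def test_json_roundtrip_preserves_decisions(self, tmp_path, cluster_fixture):
        model = fit_ad(cluster_fixture, k=12)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = KNNApplicabilityDomain.from_json(path)
        rng = np.random.default_rng(3)
        Q = rng.standard_normal((30, 2)) * 5
        np.testing.assert_array_equal(back.predict(Q), model.predict(Q))
        np.testing.assert_array_equal(back.reliability_counts(Q),
                                      model.reliability_counts(Q))
        np.testing.assert_array_equal(back.thresholds_, model.thresholds_)

    def test_unfitted_serialization_fails(self):
        with pytest.raises(ValueError):
            KNNApplicabilityDomain().to_json()
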