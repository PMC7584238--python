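import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qustex.response_model import (
    CohortTable,
    FLDClassifier,
    KNNClassifier,
    SVMRBFClassifier,
    aggregate_subsets,
    balanced_subsets,
    compare_feature_distributions,
    forward_select,
    loocv_evaluate,
    roc_curve_points,
    train_fld,
    train_knn,
    train_svm_rbf,
)


def make_cohort(X, labels, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "id", [f"p{i:03d}" for i in range(len(df))])
    df.insert(1, "label", labels)
    return CohortTable(df)


def blobs(n_per_class, d=2, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, d))
    X1 = rng.normal(sep, 1.0, size=(n_per_class, d))
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestCohortTable:
    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame({"id": ["a", "a"], "label": ["R", "NR"], "f0": [1.0, 2.0]})
        with pytest.raises(ValueError, match="unique"):
            CohortTable(df)

    def test_bad_label_rejected(self):
        df = pd.DataFrame({"id": ["a", "b"], "label": ["R", "maybe"], "f0": [1, 2]})
        with pytest.raises(ValueError):
            CohortTable(df)

    def test_positive_class_is_nr(self):
        c = make_cohort(np.zeros((2, 1)), ["R", "NR"])
        np.testing.assert_array_equal(c.y(), [0, 1])


class TestBalancedSubsets:
    def test_imbalanced_83_17(self):
        X = np.random.default_rng(0).normal(size=(100, 3))
        cohort = make_cohort(X, ["R"] * 83 + ["NR"] * 17)
        subsets = balanced_subsets(cohort, n_subsets=7, seed=1)
        assert len(subsets) == 7
        for s in subsets:
            assert s.n == 34
            n0, n1 = s.class_counts()
            assert n0 == n1 == 17

    def test_already_balanced_is_full_cohort(self):
        cohort = make_cohort(np.zeros((10, 2)), ["R"] * 5 + ["NR"] * 5)
        subsets = balanced_subsets(cohort, n_subsets=3, seed=0)
        for s in subsets:
            assert sorted(s.df["id"]) == sorted(cohort.df["id"])

    def test_deterministic(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        cohort = make_cohort(X, ["R"] * 24 + ["NR"] * 6)
        a = balanced_subsets(cohort, 7, seed=42)
        b = balanced_subsets(cohort, 7, seed=42)
        for sa, sb in zip(a, b):
            assert list(sa.df["id"]) == list(sb.df["id"])

    def test_majority_without_replacement(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        cohort = make_cohort(X, ["R"] * 24 + ["NR"] * 6)
        for s in balanced_subsets(cohort, 7, seed=3):
            assert not s.df["id"].duplicated().any()

    def test_bad_args(self):
        cohort = make_cohort(np.zeros((4, 1)), ["R", "R", "R", "NR"])
        with pytest.raises(ValueError):
            balanced_subsets(cohort, 0)
        with pytest.raises(ValueError, match="minority"):
            balanced_subsets(cohort, 2)


class TestFLD:
    def test_separable_training_accuracy(self):
        X, y = blobs(20, sep=8.0)
        clf = train_fld(X, y)
        assert (clf.predict(X) == y).all()

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(1)
        X_train, y_train = rng.normal(size=(40, 3)), np.repeat([0, 1], 20)
        clf = train_fld(X_train, y_train)
        X_test = rng.normal(size=(400, 3))
        y_test = np.repeat([0, 1], 200)
        auc = roc_curve_points(clf.score_samples(X_test), y_test).auc
        assert 0.4 < auc < 0.6

    def test_affine_rescaling_invariant_scores(self):
        X, y = blobs(15, d=3, sep=3.0, seed=2)
        scale = np.array([0.1, 10.0, 3.0])
        shift = np.array([5.0, -2.0, 0.5])
        a = train_fld(X, y).score_samples(X)
        b = train_fld(X * scale + shift, y).score_samples(X * scale + shift)
        np.testing.assert_allclose(a, b, rtol=1e-8, atol=1e-10)

    def test_singular_covariance_ridge_fallback(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        clf = train_fld(X, y)  # perfectly collinear features
        assert (clf.predict(X) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_fld(np.zeros((4, 2)), np.zeros(4, int))


class TestKNN:
    def test_k1_training_recall(self):
        X, y = blobs(10, seed=3)
        clf = train_knn(X, y, k=1)
        assert (clf.predict(X) == y).all()

    def test_duplicated_training_points_scores_unchanged(self):
        X, y = blobs(8, seed=4)
        rng = np.random.default_rng(5)
        queries = rng.normal(1.0, 3.0, size=(20, 2))
        a = train_knn(X, y, k=3).score_samples(queries)
        b = train_knn(np.vstack([X, X]), np.concatenate([y, y]), k=6).score_samples(
            queries
        )
        np.testing.assert_allclose(a, b)

    def test_k_too_large_rejected(self):
        X, y = blobs(2)
        with pytest.raises(ValueError, match="k="):
            train_knn(X, y, k=10)

    def test_score_is_nr_fraction(self):
        X = np.array([[0.0], [0.1], [10.0]])
        y = np.array([1, 1, 0])
        clf = train_knn(X, y, k=2)
        assert clf.score_samples(np.array([[0.05]]))[0] == 1.0


class TestSVM:
    def test_xor_separated_by_rbf_not_fld(self):
        rng = np.random.default_rng(6)
        n = 50
        X = rng.uniform(-1, 1, size=(4 * n, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        svm = train_svm_rbf(X, y, C=10.0)
        fld = train_fld(X, y)
        assert (svm.predict(X) == y).mean() >= 0.9
        assert abs((fld.predict(X) == y).mean() - 0.5) < 0.15


class TestForwardSelect:
    def test_informative_feature_found_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 40
            y = np.repeat([0, 1], n // 2)
            X = rng.normal(size=(n, 10))
            X[:, 4] += 3.0 * y  # single informative feature
            names = [f"f{i}" for i in range(10)]
            sel = forward_select(X, y, lambda: FLDClassifier(), names, max_k=1)
            hits += sel[0] == "f4"
        assert hits >= 18  # >= 90% of seeds

    def test_max_k_one(self):
        X, y = blobs(10, d=4, seed=7)
        sel = forward_select(X, y, lambda: FLDClassifier(),
                             [f"f{i}" for i in range(4)], max_k=1)
        assert len(sel) == 1

    def test_tie_break_canonical_order(self):
        X, y = blobs(10, d=1, sep=5.0, seed=8)
        X = np.hstack([X, X])  # identical duplicate columns
        sel = forward_select(X, y, lambda: FLDClassifier(), ["a", "b"], max_k=1)
        assert sel == ["a"]

    def test_stops_when_no_improvement(self):
        rng = np.random.default_rng(9)
        n = 30
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 5))
        X[:, 0] += 10.0 * y  # one perfect feature; others pure noise
        sel = forward_select(X, y, lambda: FLDClassifier(),
                             [f"f{i}" for i in range(5)], max_k=3)
        assert sel[0] == "f0"
        assert len(sel) == 1  # accuracy already 1.0, no strict improvement

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            forward_select(np.zeros((4, 0)), np.array([0, 0, 1, 1]),
                           lambda: FLDClassifier(), [])


class TestLOOCVEvaluate:
    def test_separable_cohort_perfect_panel(self):
        X, y = blobs(10, sep=10.0, seed=10)
        cohort = make_cohort(X, ["NR" if v else "R" for v in y])
        res = loocv_evaluate(cohort, lambda: KNNClassifier(3),
                             selection_policy="none")
        assert res.sensitivity == res.specificity == res.accuracy == 1.0
        assert res.auc == 1.0

    def test_panel_keys(self):
        X, y = blobs(6, seed=11)
        cohort = make_cohort(X, ["NR" if v else "R" for v in y])
        res = loocv_evaluate(cohort, lambda: FLDClassifier(),
                             selection_policy="none")
        assert set(res.panel()) == {
            "sensitivity", "specificity", "ppv", "npv", "accuracy", "auc"
        }

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(34, 5))
        labels = rng.permutation(["R"] * 17 + ["NR"] * 17)
        cohort = make_cohort(X, list(labels))
        res = loocv_evaluate(cohort, lambda: FLDClassifier(),
                             selection_policy="none")
        assert 0.3 <= res.auc <= 0.7

    def test_selection_policies_differ_only_in_selection(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(16, 6))
        X[:, 2] += 4.0 * np.repeat([0, 1], 8)
        cohort = make_cohort(X, ["R"] * 8 + ["NR"] * 8)
        nested = loocv_evaluate(cohort, lambda: FLDClassifier(),
                                selection_policy="nested", max_features=2)
        legacy = loocv_evaluate(cohort, lambda: FLDClassifier(),
                                selection_policy="per_subset", max_features=2)
        assert nested.selection_mode == "nested"
        assert legacy.selection_mode == "per_subset"
        assert "f2" in legacy.selected_features
        assert "f2" in nested.selected_features

    def test_no_leakage_held_out_row_does_not_affect_fold_model(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(12, 4))
        X[:, 1] += 3.0 * np.repeat([0, 1], 6)
        y = np.repeat([0, 1], 6)
        names = [f"f{i}" for i in range(4)]
        i = 5
        keep = np.arange(12) != i

        # selection computed from training rows only
        sel_clean = forward_select(X[keep], y[keep], lambda: FLDClassifier(),
                                   names, max_k=2)
        X_outlier = X.copy()
        X_outlier[i] = 1e6  # absurd held-out-only outlier
        sel_outlier = forward_select(X_outlier[keep], y[keep],
                                     lambda: FLDClassifier(), names, max_k=2)
        assert sel_clean == sel_outlier

        # and the fold model itself is identical
        cols = [names.index(f) for f in sel_clean]
        w_clean = FLDClassifier().fit(X[np.ix_(keep, cols)], y[keep]).w_
        w_outlier = FLDClassifier().fit(X_outlier[np.ix_(keep, cols)], y[keep]).w_
        np.testing.assert_array_equal(w_clean, w_outlier)

    def test_unknown_policy_rejected(self):
        X, y = blobs(4)
        cohort = make_cohort(X, ["NR" if v else "R" for v in y])
        with pytest.raises(ValueError):
            loocv_evaluate(cohort, lambda: FLDClassifier(), selection_policy="bogus")


class TestROCAndAggregate:
    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_mann_whitney_u(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = 13, 21
        scores = np.round(rng.normal(size=n1 + n0), 1)  # rounding forces ties
        y = np.array([1] * n1 + [0] * n0)
        scores[y == 1] += rng.uniform(0, 1)
        roc = roc_curve_points(scores, y)
        u = stats.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert roc.auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_roc_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(20)
        scores = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        roc = roc_curve_points(scores, y)
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    def _results(self):
        X, y = blobs(8, seed=21)
        cohort = make_cohort(X, ["NR" if v else "R" for v in y])
        r = loocv_evaluate(cohort, lambda: FLDClassifier(), selection_policy="none")
        return [r, r, r]

    def test_identical_results_aggregate_to_same(self):
        results = self._results()
        agg = aggregate_subsets(results, rule="mean")
        for key, value in agg.panel().items():
            assert value == pytest.approx(results[0].panel()[key])

    def test_aggregate_within_min_max(self):
        results = self._results()
        agg = aggregate_subsets(results)
        for key, value in agg.panel().items():
            vals = [r.panel()[key] for r in results]
            assert min(vals) - 1e-12 <= value <= max(vals) + 1e-12

    def test_rule_switch_preserves_per_subset(self):
        results = self._results()
        a = aggregate_subsets(results, rule="mean")
        b = aggregate_subsets(results, rule="pooled")
        for ra, rb in zip(a.per_subset, b.per_subset):
            assert ra.panel() == rb.panel()


class TestCompareFeatureDistributions:
    def test_shifted_feature_detected(self):
        rng = np.random.default_rng(22)
        n = 50
        X = rng.normal(size=(2 * n, 3))
        X[n:, 1] += 3.0
        cohort = make_cohort(X, ["R"] * n + ["NR"] * n)
        report = compare_feature_distributions(cohort)
        row = report[report.feature == "f1"].iloc[0]
        assert row.p_value < 1e-3 and row.significant

    def test_gate_routes_heavy_tails_to_mannwhitney(self):
        rng = np.random.default_rng(23)
        n = 50
        heavy = rng.standard_cauchy(size=2 * n)
        normal = rng.normal(size=2 * n)
        X = np.column_stack([heavy, normal])
        cohort = make_cohort(X, ["R"] * n + ["NR"] * n)
        report = compare_feature_distributions(cohort)
        assert report[report.feature == "f0"].iloc[0].test == "mannwhitney"
        assert report[report.feature == "f1"].iloc[0].test == "t"

    def test_constant_feature_skipped(self):
        rng = np.random.default_rng(24)
        X = np.column_stack([np.full(20, 7.0), rng.normal(size=20)])
        cohort = make_cohort(X, ["R"] * 10 + ["NR"] * 10)
        report = compare_feature_distributions(cohort)
        assert report[report.feature == "f0"].iloc[0].skipped

    def test_small_class_rejected(self):
        cohort = make_cohort(np.zeros((4, 1)), ["R", "R", "NR", "NR"])
        with pytest.raises(ValueError):
            compare_feature_distributions(cohort)
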