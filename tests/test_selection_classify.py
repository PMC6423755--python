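"""Feature ranking, stability selection, the 12-combo grid and recurrence
calls, each against brute-force oracles where one exists."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ngahic.classify import (
    ComboResult,
    RegularizedQDA,
    auc_brute_force,
    confusion_metrics,
    pick_ngahic,
    predict_recurrence,
    train_eval_grid,
    train_final,
)
from ngahic.selection import (
    FeatureBin,
    rank_mrmr,
    rank_rf_importance,
    rank_wrst,
    stability_select,
)


def exact_wrst_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration of all assignments of
    the pooled values to the two groups (tie-free data)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def ustat(idx):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    u_obs = ustat(range(n1))
    us = np.array([ustat(c) for c in combinations(range(len(pooled)), n1)])
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return float(min(1.0, 2.0 * min(lo, hi)))


class TestWRST:
    def test_extreme_three_vs_three(self):
        """{1,2,3} vs {10,11,12}: the most extreme of the 20 rank splits,
        exact two-sided p = 0.1."""
        X = pd.DataFrame({"f": [1, 2, 3, 10, 11, 12]}, dtype=float)
        y = np.array([1, 1, 1, 0, 0, 0])
        order, pvals = rank_wrst(X, y)
        assert pvals["f"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        y = np.array([1, 1, 1, 0, 0, 0])
        _, pvals = rank_wrst(X, y)
        assert pvals["f"] == pytest.approx(1.0)

    def test_constant_feature_convention(self):
        X = pd.DataFrame({"c": np.ones(10), "f": np.arange(10.0)})
        y = np.array([0, 1] * 5)
        order, pvals = rank_wrst(X, y)
        assert pvals["c"] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, seed):
        """Four-vs-four continuous data: the implementation's p equals full
        enumeration over all 70 assignments."""
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 4)
        b = rng.normal(0.5, 1, 4)
        X = pd.DataFrame({"f": np.concatenate([a, b])})
        y = np.array([1] * 4 + [0] * 4)
        _, pvals = rank_wrst(X, y)
        assert pvals["f"] == pytest.approx(exact_wrst_p(a, b), abs=1e-12)


class TestMRMR:
    def test_label_copy_ranked_first(self, rng):
        n = 60
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame({
            "label_like": y + rng.normal(0, 0.01, n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        assert rank_mrmr(X, y)[0] == "label_like"

    def test_redundancy_penalty_prefers_independent_feature(self, rng):
        """With two near-duplicate strong features and one weaker independent
        one, the second greedy pick is the independent feature."""
        n = 80
        y = np.array([0, 1] * (n // 2))
        strong = y * 2.0 + rng.normal(0, 0.3, n)
        X = pd.DataFrame({
            "strong_a": strong,
            "strong_b": strong + rng.normal(0, 1e-6, n),
            "weaker": y * 1.0 + rng.normal(0, 1.2, n),
        })
        ranked = rank_mrmr(X, y, top_k=2)
        assert ranked[0] in ("strong_a", "strong_b")
        assert ranked[1] == "weaker"

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(6.0), "b": np.arange(6.0)})
        with pytest.raises(ValueError):
            rank_mrmr(X, np.zeros(6, dtype=int))


class TestRFImportance:
    def test_informative_feature_first_and_deterministic(self, rng):
        n = 80
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"f{i}" for i in range(10)])
        X["signal"] = y * 2.0 + rng.normal(0, 0.5, n)
        r1 = rank_rf_importance(X, y, seed=5)
        r2 = rank_rf_importance(X, y, seed=5)
        assert r1[0] == "signal"
        assert r1 == r2


class TestStabilitySelection:
    def test_bin_size_and_overwhelming_feature(self, rng):
        n = 60
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame(rng.normal(size=(n, 20)), columns=[f"f{i:02d}" for i in range(20)])
        X["huge"] = y * 5.0 + rng.normal(0, 1.0, n)
        fb = stability_select(X, y, "WRST", n_iter=10, seed=0)
        assert len(fb.features) == 5
        assert len(set(fb.features)) == 5
        assert fb.stability_scores["huge"] == 1.0

    def test_pure_noise_no_dominant_feature(self, rng):
        """On pure noise no feature is selected in every fold, and the
        selection frequencies over all features sum to the bin size (each
        fold-level list contributes exactly k picks)."""
        n = 60
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame(rng.normal(size=(n, 100)), columns=[f"f{i:03d}" for i in range(100)])
        fb = stability_select(X, y, "WRST", n_iter=10, seed=1)
        assert max(fb.stability_scores.values()) < 1.0

    def test_duplicate_features_rejected_in_bin(self):
        with pytest.raises(ValueError, match="duplicates"):
            FeatureBin(method="WRST", features=["a", "a", "b", "c", "d"])


def make_cohort(rng, n=60, effect=2.0):
    y = np.array([0, 1] * (n // 2))
    X = pd.DataFrame(rng.normal(size=(n, 30)), columns=[f"f{i:02d}" for i in range(30)])
    for col in ("f00", "f01", "f02", "f03", "f04"):
        X[col] += y * effect
    return X, y


class TestGrid:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(10)
        X, y = make_cohort(rng)
        bins = [stability_select(X, y, m, n_iter=5, seed=2) for m in ("WRST", "MRMR", "RF")]
        grid = train_eval_grid(X, y, bins, seed=3, n_repeats=3)
        return X, y, bins, grid

    def test_twelve_combos(self, fitted):
        _, _, _, grid = fitted
        assert len(grid) == 12
        assert {(r.learner, r.bin_method) for r in grid} == {
            (l, b) for l in ("ALD", "AQD", "MSV", "RF") for b in ("WRST", "MRMR", "RF")
        }

    def test_separable_cohort_high_auc(self, fitted):
        _, _, _, grid = fitted
        assert all(r.auc >= 0.95 for r in grid)

    def test_permuted_labels_chance_auc(self, fitted):
        X, y, bins, _ = fitted
        rng = np.random.default_rng(4)
        grid = train_eval_grid(X, rng.permutation(y), bins, seed=5, n_repeats=3)
        mean_auc = np.mean([r.auc for r in grid])
        assert 0.35 < mean_auc < 0.65

    def test_pick_best_and_tiebreak(self, fitted):
        _, _, _, grid = fitted
        best = pick_ngahic(grid)
        assert best.auc == max(r.auc for r in grid)
        with pytest.raises(ValueError, match="expected 12"):
            pick_ngahic(grid[:2])

    def test_tiebreak_uses_fixed_order(self):
        results = [
            ComboResult(learner=l, bin_method=b, auc=0.8, auc_sd=0, accuracy=0.8,
                        accuracy_sd=0, specificity=0.8, specificity_sd=0,
                        sensitivity=0.8, sensitivity_sd=0)
            for l in ("ALD", "AQD", "MSV", "RF") for b in ("WRST", "MRMR", "RF")
        ]
        best = pick_ngahic(results)
        assert (best.learner, best.bin_method) == ("ALD", "WRST")


class TestPrediction:
    def test_threshold_is_strict(self):
        class Stub:
            features = ["f"]

            def predict_proba(self, X):
                return np.array([0.50, 0.51])

        calls = predict_recurrence(Stub(), pd.DataFrame({"f": [0.0, 1.0]}, index=["a", "b"]))
        assert [c.label for c in calls] == [0, 1]

    def test_missing_columns_hard_error(self, rng):
        X, y = make_cohort(rng)
        fb = FeatureBin(method="WRST", features=["f00", "f01", "f02", "f03", "f04"])
        model = train_final(X, y, fb, "MSV", seed=0)
        with pytest.raises(ValueError, match="missing feature columns"):
            model.predict_proba(X.drop(columns=["f02"]))

    def test_empty_input_empty_output(self, rng):
        X, y = make_cohort(rng)
        fb = FeatureBin(method="WRST", features=["f00", "f01", "f02", "f03", "f04"])
        model = train_final(X, y, fb, "RF", seed=0)
        assert predict_recurrence(model, X.iloc[:0]) == []

    def test_training_labels_recovered_on_separable_cohort(self, rng):
        X, y = make_cohort(rng, effect=4.0)
        fb = FeatureBin(method="WRST", features=["f00", "f01", "f02", "f03", "f04"])
        model = train_final(X, y, fb, "MSV", seed=0)
        calls = predict_recurrence(model, X)
        assert np.mean([c.label for c in calls] == y) >= 0.95


class TestMetricsOracles:
    def test_auc_equals_pairwise_concordance(self, rng):
        """sklearn's ROC AUC equals the brute-force pairwise count (ties as
        half) on a 50-spot set with deliberate score ties."""
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        scores = np.round(rng.uniform(0, 1, 50), 1)  # force ties
        assert roc_auc_score(y, scores) == pytest.approx(auc_brute_force(y, scores), abs=1e-12)

    def test_confusion_metrics_match_hand_counts(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        p = np.array([0.9, 0.6, 0.2, 0.1, 0.7, 0.4, 0.5, 0.5])
        acc, spec, sens = confusion_metrics(y, p)
        # calls: 1,1,0,0,1,0,0,0 -> TP=2 FN=2 TN=3 FP=1
        assert acc == pytest.approx(5 / 8)
        assert spec == pytest.approx(3 / 4)
        assert sens == pytest.approx(2 / 4)

    def test_regularized_qda_small_class(self, rng):
        """The quadratic discriminant stays defined when one class has fewer
        samples than features."""
        X = rng.normal(size=(9, 5))
        y = np.array([0] * 4 + [1] * 5)
        X[y == 1] += 3.0
        proba = RegularizedQDA().fit(X, y).predict_proba(X)
        assert proba.shape == (9, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert ((proba[:, 1] > 0.5).astype(int) == y).mean() == 1.0
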