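import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ketox import aop_model


def make_xy(n=20, p=3, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    y = pd.Series(rng.integers(0, 2, n), index=[f"C{i:03d}" for i in range(n)])
    if y.nunique() < 2:
        y.iloc[0] = 1 - y.iloc[0]
    X = pd.DataFrame(
        rng.normal(size=(n, p)), index=y.index, columns=[f"f{j}" for j in range(p)]
    )
    if informative:
        X["f0"] = y + 0.01 * rng.normal(size=n)
    return X, y


class TestUndersample:
    def test_imbalanced_reduced_to_minority_size(self):
        labels = pd.Series([1] * 80 + [0] * 20, index=[f"C{i}" for i in range(100)])
        kept = aop_model.undersample_balance(labels, seed=0)
        sub = labels.loc[kept]
        assert len(kept) == 40
        assert (sub == 1).sum() == 20 and (sub == 0).sum() == 20

    def test_already_balanced_unchanged(self):
        labels = pd.Series([1] * 53 + [0] * 53, index=[f"C{i}" for i in range(106)])
        kept = aop_model.undersample_balance(labels, seed=3)
        assert sorted(kept) == sorted(labels.index)

    def test_deterministic_given_seed(self):
        labels = pd.Series([1] * 60 + [0] * 15, index=[f"C{i}" for i in range(75)])
        a = aop_model.undersample_balance(labels, seed=9)
        b = aop_model.undersample_balance(labels, seed=9)
        c = aop_model.undersample_balance(labels, seed=10)
        assert a == b
        assert a != c

    def test_single_class_rejected(self):
        labels = pd.Series([1, 1, 1], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            aop_model.undersample_balance(labels, seed=0)


class TestFitLogistic:
    def test_label_copy_feature_gives_perfect_training_accuracy(self):
        y = pd.Series([0, 1] * 5, index=[f"C{i}" for i in range(10)])
        X = pd.DataFrame({"f": y.astype(float)})
        model, _ = aop_model.fit_logistic(X, y)
        pred = model.predict(X.to_numpy())
        assert (pred == y.to_numpy()).all()

    def test_constant_feature_zero_coef_base_rate_intercept(self):
        y = pd.Series([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], index=[f"C{i}" for i in range(10)])
        X = pd.DataFrame({"f": np.ones(10)}, index=y.index)
        model, coef = aop_model.fit_logistic(X, y)
        table = coef.set_index("feature")["coefficient"]
        assert table["f"] == pytest.approx(0.0, abs=1e-8)
        base_rate = 0.3
        assert table["(intercept)"] == pytest.approx(math.log(base_rate / (1 - base_rate)), abs=1e-6)

    def test_label_independent_features_stay_near_base_rate(self):
        rng = np.random.default_rng(7)
        n = 200
        y = pd.Series(rng.integers(0, 2, n), index=[f"C{i}" for i in range(n)])
        X = pd.DataFrame(rng.normal(size=(n, 5)), index=y.index, columns=[f"f{j}" for j in range(5)])
        model, _ = aop_model.fit_logistic(X, y)
        acc = (model.predict(X.to_numpy()) == y.to_numpy()).mean()
        base = max(y.mean(), 1 - y.mean())
        assert acc <= base + 0.12  # near the base-rate bound, small overfit allowance


class TestLooCV:
    def test_perfectly_separable_gives_loo_accuracy_one(self):
        y = pd.Series([0, 1] * 6, index=[f"C{i}" for i in range(12)])
        X = pd.DataFrame({"f": y.astype(float), "noise": 0.0}, index=y.index)
        result = aop_model.loo_cv(X, y)
        assert result.accuracy == 1.0

    def test_confusion_arithmetic(self):
        # TP=3, FN=1, TN=2, FP=2 -> accuracy 5/8, recall 3/4
        y = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=list("abcdefgh"))
        probs = pd.Series([0.9, 0.8, 0.7, 0.2, 0.1, 0.3, 0.6, 0.8], index=y.index)
        result = aop_model.AopModelResult(model_id=1, probabilities=probs, actual=y)
        assert result.confusion == {"TP": 3, "FP": 2, "TN": 2, "FN": 1}
        assert result.accuracy == pytest.approx(5 / 8)
        assert result.recall == pytest.approx(3 / 4)

    def test_class_swap_symmetry(self):
        y = pd.Series([1, 1, 0, 0], index=list("abcd"))
        X = pd.DataFrame({"f": [1.0, 1.0, -1.0, -1.0]}, index=y.index)
        result = aop_model.loo_cv(X, y)
        swapped = aop_model.loo_cv(-X, 1 - y)
        # negating features and swapping classes complements every probability
        np.testing.assert_allclose(
            result.probabilities.to_numpy(), 1.0 - swapped.probabilities.to_numpy(), atol=1e-6
        )

    def test_single_class_rejected(self):
        y = pd.Series([1, 1, 1, 1], index=list("abcd"))
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]}, index=y.index)
        with pytest.raises(ValueError):
            aop_model.loo_cv(X, y)

    def test_too_small_rejected(self):
        y = pd.Series([1, 0], index=list("ab"))
        X = pd.DataFrame({"f": [1.0, 0.0]}, index=y.index)
        with pytest.raises(ValueError):
            aop_model.loo_cv(X, y)

    def test_flipping_heldout_label_never_changes_its_prediction(self):
        """Leakage canary: the held-out chemical's label must be invisible
        to the fold that predicts it."""
        X, y = make_xy(n=16, p=2, seed=5)
        base = aop_model.loo_cv(X, y)
        for i in range(len(y)):
            y_flip = y.copy()
            y_flip.iloc[i] = 1 - y_flip.iloc[i]
            if y_flip.nunique() < 2:
                continue
            flipped = aop_model.loo_cv(X, y_flip)
            assert flipped.probabilities.iloc[i] == pytest.approx(
                base.probabilities.iloc[i], abs=1e-9
            )


class TestFeatureGroupTest:
    def test_identical_distributions_give_zero_t(self):
        y = pd.Series([1, 1, 0, 0], index=list("abcd"))
        X = pd.DataFrame({"f": [3.0, 3.0, 3.0, 3.0]}, index=y.index)
        row = aop_model.feature_group_test(X, y).iloc[0]
        assert row["t_stat"] == 0.0
        assert row["p_value"] == 1.0

    def test_constant_separated_groups_give_infinite_t(self):
        y = pd.Series([1, 1, 1, 0, 0, 0], index=list("abcdef"))
        X = pd.DataFrame({"f": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]}, index=y.index)
        row = aop_model.feature_group_test(X, y).iloc[0]
        assert row["t_stat"] == math.inf
        assert row["p_value"] == 0.0

    def test_matches_welch_formula_on_hand_data(self):
        y = pd.Series([1, 1, 1, 0, 0, 0], index=list("abcdef"))
        vals = np.array([2.1, 2.9, 2.5, 1.0, 1.6, 1.3])
        X = pd.DataFrame({"f": vals}, index=y.index)
        row = aop_model.feature_group_test(X, y).iloc[0]
        expected_t, expected_p = stats.ttest_ind(vals[:3], vals[3:], equal_var=False)
        assert row["t_stat"] == pytest.approx(float(expected_t), rel=1e-12)
        assert row["p_value"] == pytest.approx(float(expected_p), rel=1e-12)

    def test_ranked_by_absolute_t(self):
        X, y = make_xy(n=40, p=4, seed=2)
        frame = aop_model.feature_group_test(X, y)
        assert frame.iloc[0]["feature"] == "f0"  # the informative one
        assert frame["t_stat"].abs().is_monotonic_decreasing


class TestCompareModels:
    def _result(self, probs, y):
        return aop_model.AopModelResult(
            model_id=1, probabilities=pd.Series(probs, index=y.index), actual=y
        )

    def test_identical_results_give_zero_deltas(self):
        y = pd.Series([1, 0, 1, 0], index=list("abcd"))
        r = self._result([0.9, 0.1, 0.8, 0.2], y)
        comp = aop_model.compare_models(r, r)
        assert comp["accuracy_delta"] == 0.0
        assert comp["corrected"] == []

    def test_constructed_three_corrections(self):
        y = pd.Series([1, 1, 1, 0, 0, 0], index=list("abcdef"))
        r1 = self._result([0.2, 0.3, 0.1, 0.9, 0.4, 0.3], y)  # wrong on a, b, c, d
        r2 = self._result([0.8, 0.7, 0.9, 0.8, 0.1, 0.2], y)  # fixes a, b, c; d still wrong
        comp = aop_model.compare_models(r1, r2)
        assert comp["corrected"] == ["a", "b", "c"]
        assert comp["n_corrected"] == 3
        assert comp["accuracy_delta"] == pytest.approx(3 / 6)


class TestBuildFeatures:
    def test_model1_uses_scores_only(self):
        scores = pd.DataFrame({"KE1": [0.1, 0.5]}, index=["C1", "C2"])
        labels = pd.DataFrame({"hepatotoxic": [1, 0]}, index=["C1", "C2"])
        X, y = aop_model.build_features(scores, labels, model_id=1)
        assert list(X.columns) == ["KE1"]
        assert len(X) == 2

    def test_model2_requires_and_joins_css_and_descriptors(self):
        scores = pd.DataFrame({"KE1": [0.1, 0.5, 0.7]}, index=["C1", "C2", "C3"])
        labels = pd.DataFrame({"hepatotoxic": [1, 0, 1]}, index=["C1", "C2", "C3"])
        css = pd.Series({"C1": 10.0, "C2": 100.0})  # C3 missing -> dropped
        desc = pd.DataFrame({"mol_weight": [46.0, 78.0]}, index=["C1", "C2"])
        X, y = aop_model.build_features(scores, labels, model_id=2, css=css, descriptors=desc)
        assert sorted(X.index) == ["C1", "C2"]
        assert "log10_css" in X.columns and "mol_weight" in X.columns
        assert X.loc["C1", "log10_css"] == pytest.approx(1.0)
        assert not X.isna().any().any()

    def test_model2_without_css_rejected(self):
        scores = pd.DataFrame({"KE1": [0.1]}, index=["C1"])
        labels = pd.DataFrame({"hepatotoxic": [1]}, index=["C1"])
        with pytest.raises(ValueError):
            aop_model.build_features(scores, labels, model_id=2)
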