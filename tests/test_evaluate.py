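"""ROC/AUC, DeLong intervals, operating points, calibration, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hrnv.evaluate import (calibration_curve, crossval_predict, delong_variance,
                           operating_point, roc_auc_ci)
from hrnv.model import ColumnStandardizer, make_logistic, stratified_folds


def brute_force_auc(probs, y):
    """Pairwise concordance with ties counted half."""
    probs, y = np.asarray(probs, float), np.asarray(y, int)
    pos, neg = probs[y == 1], probs[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    @pytest.mark.parametrize("probs,y,expected", [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
        ([0.9, 0.4, 0.6, 0.2], [1, 0, 1, 0], 1.0),
        ([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], 0.0),
        ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),
    ])
    def test_small_examples(self, probs, y, expected):
        assert roc_auc_ci(probs, y)["auc"] == pytest.approx(expected)

    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=10, max_value=200))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_concordance(self, seed, n):
        rng = np.random.default_rng(seed)
        y = np.zeros(n, int)
        y[: max(1, n // 3)] = 1
        rng.shuffle(y)
        probs = rng.choice(np.linspace(0, 1, 11), size=n)  # ties likely
        auc, _ = delong_variance(probs, y)
        assert auc == pytest.approx(brute_force_auc(probs, y), abs=1e-12)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.permutation(np.r_[np.ones(310, int), np.zeros(690, int)])
        probs = rng.random(1000)
        assert 0.45 <= roc_auc_ci(probs, y)["auc"] <= 0.55

    def test_ci_contains_point_and_orders(self):
        rng = np.random.default_rng(1)
        y = (rng.random(300) < 0.3).astype(int)
        probs = np.clip(0.3 + 0.3 * y + rng.normal(0, 0.2, 300), 0, 1)
        ci = roc_auc_ci(probs, y)
        assert ci["ci_low"] <= ci["auc"] <= ci["ci_high"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            roc_auc_ci([0.2, 0.4], [1, 1])

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        y = (rng.random(200) < 0.4).astype(int)
        score = rng.integers(0, 10, 200).astype(float) + y
        a1 = roc_auc_ci(score, y)["auc"]
        a2 = roc_auc_ci(np.exp(score / 3), y)["auc"]
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestOperatingPoint:
    def test_perfect_classifier(self):
        op = operating_point([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert op["sensitivity"] == 100.0 and op["specificity"] == 100.0

    def test_exhaustive_enumeration_example(self):
        op = operating_point([0.9, 0.7, 0.6, 0.3, 0.2], [1, 1, 0, 1, 0])
        assert 0.6 < op["cutoff"] <= 0.7
        assert op["sensitivity"] == pytest.approx(66.7, abs=0.1)
        assert op["specificity"] == pytest.approx(100.0)

    def test_metrics_recomputable_from_confusion_counts(self):
        rng = np.random.default_rng(3)
        y = (rng.random(150) < 0.35).astype(int)
        probs = np.clip(0.3 * y + rng.random(150) * 0.7, 0, 1)
        op = operating_point(probs, y)
        tp, fp, fn, tn = op["tp"], op["fp"], op["fn"], op["tn"]
        assert tp + fp + fn + tn == 150
        assert op["ppv"] == pytest.approx(100 * tp / (tp + fp))
        assert op["npv"] == pytest.approx(100 * tn / (tn + fn))
        for key in ("sensitivity", "specificity", "ppv", "npv"):
            lo, hi = op[f"{key}_ci"]
            assert lo <= op[key] <= hi

    def test_chooses_minimum_corner_distance(self):
        rng = np.random.default_rng(4)
        y = (rng.random(200) < 0.4).astype(int)
        probs = np.clip(0.4 * y + rng.random(200) * 0.6, 0, 1)
        op = operating_point(probs, y)
        best = (1 - op["specificity"] / 100) ** 2 + (1 - op["sensitivity"] / 100) ** 2
        for thr in np.unique(probs):
            pred = probs >= thr
            sens = (pred & (y == 1)).sum() / (y == 1).sum()
            spec = (~pred & (y == 0)).sum() / (y == 0).sum()
            assert best <= (1 - spec) ** 2 + (1 - sens) ** 2 + 1e-12


class TestCalibration:
    def test_constant_prediction_single_bin_on_diagonal(self):
        y = np.r_[np.ones(31, int), np.zeros(69, int)]
        cal = calibration_curve(np.full(100, 0.31), y)
        assert len(cal) == 1
        assert cal.loc[0, "mean_predicted"] == pytest.approx(0.31)
        assert cal.loc[0, "observed_fraction"] == pytest.approx(0.31)

    def test_well_calibrated_probabilities(self):
        rng = np.random.default_rng(5)
        probs = rng.random(10_000)
        y = (rng.random(10_000) < probs).astype(int)
        cal = calibration_curve(probs, y)
        assert (cal["mean_predicted"] - cal["observed_fraction"]).abs().max() < 0.05

    def test_counts_partition_patients(self):
        rng = np.random.default_rng(6)
        probs = rng.random(500)
        y = (rng.random(500) < 0.3).astype(int)
        assert calibration_curve(probs, y)["count"].sum() == 500


class TestCrossvalPredict:
    @pytest.fixture(scope="class")
    def toy(self):
        rng = np.random.default_rng(7)
        n = 300
        y = (rng.random(n) < 0.35).astype(int)
        X = rng.normal(size=(n, 6))
        X[:, 0] += 1.5 * y
        return X, y

    def test_deterministic_under_seed(self, toy):
        X, y = toy
        a = crossval_predict(X, y, folds=5, seed=3)
        b = crossval_predict(X, y, folds=5, seed=3)
        np.testing.assert_array_equal(a, b)
        assert np.all((a >= 0) & (a <= 1))

    def test_perfect_feature_gives_auc_one(self):
        y = np.r_[np.ones(50, int), np.zeros(100, int)]
        X = y[:, None].astype(float)
        probs = crossval_predict(X, y, folds=5, seed=0)
        assert roc_auc_ci(probs, y)["auc"] == 1.0

    def test_fitted_probabilities_average_to_fold_prevalence(self, toy):
        # the ML score equation for LR with intercept forces mean(p) = mean(y)
        X, y = toy
        for tr, _ in stratified_folds(y, 5, seed=0):
            Z = ColumnStandardizer().fit_transform(X[tr])
            clf = make_logistic().fit(Z, y[tr])
            fitted = clf.predict_proba(Z)[:, 1]
            assert fitted.mean() == pytest.approx(y[tr].mean(), abs=1e-6)
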