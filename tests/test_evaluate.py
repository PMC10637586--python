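"""SVM training, DeLong AUC machinery, threshold metrics, calibration and
decision curves."""

import numpy as np
import pytest

from habitatomics.evaluate import (
    auc_ci_delong,
    calibration_curve,
    decision_curve,
    delong_paired_test,
    threshold_metrics,
    train_svm,
    youden_threshold,
)


def pair_counting_auc(scores, labels):
    """Exhaustive concordant-pair oracle (ties count half)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_worked_example(self):
        scores = np.array([0.1, 0.4, 0.2, 0.8])
        labels = np.array([0, 0, 1, 1])
        auc, _ = auc_ci_delong(scores, labels)
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(pair_counting_auc(scores, labels))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        labels = rng.integers(0, 2, n)
        labels[0], labels[1] = 0, 1
        scores = np.round(rng.random(n), 2)  # rounded scores induce ties
        auc, (lo, hi) = auc_ci_delong(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
        assert lo <= auc <= hi

    def test_perfect_ranking(self):
        labels = np.array([0] * 10 + [1] * 10)
        scores = np.linspace(0, 1, 20)
        auc, (lo, hi) = auc_ci_delong(scores, labels)
        assert auc == 1.0 and lo == 1.0 and hi == 1.0  # SE = 0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a, _ = auc_ci_delong(scores, labels)
        b, _ = auc_ci_delong(scores, 1 - labels)
        assert a == pytest.approx(1.0 - b, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc_ci_delong(np.array([0.1, 0.2]), np.array([1, 1]))


class TestDeLongPaired:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        assert delong_paired_test(s, s.copy(), y) == 1.0

    def test_perfect_vs_random_significant(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 200)
        perfect = y + rng.normal(0, 0.01, 200)
        random = rng.random(200)
        assert delong_paired_test(perfect, random, y) < 0.001

    def test_sign_agrees_with_bootstrap(self):
        rng = np.random.default_rng(3)
        n = 120
        y = rng.integers(0, 2, n)
        strong = y + rng.normal(0, 0.8, n)
        weak = y + rng.normal(0, 2.5, n)
        p = delong_paired_test(strong, weak, y)
        # seeded bootstrap of the AUC difference
        diffs = []
        for b in range(300):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            a1, _ = auc_ci_delong(strong[idx], y[idx])
            a2, _ = auc_ci_delong(weak[idx], y[idx])
            diffs.append(a1 - a2)
        diffs = np.array(diffs)
        boot_p = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        assert p < 0.2  # both detect the difference
        assert (p < 0.05) == (boot_p < 0.05)


class TestThresholdMetrics:
    def test_all_predicted_positive(self):
        y = np.array([0, 1, 0, 1, 1])
        m = threshold_metrics(np.full(5, 0.9), y, 0.5)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_worked_confusion_matrix(self):
        # TP=3, FP=1, FN=1, TN=5
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.2, 0.3, 0.1, 0.15, 0.05])
        labels = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        m = threshold_metrics(scores, labels, 0.5)
        assert m["confusion_matrix"] == {"tp": 3, "fp": 1, "fn": 1, "tn": 5}
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        t = 0.4
        m = threshold_metrics(scores, labels, t)
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        fn = sum(1 for s, y in zip(scores, labels) if s < t and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s < t and y == 0)
        assert m["confusion_matrix"] == {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        assert m["accuracy"] == pytest.approx((tp + tn) / 50)

    def test_margins_match_cohort_size(self):
        rng = np.random.default_rng(9)
        scores, labels = rng.random(33), rng.integers(0, 2, 33)
        cm = threshold_metrics(scores, labels, 0.5)["confusion_matrix"]
        assert sum(cm.values()) == 33

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            threshold_metrics(np.array([0.5]), np.array([1]), 1.0)


class TestCalibration:
    def test_perfectly_calibrated_slope_near_one(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0.02, 0.98, 2000)
        labels = (rng.random(2000) < scores).astype(int)
        out = calibration_curve(scores, labels)
        assert out["slope"] == pytest.approx(1.0, abs=0.15)

    def test_constant_half_score(self):
        labels = np.array([0, 1] * 50)
        out = calibration_curve(np.full(100, 0.5), labels)
        occupied = [p for p in out["points"] if p["count"] > 0]
        assert len(occupied) == 1
        assert occupied[0]["mean_predicted"] == pytest.approx(0.5)
        assert occupied[0]["observed_frequency"] == pytest.approx(0.5)

    def test_extreme_scores_match_labels(self):
        labels = np.array([0] * 20 + [1] * 20)
        scores = labels.astype(float)
        out = calibration_curve(scores, labels)
        occupied = [p for p in out["points"] if p["count"] > 0]
        assert occupied[0]["observed_frequency"] == 0.0
        assert occupied[-1]["observed_frequency"] == 1.0


class TestDecisionCurve:
    def test_treat_all_limit_at_low_threshold(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 400)
        dca = decision_curve(rng.random(400), labels, thresholds=[0.001, 0.5])
        assert dca["treat_all"].iloc[0] == pytest.approx(labels.mean(), abs=0.01)

    def test_perfect_model_net_benefit_is_prevalence(self):
        labels = np.array([0] * 30 + [1] * 20)
        scores = labels.astype(float) * 0.98 + 0.01
        dca = decision_curve(scores, labels, thresholds=np.arange(0.05, 0.95, 0.1))
        assert np.allclose(dca["net_benefit"], 0.4)

    def test_random_scores_bounded_by_references(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 500)
        dca = decision_curve(rng.random(500), labels)
        bound = np.maximum(dca["treat_all"], 0.0) + 0.02
        assert np.all(dca["net_benefit"] <= bound)

    def test_threshold_one_rejected(self):
        with pytest.raises(ValueError):
            decision_curve(np.array([0.5]), np.array([1]), thresholds=[1.0])


class TestSVM:
    def test_separable_training_auc_one(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.3, (20, 2)), rng.normal(2, 0.3, (20, 2))])
        y = np.repeat([0, 1], 20)
        svm = train_svm(X, y, seed=0)
        auc, _ = auc_ci_delong(svm.decision_scores(X), y)
        assert auc == 1.0

    def test_null_labels_cv_auc_near_half(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 8))
        y = rng.permutation(np.repeat([0, 1], 100))
        aucs = [train_svm(X, y, seed=s).cv_auc_ for s in (0, 1, 2)]
        assert 0.4 <= float(np.mean(aucs)) <= 0.6

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + rng.normal(0, 1, 60) > 0).astype(int)
        a = train_svm(X, y, seed=7)
        b = train_svm(X, y, seed=7)
        assert np.array_equal(a.decision_scores(X), b.decision_scores(X))
        assert a.threshold_ == b.threshold_
        assert a.best_params_ == b.best_params_

    def test_youden_threshold_optimal(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        scores = np.clip(y * 0.4 + rng.random(100) * 0.6, 0, 1)
        t = youden_threshold(scores, y)
        m = threshold_metrics(scores, y, t)
        best = m["sensitivity"] + m["specificity"]
        for other in np.linspace(0.01, 0.99, 50):
            mo = threshold_metrics(scores, y, other)
            assert mo["sensitivity"] + mo["specificity"] <= best + 1e-9

    def test_degenerate_labels_raise(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((10, 2)), np.zeros(10, dtype=int))
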