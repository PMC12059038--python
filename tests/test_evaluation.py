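"""ROC/AUC, Youden thresholding, confusion metrics, DeLong, binomial CIs."""

import numpy as np
import pytest

from slicemil.evaluation import (
    ConfusionCounts,
    PredictionSet,
    apply_threshold,
    auc_ci,
    binomial_ci,
    confusion_metrics,
    delong_test,
    ensemble_predictions,
    evaluate,
    roc_auc,
    subtype_reports,
    youden_threshold,
)


def _preds(scores, labels):
    ids = tuple(f"e{i}" for i in range(len(scores)))
    return PredictionSet(ids, np.asarray(scores, float), np.asarray(labels, int))


def _random_preds(rng, n=None):
    n = n or int(rng.integers(6, 200))
    scores = np.round(rng.random(n), 2)  # rounding induces ties
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
    if labels.sum() == n:
        labels[0] = 0
    return _preds(scores, labels)


def brute_force_auc(preds):
    pos = preds.scores[preds.labels == 1]
    neg = preds.scores[preds.labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_youden(preds):
    best_j, best_t = -np.inf, None
    for t in np.unique(preds.scores):
        pred_pos = preds.scores >= t
        tpr = pred_pos[preds.labels == 1].mean()
        fpr = pred_pos[preds.labels == 0].mean()
        if tpr - fpr > best_j + 1e-12:
            best_j, best_t = tpr - fpr, t
    return best_t


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(_preds([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc(_preds([0.5] * 6, [0, 1, 0, 1, 0, 1])) == 0.5

    def test_four_pair_example(self):
        # pairs: (0.35,0.1)+, (0.35,0.4)-, (0.8,0.1)+, (0.8,0.4)+ -> 3/4
        assert roc_auc(_preds([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])) == 0.75

    def test_matches_pair_counting_on_random_instances(self, rng):
        for _ in range(100):
            preds = _random_preds(rng)
            assert roc_auc(preds) == pytest.approx(brute_force_auc(preds), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(_preds([0.3, 0.4], [1, 1]))


class TestYouden:
    def test_separated_classes_threshold_at_min_positive(self):
        preds = _preds([0.1, 0.2, 0.6, 0.9], [0, 0, 1, 1])
        assert youden_threshold(preds) == 0.6

    def test_tie_broken_by_smallest_threshold(self):
        # J is 0.5 at both 0.3 and 0.9; the smaller threshold wins
        assert youden_threshold(_preds([0.2, 0.3, 0.4, 0.9], [0, 1, 0, 1])) == 0.3

    def test_shift_invariance(self):
        preds = _preds([0.2, 0.3, 0.4, 0.9], [0, 1, 0, 1])
        shifted = _preds([1.2, 1.3, 1.4, 1.9], [0, 1, 0, 1])
        assert youden_threshold(shifted) == pytest.approx(
            youden_threshold(preds) + 1.0
        )

    def test_matches_exhaustive_scan_on_random_instances(self, rng):
        for _ in range(100):
            preds = _random_preds(rng)
            assert youden_threshold(preds) == pytest.approx(
                brute_force_youden(preds), abs=1e-12
            )

    def test_youden_optimum_is_self_consistent(self, rng):
        preds = _random_preds(rng)
        t = youden_threshold(preds)
        c = apply_threshold(preds, t)
        j_at_t = c.tp / (c.tp + c.fn) - c.fp / (c.fp + c.tn)
        best_j = max(
            (apply_threshold(preds, u).tp / max(preds.labels.sum(), 1))
            - (apply_threshold(preds, u).fp / max((1 - preds.labels).sum(), 1))
            for u in np.unique(preds.scores)
        )
        assert j_at_t == pytest.approx(best_j, abs=1e-12)


class TestConfusionMetrics:
    def test_all_metrics_from_large_validation_row(self):
        m = confusion_metrics(ConfusionCounts(tp=350, fn=88, tn=939, fp=67))
        assert m == {
            "accuracy": 0.893,
            "sensitivity": 0.799,
            "specificity": 0.933,
            "ppv": 0.839,
            "npv": 0.914,
            "f1": 0.819,
        }

    def test_all_metrics_from_external_row(self):
        m = confusion_metrics(ConfusionCounts(tp=38, fn=0, tn=25, fp=2))
        assert m["accuracy"] == 0.969
        assert m["specificity"] == 0.926
        assert m["ppv"] == 0.950
        assert m["f1"] == 0.974
        assert m["sensitivity"] == 1.0 and m["npv"] == 1.0

    def test_degenerate_counts_marked_undefined(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
        assert m["sensitivity"] is None
        assert m["specificity"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fn=0, tn=0, fp=0)


class TestApplyThreshold:
    def test_threshold_below_min_marks_everything_positive(self):
        c = apply_threshold(_preds([0.3, 0.6], [0, 1]), 0.0)
        assert (c.fn, c.tn) == (0, 0) and c.total == 2

    def test_threshold_above_max_marks_everything_negative(self):
        c = apply_threshold(_preds([0.3, 0.6], [0, 1]), 0.99)
        assert (c.tp, c.fp) == (0, 0)

    def test_counts_sum_to_cohort_size(self, rng):
        preds = _random_preds(rng)
        c = apply_threshold(preds, 0.5)
        assert c.total == len(preds.scores)


class TestDeLong:
    def test_identical_predictions_give_p_one(self):
        preds = _preds([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        auc_a, auc_b, z, p = delong_test(preds, preds)
        assert auc_a == auc_b == 0.75
        assert p == 1.0

    def test_midrank_auc_equals_pair_counting(self, rng):
        for _ in range(50):
            preds = _random_preds(rng)
            auc_a, _, _, _ = delong_test(preds, preds)
            assert auc_a == pytest.approx(brute_force_auc(preds), abs=1e-12)

    def test_symmetry(self, rng):
        labels = np.array([0, 1] * 15)
        a = _preds(rng.random(30), labels)
        b = _preds(rng.random(30), labels)
        auc_a, auc_b, z_ab, p_ab = delong_test(a, b)
        auc_b2, auc_a2, z_ba, p_ba = delong_test(b, a)
        assert (auc_a, auc_b) == (auc_a2, auc_b2)
        assert z_ab == pytest.approx(-z_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_null_calibration_rejection_rate(self):
        """Under the null (independent random scores, same labels) the test
        rejects at close to its nominal 5% level."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 2000
        ids = tuple(map(str, range(60)))
        for _ in range(n_sim):
            labels = np.zeros(60, dtype=int)
            labels[rng.choice(60, 20, replace=False)] = 1
            a = PredictionSet(ids, rng.random(60), labels)
            b = PredictionSet(ids, rng.random(60), labels)
            _, _, _, p = delong_test(a, b)
            rejections += p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.01)

    def test_mismatched_exams_rejected(self, rng):
        a = _preds([0.1, 0.9], [0, 1])
        b = PredictionSet(("x", "y"), np.array([0.1, 0.9]), np.array([0, 1]))
        with pytest.raises(ValueError):
            delong_test(a, b)


class TestAucCI:
    def test_perfect_separation_gives_degenerate_interval(self):
        assert auc_ci(_preds([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])) == (1.0, 1.0)

    def test_interval_contains_point_estimate(self, rng):
        preds = _random_preds(rng)
        lo, hi = auc_ci(preds)
        assert lo <= roc_auc(preds) <= hi

    def test_width_shrinks_with_sample_size(self, rng):
        def width(n):
            labels = np.tile([0, 1], n // 2)
            scores = np.clip(labels * 0.3 + rng.normal(0.4, 0.25, n), 0, 1)
            lo, hi = auc_ci(_preds(scores, labels))
            return hi - lo

        w_small = np.mean([width(40) for _ in range(10)])
        w_large = np.mean([width(360) for _ in range(10)])
        assert w_large < w_small / 2  # ~1/sqrt(9) = 1/3 expected


class TestBinomialCI:
    def test_extremes(self):
        assert binomial_ci(10, 10)[1] == pytest.approx(1.0)
        assert binomial_ci(0, 10)[0] == pytest.approx(0.0)

    def test_wilson_closed_form_example(self):
        lo, hi = binomial_ci(8, 10)
        assert (lo, hi) == (pytest.approx(0.4902, abs=2e-4),
                            pytest.approx(0.9433, abs=2e-4))

    def test_exact_interval_is_wider(self):
        w_lo, w_hi = binomial_ci(8, 10)
        e_lo, e_hi = binomial_ci(8, 10, method="exact")
        assert e_hi - e_lo > w_hi - w_lo

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(11, 10)


class TestEnsembleAndReports:
    def test_mean_of_two_folds(self):
        a = _preds([0.2, 0.6], [0, 1])
        b = _preds([0.4, 0.8], [0, 1])
        merged = ensemble_predictions([a, b])
        np.testing.assert_allclose(merged.scores, [0.3, 0.7])

    def test_fold_order_invariance(self, rng):
        labels = np.array([0, 1, 0, 1])
        folds = [_preds(rng.random(4), labels) for _ in range(5)]
        fwd = ensemble_predictions(folds)
        rev = ensemble_predictions(folds[::-1])
        np.testing.assert_allclose(fwd.scores, rev.scores)

    def test_mismatched_exam_sets_rejected(self):
        a = _preds([0.2, 0.6], [0, 1])
        b = PredictionSet(("x", "y"), np.array([0.4, 0.8]), np.array([0, 1]))
        with pytest.raises(ValueError):
            ensemble_predictions([a, b])

    def test_evaluate_report_is_internally_consistent(self, rng):
        preds = _random_preds(rng, n=80)
        report = evaluate(preds)
        assert report.metrics == confusion_metrics(report.counts)
        assert report.auc_ci[0] <= report.auc <= report.auc_ci[1]
        assert report.counts.total == 80

    def test_subtype_subsets(self):
        scores = [0.1, 0.2, 0.3, 0.8, 0.7, 0.9, 0.6, 0.5]
        labels = [0, 0, 0, 1, 1, 1, 1, 1]
        ids = tuple(f"e{i}" for i in range(8))
        preds = PredictionSet(ids, np.array(scores), np.array(labels))
        subtypes = {
            "e0": "negative", "e1": "negative", "e2": "negative",
            "e3": "central", "e4": "central",
            "e5": "peripheral", "e6": "peripheral", "e7": "peripheral",
        }
        reports = subtype_reports(subtypes, preds, threshold=0.5)
        assert reports["central"].counts.total == 5  # 3 neg + 2 central
        assert reports["peripheral"].counts.total == 6

    def test_missing_subtype_annotation_rejected(self):
        preds = _preds([0.2, 0.8], [0, 1])
        with pytest.raises(ValueError, match="subtype"):
            subtype_reports({"e0": "negative"}, preds)

    def test_cohort_without_central_positives_reports_unavailable(self):
        preds = _preds([0.2, 0.8, 0.9], [0, 1, 1])
        subtypes = {"e0": "negative", "e1": "peripheral", "e2": "peripheral"}
        reports = subtype_reports(subtypes, preds, threshold=0.5)
        assert reports["central"] is None
        assert reports["peripheral"] is not None
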