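"""Evaluation metrics against independent oracles and the published tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import AB_CM, GB_CM, RF_CM, random_confusion
from noshowpricing.metrics import (
    ConfusionMatrix,
    calibration_curve,
    classification_accuracy,
    column_rates,
    confusion_from_labels,
    evaluate_predictions,
    f1,
    mcc,
    precision,
    recall,
    roc_auc,
)


def naive_metrics(cm: ConfusionMatrix) -> dict:
    """Brute-force recomputation of every metric with plain Python loops."""
    cells = [("show", "show", cm.tp), ("no", "no", cm.tn), ("no", "show", cm.fp), ("show", "no", cm.fn)]
    actual, predicted = [], []
    for a, p, count in cells:
        actual += [a] * count
        predicted += [p] * count
    n = len(actual)
    correct = sum(1 for a, p in zip(actual, predicted) if a == p)

    def prf(cls):
        tp = sum(1 for a, p in zip(actual, predicted) if a == cls and p == cls)
        pred_cls = sum(1 for p in predicted if p == cls)
        act_cls = sum(1 for a in actual if a == cls)
        prec = tp / pred_cls if pred_cls else 0.0
        rec = tp / act_cls if act_cls else 0.0
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return prec, rec, f, act_cls

    pp, rp, fp_, wp = prf("show")
    pn, rn, fn_, wn = prf("no")
    s1 = sum(1 for a, p in zip(actual, predicted) if p == "show")
    s2 = sum(1 for a in actual if a == "show")
    s3 = sum(1 for a in actual if a == "no")
    s4 = sum(1 for p in predicted if p == "no")
    denom = math.sqrt(s1 * s2 * s3 * s4)
    mcc_val = (cm.tp * cm.tn - cm.fp * cm.fn) / denom if denom else 0.0
    return {
        "ca": correct / n,
        "precision": (wp * pp + wn * pn) / n,
        "recall": (wp * rp + wn * rn) / n,
        "f1": (wp * fp_ + wn * fn_) / n,
        "mcc": mcc_val,
    }


class TestConfusionFromLabels:
    def test_perfect_agreement(self):
        cm = confusion_from_labels([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_reconstructed_rf_test_predictions(self):
        actual = [1] * 121 + [0] * 93
        predicted = [1] * 116 + [0] * 5 + [0] * 90 + [1] * 3
        cm = confusion_from_labels(actual, predicted)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (116, 90, 3, 5)

    def test_random_vectors_match_naive_tally(self, rng):
        a = rng.integers(0, 2, 300)
        p = rng.integers(0, 2, 300)
        cm = confusion_from_labels(a, p)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for ai, pi in zip(a, p):
            key = {(1, 1): "tp", (0, 0): "tn", (0, 1): "fp", (1, 0): "fn"}[(ai, pi)]
            tally[key] += 1
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tally["tp"], tally["tn"], tally["fp"], tally["fn"])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            confusion_from_labels([1, 0], [1])


# Published test-phase rows: (cm, AUC-less metric values to 3 decimals).
PUBLISHED = [
    pytest.param(RF_CM, dict(ca=0.963, f1=0.963, precision=0.963, recall=0.963, mcc=0.924), id="RF"),
    pytest.param(GB_CM, dict(ca=0.967, f1=0.967, precision=0.967, recall=0.967, mcc=0.934), id="GB"),
    pytest.param(AB_CM, dict(ca=0.939, f1=0.939, precision=0.939, recall=0.939, mcc=0.877), id="AB"),
]


class TestPublishedValues:
    @pytest.mark.parametrize("cm,expected", PUBLISHED)
    def test_weighted_metrics_reproduce_performance_table(self, cm, expected):
        assert round(classification_accuracy(cm), 3) == expected["ca"]
        assert round(precision(cm).weighted, 3) == expected["precision"]
        assert round(recall(cm).weighted, 3) == expected["recall"]
        assert round(f1(cm).weighted, 3) == expected["f1"]
        assert round(mcc(cm), 3) == expected["mcc"]

    def test_column_rates_reproduce_percentages(self):
        assert round(100 * column_rates(RF_CM).alpha, 1) == 94.7
        assert round(100 * column_rates(GB_CM).alpha, 1) == 95.7
        assert round(100 * column_rates(RF_CM).beta, 1) == 97.5
        assert round(100 * column_rates(AB_CM).beta, 1) == 95.0


class TestEdgeCases:
    def test_perfect_matrix(self):
        cm = ConfusionMatrix(tp=10, tn=10, fp=0, fn=0)
        assert classification_accuracy(cm) == 1.0
        assert f1(cm).weighted == 1.0
        assert mcc(cm) == 1.0
        rates = column_rates(cm)
        assert rates.alpha == 1.0 and rates.beta == 1.0

    def test_single_cell_matrix(self):
        cm = ConfusionMatrix(tp=1, tn=0, fp=0, fn=0)
        assert precision(cm).positive == 1.0
        assert mcc(cm) == 0.0  # zero margin -> 0 with warning

    def test_zero_denominator_yields_zero_not_error(self):
        cm = ConfusionMatrix(tp=0, tn=5, fp=0, fn=5)
        assert precision(cm).positive == 0.0
        assert f1(cm).positive == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, tn=1, fp=0, fn=0)


class TestOracleEquivalence:
    def test_thousand_random_matrices_match_naive_loop(self, rng):
        for _ in range(1000):
            cm = random_confusion(rng)
            oracle = naive_metrics(cm)
            assert classification_accuracy(cm) == pytest.approx(oracle["ca"], abs=1e-12)
            assert precision(cm).weighted == pytest.approx(oracle["precision"], abs=1e-12)
            assert recall(cm).weighted == pytest.approx(oracle["recall"], abs=1e-12)
            assert f1(cm).weighted == pytest.approx(oracle["f1"], abs=1e-12)
            assert mcc(cm) == pytest.approx(oracle["mcc"], abs=1e-12)

    def test_against_scikit_learn(self, rng):
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            matthews_corrcoef,
            precision_score,
            recall_score,
        )

        for _ in range(25):
            a = rng.integers(0, 2, 200)
            p = rng.integers(0, 2, 200)
            if len(set(a)) < 2 or len(set(p)) < 2:
                continue
            cm = confusion_from_labels(a, p)
            assert classification_accuracy(cm) == pytest.approx(accuracy_score(a, p))
            assert precision(cm).weighted == pytest.approx(precision_score(a, p, average="weighted"))
            assert recall(cm).weighted == pytest.approx(recall_score(a, p, average="weighted"))
            assert f1(cm).weighted == pytest.approx(f1_score(a, p, average="weighted"))
            assert mcc(cm) == pytest.approx(matthews_corrcoef(a, p))

    @given(
        tp=st.integers(0, 200),
        tn=st.integers(0, 200),
        fp=st.integers(0, 200),
        fn=st.integers(0, 200),
    )
    @settings(max_examples=200, derandomize=True)
    def test_metric_ranges(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        cm = ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
        assert 0.0 <= classification_accuracy(cm) <= 1.0
        assert 0.0 <= f1(cm).weighted <= 1.0
        assert -1.0 <= mcc(cm) <= 1.0

    def test_balanced_symmetric_matrix_metrics_coincide(self):
        cm = ConfusionMatrix(tp=40, tn=40, fp=10, fn=10)
        ca = classification_accuracy(cm)
        assert precision(cm).weighted == pytest.approx(ca)
        assert recall(cm).weighted == pytest.approx(ca)
        assert f1(cm).weighted == pytest.approx(ca)


class TestRocAuc:
    def test_perfect_separation(self):
        curve, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0

    def test_independent_scores_give_half(self, rng):
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_equals_mann_whitney_rank_statistic(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            scores = rng.choice(np.linspace(0, 1, 20), size=300)  # heavy ties
            labels = rng.integers(0, 2, 300)
            if labels.sum() in (0, 300):
                continue
            _, auc = roc_auc(scores, labels)
            n_pos, n_neg = labels.sum(), (1 - labels).sum()
            u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
            assert auc == pytest.approx(u / (n_pos * n_neg), abs=1e-10)

    def test_equals_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(500)
        labels = (scores + rng.normal(0, 0.3, 500) > 0.5).astype(int)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(400)
        labels = rng.integers(0, 2, 400)
        _, auc1 = roc_auc(scores, labels)
        _, auc2 = roc_auc(np.exp(3 * scores) - 0.5, labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_curve_monotone(self, rng):
        scores = rng.random(200).round(1)
        labels = rng.integers(0, 2, 200)
        curve, _ = roc_auc(scores, labels)
        assert (np.diff(curve.fpr) >= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.9], [1, 1])


class TestCalibrationCurve:
    def test_constant_scores_single_point(self):
        curve = calibration_curve([0.5] * 100, [1, 0] * 50, n_bins=10)
        assert len(curve.mean_score) == 1
        assert curve.mean_score[0] == pytest.approx(0.5)
        assert curve.frac_positive[0] == pytest.approx(0.5)

    def test_bin_counts_partition_sample(self, rng):
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        curve = calibration_curve(scores, labels, n_bins=10)
        assert curve.counts.sum() == 500

    def test_calibrated_by_construction(self, rng):
        # labels drawn with probability equal to the score: curve hugs diagonal
        scores = rng.random(50_000)
        labels = (rng.random(50_000) < scores).astype(int)
        curve = calibration_curve(scores, labels, n_bins=10)
        assert np.max(np.abs(curve.frac_positive - curve.mean_score)) <= 0.05

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            calibration_curve([0.5], [1], n_bins=1)


class TestEvaluatePredictions:
    def test_full_report(self, rng):
        actual = rng.integers(0, 2, 300)
        scores = np.clip(actual * 0.6 + rng.random(300) * 0.4, 0, 1)
        predicted = (scores >= 0.5).astype(int)
        report = evaluate_predictions(actual, predicted, scores)
        cm = confusion_from_labels(actual, predicted)
        assert report.ca == pytest.approx(classification_accuracy(cm))
        assert report.mcc == pytest.approx(mcc(cm))
        assert 0.5 < report.auc <= 1.0

    def test_auc_nan_without_scores(self):
        report = evaluate_predictions([1, 0, 1, 0], [1, 0, 1, 1])
        assert math.isnan(report.auc)
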