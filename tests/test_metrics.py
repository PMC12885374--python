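import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from fleaselect.metrics import (
    ConfusionCounts,
    compute_metrics,
    confusion_counts,
    macro_metrics,
    mean_confidence_interval,
    one_sample_t_test,
    per_class_accuracy,
    reports_table,
    t_tail_p_value,
)


class TestConfusionCounts:
    def test_perfect_agreement(self):
        c = confusion_counts([1, 1, 0, 0], [1, 1, 0, 0], 1)
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_complement_prediction(self):
        c = confusion_counts([1, 1, 0, 0], [0, 0, 1, 1], 1)
        assert c.TP == 0 and c.TN == 0
        assert c.FP == 2 and c.FN == 2

    def test_matches_per_element_loop(self, rng):
        y_true = rng.integers(0, 3, size=50)
        y_pred = rng.integers(0, 3, size=50)
        c = confusion_counts(y_true, y_pred, 1)
        tp = tn = fp = fn = 0
        for t, p in zip(y_true, y_pred):
            if t == 1 and p == 1:
                tp += 1
            elif t != 1 and p != 1:
                tn += 1
            elif t != 1 and p == 1:
                fp += 1
            else:
                fn += 1
        assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)
        assert c.total == 50

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts([1, 0], [1], 1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestComputeMetrics:
    def test_hand_computed_table(self):
        rep = compute_metrics(ConfusionCounts(TP=50, TN=40, FP=5, FN=5))
        assert rep.accuracy == pytest.approx(0.90)
        assert rep.error == pytest.approx(0.10)
        assert rep.mcc == pytest.approx(1975 / 2475)
        assert rep.recall == pytest.approx(50 / 55)
        assert rep.specificity == pytest.approx(40 / 45)
        assert rep.precision == pytest.approx(50 / 55)
        assert rep.fpr == pytest.approx(5 / 45)
        p, r = 50 / 55, 50 / 55
        assert rep.f1 == pytest.approx(2 * p * r / (p + r))

    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionCounts(TP=10, TN=10, FP=0, FN=0))
        assert rep.accuracy == 1.0 and rep.error == 0.0
        assert rep.mcc == pytest.approx(1.0)
        assert rep.kappa == pytest.approx(1.0)
        assert rep.fpr == 0.0

    def test_all_one_class_balanced_truth_kappa_zero(self):
        # Predict everything positive on balanced truth: Po = Pe = 0.5.
        rep = compute_metrics(ConfusionCounts(TP=10, TN=0, FP=10, FN=0))
        assert rep.kappa == pytest.approx(0.0)

    def test_undefined_denominator_is_nan_not_exception(self):
        rep = compute_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert np.isnan(rep.recall)  # TP+FN == 0
        assert np.isnan(rep.precision)  # TP+FP == 0

    def test_accuracy_plus_error_exactly_one(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + tn + fp + fn == 0:
                continue
            rep = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert rep.accuracy + rep.error == 1.0

    def test_mcc_symmetry_under_role_swap(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = (int(x) for x in rng.integers(1, 30, size=4))
            a = compute_metrics(ConfusionCounts(tp, tn, fp, fn)).mcc
            b = compute_metrics(ConfusionCounts(tn, tp, fn, fp)).mcc
            assert abs(a) == pytest.approx(abs(b))

    def test_kappa_equals_mcc_on_symmetric_balanced_tables(self):
        for tp, err in ((40, 10), (25, 5), (9, 3)):
            rep = compute_metrics(ConfusionCounts(TP=tp, TN=tp, FP=err, FN=err))
            assert rep.kappa == pytest.approx(rep.mcc)

    @given(st.integers(min_value=0, max_value=50), st.integers(min_value=0, max_value=50),
           st.integers(min_value=0, max_value=50), st.integers(min_value=0, max_value=50))
    @settings(max_examples=50, deadline=None)
    def test_mcc_bounded(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        rep = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        if not np.isnan(rep.mcc):
            assert -1.0 - 1e-12 <= rep.mcc <= 1.0 + 1e-12
        if not np.isnan(rep.kappa):
            assert rep.kappa <= 1.0 + 1e-12


class TestMacroMetrics:
    def test_perfect_eight_class(self, rng):
        y = rng.integers(0, 8, size=64)
        rep = macro_metrics(y, y.copy())
        for attr in ("accuracy", "recall", "specificity", "precision", "f1",
                     "mcc", "kappa"):
            assert getattr(rep, attr) == pytest.approx(1.0)
        assert rep.error == 0.0 and rep.fpr == 0.0

    def test_macro_recall_is_balanced_accuracy_two_classes(self, rng):
        y_true = np.repeat([0, 1], 20)
        y_pred = rng.integers(0, 2, size=40)
        rep = macro_metrics(y_true, y_pred)
        r0 = np.mean(y_pred[y_true == 0] == 0)
        r1 = np.mean(y_pred[y_true == 1] == 1)
        assert rep.recall == pytest.approx((r0 + r1) / 2)

    def test_permutation_invariant(self, rng):
        y_true = rng.integers(0, 4, size=30)
        y_pred = rng.integers(0, 4, size=30)
        perm = rng.permutation(30)
        a = macro_metrics(y_true, y_pred)
        b = macro_metrics(y_true[perm], y_pred[perm])
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.mcc == pytest.approx(b.mcc)

    def test_absent_class_excluded_with_warning(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 2, 1, 1])
        with pytest.warns(RuntimeWarning, match="absent"):
            rep = macro_metrics(y_true, y_pred, classes=[0, 1, 2])
        assert len(rep.per_class) == 2

    def test_per_class_accuracy_values(self):
        y_true = np.array([0, 0, 1, 1, 1])
        y_pred = np.array([0, 1, 1, 1, 0])
        acc = per_class_accuracy(y_true, y_pred)
        assert acc[0] == pytest.approx(0.5)
        assert acc[1] == pytest.approx(2 / 3)


class TestTTest:
    def test_printed_p_value(self):
        assert round(t_tail_p_value(0.712, 5), 2) == 0.51

    def test_symmetric_values_give_t_zero_p_one(self):
        t, df, p = one_sample_t_test([4.0, 6.0, 5.5, 4.5], 5.0)
        assert t == pytest.approx(0.0)
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_p_matches_quadrature_of_t_density(self):
        t_stat, df = 0.712, 5
        pdf = lambda x: stats.t.pdf(x, df)
        central, _ = integrate.quad(pdf, -abs(t_stat), abs(t_stat))
        assert t_tail_p_value(t_stat, df) == pytest.approx(1.0 - central, abs=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t_test([2.0, 2.0, 2.0], 1.0)

    def test_t_statistic_closed_form(self, rng):
        vals = rng.standard_normal(6) + 0.99
        t, df, p = one_sample_t_test(vals, 0.95)
        sd = vals.std(ddof=1)
        assert t == pytest.approx((vals.mean() - 0.95) / (sd / np.sqrt(6)))
        assert df == 5


class TestConfidenceInterval:
    def test_constant_values_zero_width(self):
        lo, hi = mean_confidence_interval([0.5, 0.5, 0.5])
        assert lo == hi == 0.5

    def test_wider_at_higher_level(self, rng):
        vals = rng.standard_normal(10)
        lo95, hi95 = mean_confidence_interval(vals, 0.95)
        lo99, hi99 = mean_confidence_interval(vals, 0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_width_closed_form_n6(self, rng):
        vals = 0.991 + 0.004 * rng.standard_normal(6)
        lo, hi = mean_confidence_interval(vals, 0.95)
        sd = vals.std(ddof=1)
        expected = 2 * stats.t.ppf(0.975, 5) * sd / np.sqrt(6)
        assert hi - lo == pytest.approx(expected)

    def test_contains_mean(self, rng):
        vals = rng.standard_normal(8)
        lo, hi = mean_confidence_interval(vals)
        assert lo <= vals.mean() <= hi


def test_reports_table_column_order(rng):
    y = rng.integers(0, 3, size=30)
    rep = macro_metrics(y, y.copy(), classifier_name="tree")
    df = reports_table({"tree": rep}, training_time={"tree": 1.5})
    assert list(df.columns) == [
        "Accuracy", "Error", "Recall", "Specificity", "Precision",
        "False Positive Rate", "F1_Score", "MCC", "Kappa", "Training Time(Sec)",
    ]
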