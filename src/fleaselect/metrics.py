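"""Confusion-count metric suite, one-sample t-test and mean confidence interval.

Binary metrics follow the standard confusion-table formulas:

- accuracy = (TP+TN)/n, error = 1 - accuracy
- recall (sensitivity) = TP/(TP+FN), specificity = TN/(TN+FP)
- precision = TP/(TP+FP), false positive rate = FP/(FP+TN)
- F1 = 2PR/(P+R)
- MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
- kappa = (Po - Pe)/(1 - Pe), Po = accuracy,
  Pe = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / n^2

Undefined denominators produce NaN (printed as "NA" in CSV), never an
exception. Multiclass reports macro-average one-vs-rest metrics; accuracy is
computed globally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

#: Column order used by the tabular reports.
REPORT_COLUMNS = [
    "Accuracy",
    "Error",
    "Recall",
    "Specificity",
    "Precision",
    "False Positive Rate",
    "F1_Score",
    "MCC",
    "Kappa",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    accuracy: float
    error: float
    recall: float
    specificity: float
    precision: float
    fpr: float
    f1: float
    mcc: float
    kappa: float
    classifier_name: str = ""
    per_class: dict | None = field(default=None, repr=False)

    def as_row(self) -> dict:
        return {
            "Accuracy": self.accuracy,
            "Error": self.error,
            "Recall": self.recall,
            "Specificity": self.specificity,
            "Precision": self.precision,
            "False Positive Rate": self.fpr,
            "F1_Score": self.f1,
            "MCC": self.mcc,
            "Kappa": self.kappa,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def confusion_counts(y_true, y_pred, positive_class) -> ConfusionCounts:
    """One-vs-rest binarization of two label vectors against ``positive_class``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length non-empty vectors")
    t = y_true == positive_class
    p = y_pred == positive_class
    return ConfusionCounts(
        TP=int(np.sum(t & p)),
        TN=int(np.sum(~t & ~p)),
        FP=int(np.sum(~t & p)),
        FN=int(np.sum(t & ~p)),
    )


def compute_metrics(c: ConfusionCounts, classifier_name: str = "") -> MetricsReport:
    """Evaluate every binary formula on one confusion table."""
    n = c.total
    if n == 0:
        raise ValueError("confusion counts sum to zero")
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    accuracy = (tp + tn) / n
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    precision = _safe_div(tp, tp + fp)
    fpr = _safe_div(fp, fp + tn)
    f1 = _safe_div(2.0 * precision * recall, precision + recall)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    po = accuracy
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = _safe_div(po - pe, 1.0 - pe)
    return MetricsReport(
        accuracy=accuracy,
        error=1.0 - accuracy,
        recall=recall,
        specificity=specificity,
        precision=precision,
        fpr=fpr,
        f1=f1,
        mcc=mcc,
        kappa=kappa,
        classifier_name=classifier_name,
    )


def macro_metrics(y_true, y_pred, classes=None, classifier_name: str = "") -> MetricsReport:
    """Macro (unweighted) mean of one-vs-rest metrics; global accuracy.

    Classes absent from ``y_true`` are excluded from the macro mean with a
    warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    if classes.size < 2:
        raise ValueError("macro metrics need at least two classes")
    present = [c for c in classes if np.any(y_true == c)]
    absent = [c for c in classes if c not in present]
    if absent:
        warnings.warn(
            f"classes {absent} absent from y_true; excluded from macro mean",
            RuntimeWarning,
            stacklevel=2,
        )
    per_class = {c: compute_metrics(confusion_counts(y_true, y_pred, c)) for c in present}
    accuracy = float(np.mean(y_true == y_pred))

    def mean_of(attr: str) -> float:
        return float(np.mean([getattr(per_class[c], attr) for c in present]))

    return MetricsReport(
        accuracy=accuracy,
        error=1.0 - accuracy,
        recall=mean_of("recall"),
        specificity=mean_of("specificity"),
        precision=mean_of("precision"),
        fpr=mean_of("fpr"),
        f1=mean_of("f1"),
        mcc=mean_of("mcc"),
        kappa=mean_of("kappa"),
        classifier_name=classifier_name,
        per_class=per_class,
    )


def per_class_accuracy(y_true, y_pred) -> dict:
    """Recall per class (fraction of class-c samples predicted as c)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return {
        c: float(np.mean(y_pred[y_true == c] == c)) for c in np.unique(y_true)
    }


def t_tail_p_value(t_stat: float, df: int) -> float:
    """Two-tailed p-value of a Student t statistic."""
    if df < 1:
        raise ValueError("df must be at least 1")
    return float(2.0 * stats.t.sf(abs(t_stat), df))


def one_sample_t_test(values, mu0: float) -> tuple[float, int, float]:
    """Classical one-sample t-test: (t, df, two-tailed p)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("t-test needs at least two values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("t-test undefined for zero-variance values")
    n = values.size
    t_stat = (values.mean() - mu0) / (sd / math.sqrt(n))
    df = n - 1
    return float(t_stat), df, t_tail_p_value(t_stat, df)


def mean_confidence_interval(values, level: float = 0.95) -> tuple[float, float]:
    """mean +/- t_{df,(1+level)/2} * sd / sqrt(n); degenerate at zero variance."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("confidence interval needs at least two values")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return float(mean), float(mean)
    half = stats.t.ppf((1.0 + level) / 2.0, values.size - 1) * sd / math.sqrt(values.size)
    return float(mean - half), float(mean + half)


def reports_table(reports: dict[str, MetricsReport], training_time: dict | None = None) -> pd.DataFrame:
    """Rows = classifiers, columns in the standard report order."""
    rows = {}
    for name, rep in reports.items():
        row = rep.as_row()
        if training_time is not None:
            row["Training Time(Sec)"] = training_time.get(name, float("nan"))
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
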