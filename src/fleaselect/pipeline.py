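"""Before/after-optimization experiment: classifier bank, k-fold evaluation,
three-arm ablation (LASSO-only, FOA-only, hybrid) and report writing.

The classifier bank mirrors the six reference models: a decision tree and
five multilayer perceptrons with tanh hidden activations and layouts
(10), (20), (50), (10, 10), (10, 10, 10).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.tree import DecisionTreeClassifier

from fleaselect.dataset import FeatureDataset
from fleaselect.dissimilarity import dissimilarity_report
from fleaselect.foa import FOAConfig, run_foa
from fleaselect.lasso import fit_lasso_multiclass, one_hot
from fleaselect.metrics import (
    MetricsReport,
    macro_metrics,
    per_class_accuracy,
    reports_table,
)
from fleaselect.synthetic import train_validation_split

logger = logging.getLogger("fleaselect")

CLASSIFIER_LAYOUTS: dict[str, tuple[int, ...] | None] = {
    "tree": None,
    "narrow_nn": (10,),
    "medium_nn": (20,),
    "wide_nn": (50,),
    "bilayer_nn": (10, 10),
    "trilayer_nn": (10, 10, 10),
}


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    hidden_layout: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_LAYOUTS:
            raise ValueError(f"unknown classifier: {self.name}")
        expected = CLASSIFIER_LAYOUTS[self.name]
        layout = self.hidden_layout if self.hidden_layout is not None else expected
        if layout != expected:
            raise ValueError(f"{self.name} must use hidden layout {expected}")
        object.__setattr__(self, "hidden_layout", expected)


@dataclass
class ExperimentConfig:
    n_folds: int = 10
    train_fraction: float = 0.7
    foa: FOAConfig = field(default_factory=FOAConfig)
    seed: int = 0
    classifiers: tuple[str, ...] = tuple(CLASSIFIER_LAYOUTS)
    classifier_max_iter: int = 300

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


def make_classifier(spec: ClassifierSpec, seed: int, max_iter: int = 300):
    if spec.name == "tree":
        return DecisionTreeClassifier(random_state=seed)
    return MLPClassifier(
        hidden_layer_sizes=spec.hidden_layout,
        activation="tanh",
        solver="lbfgs",
        max_iter=max_iter,
        random_state=seed,
    )


def evaluate_classifiers(
    ds: FeatureDataset,
    mask: np.ndarray | None,
    cfg: ExperimentConfig,
) -> tuple[dict[str, MetricsReport], dict[str, float], dict[str, np.ndarray]]:
    """Stratified k-fold cross-validation of the classifier bank.

    Returns (macro report per classifier, total fit time per classifier,
    out-of-fold predictions per classifier).
    """
    X = ds.features if mask is None else ds.features[:, np.asarray(mask, dtype=bool)]
    y = ds.labels
    smallest = min(int((y == c).sum()) for c in ds.classes)
    if cfg.n_folds > smallest:
        raise ValueError(
            f"n_folds={cfg.n_folds} exceeds the smallest class size ({smallest})"
        )
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    reports: dict[str, MetricsReport] = {}
    times: dict[str, float] = {}
    predictions: dict[str, np.ndarray] = {}
    t0 = time.perf_counter()
    for name in cfg.classifiers:
        spec = ClassifierSpec(name)
        oof = np.empty_like(y)
        elapsed = 0.0
        for train_idx, test_idx in skf.split(X, y):
            clf = make_classifier(spec, cfg.seed, cfg.classifier_max_iter)
            tic = time.perf_counter()
            clf.fit(X[train_idx], y[train_idx])
            elapsed += time.perf_counter() - tic
            oof[test_idx] = clf.predict(X[test_idx])
        reports[name] = macro_metrics(y, oof, classes=ds.classes, classifier_name=name)
        times[name] = elapsed
        predictions[name] = oof
    logger.info(
        "evaluate_classifiers: input %s -> %d reports in %.2fs",
        X.shape,
        len(reports),
        time.perf_counter() - t0,
    )
    return reports, times, predictions


def percent_improvement(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    """(after - before)/before * 100, elementwise on shared numeric cells."""
    common_cols = [c for c in before.columns if c in after.columns]
    b = before[common_cols]
    a = after[common_cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / b * 100.0
    return out


@dataclass
class PipelineResult:
    before: pd.DataFrame
    after: pd.DataFrame
    improvement: pd.DataFrame
    n_selected: int
    mask: np.ndarray
    dissimilarity: pd.DataFrame

    def summary_dict(self) -> dict:
        return {
            "n_selected": self.n_selected,
            "mask": self.mask.astype(int).tolist(),
            "before": self.before.to_dict(),
            "after": self.after.to_dict(),
            "improvement": self.improvement.to_dict(),
            "dissimilarity": self.dissimilarity.to_dict(orient="list"),
        }


def run_pipeline(
    cfg: ExperimentConfig,
    ds: FeatureDataset,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """evaluate (before) -> run_foa -> evaluate (after) -> reports."""
    t0 = time.perf_counter()
    logger.info("pipeline: dataset %s, %d classes", ds.features.shape, ds.n_classes)

    before_reports, before_times, before_preds = evaluate_classifiers(ds, None, cfg)
    before_df = reports_table(before_reports, before_times)

    foa_cfg = cfg.foa
    selection = run_foa(ds, foa_cfg)
    logger.info(
        "pipeline: FOA selected %d / %d features", selection.n_selected, ds.n_features
    )

    after_reports, after_times, after_preds = evaluate_classifiers(ds, selection.mask, cfg)
    after_df = reports_table(after_reports, after_times)

    # Timing columns are hardware-dependent; improvements cover metrics only.
    metric_cols = [c for c in before_df.columns if c != "Training Time(Sec)"]
    improvement = percent_improvement(before_df[metric_cols], after_df[metric_cols])

    best_name = after_df["Accuracy"].idxmax()
    acc = per_class_accuracy(ds.labels, after_preds[best_name])
    dissim = dissimilarity_report(ds, per_class_accuracy=acc, mask=selection.mask)

    result = PipelineResult(
        before=before_df,
        after=after_df,
        improvement=improvement,
        n_selected=selection.n_selected,
        mask=selection.mask,
        dissimilarity=dissim,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        before_df.to_csv(out_dir / "metrics_before.csv", na_rep="NA")
        after_df.to_csv(out_dir / "metrics_after.csv", na_rep="NA")
        improvement.to_csv(out_dir / "improvement_percent.csv", na_rep="NA")
        dissim.to_csv(out_dir / "dissimilarity.csv", index=False, na_rep="NA")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(result.summary_dict(), fh, indent=2)
    logger.info("pipeline: done in %.2fs", time.perf_counter() - t0)
    return result


def _downstream_regression(
    ds_train: FeatureDataset,
    ds_val: FeatureDataset,
    mask: np.ndarray,
    seed: int,
) -> tuple[int, float, float, float]:
    """Small fixed regressor on one-hot targets: (epochs, time, mse, gradient)."""
    mask = np.asarray(mask, dtype=bool)
    classes = np.unique(np.concatenate([ds_train.labels, ds_val.labels]))
    reg = MLPRegressor(
        hidden_layer_sizes=(10,),
        solver="adam",
        max_iter=300,
        random_state=seed,
    )
    tic = time.perf_counter()
    reg.fit(ds_train.features[:, mask], one_hot(ds_train.labels, classes))
    elapsed = time.perf_counter() - tic
    pred = reg.predict(ds_val.features[:, mask])
    mse = float(np.mean((pred - one_hot(ds_val.labels, classes)) ** 2))
    curve = getattr(reg, "loss_curve_", [])
    gradient = float(abs(curve[-1] - curve[-2])) if len(curve) >= 2 else float("nan")
    return int(reg.n_iter_), elapsed, mse, gradient


def run_ablation(ds: FeatureDataset, cfg: ExperimentConfig) -> pd.DataFrame:
    """Three selection arms scored by a fixed downstream regressor.

    Arm 1: plain LASSO mask. Arm 2: FOA importance threshold without the
    final LASSO. Arm 3: the full hybrid. All arms share the same seed and
    train/validation split.
    """
    ds_train, ds_val = train_validation_split(ds, cfg.train_fraction, cfg.seed)

    lasso_mask, _, _ = fit_lasso_multiclass(
        ds_train.features, ds_train.labels, cfg.foa.alpha
    )
    selection = run_foa(ds_train, cfg.foa)

    arms = {
        "LASSO": lasso_mask,
        "FOA": selection.candidate_mask,
        "FOA+LASSO": selection.mask,
    }
    rows = []
    for name, mask in arms.items():
        if not mask.any():  # degenerate arm: keep everything rather than crash
            mask = np.ones(ds.n_features, dtype=bool)
        epochs, elapsed, mse, gradient = _downstream_regression(
            ds_train, ds_val, mask, cfg.seed
        )
        rows.append(
            {
                "Model": name,
                "Selected": int(mask.sum()),
                "Epochs": epochs,
                "Time": elapsed,
                "MSE": mse,
                "Gradient": gradient,
            }
        )
    return pd.DataFrame(rows)
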