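"""Class compactness and separation from pairwise Euclidean distances.

For each class: intra = mean distance over unordered same-class pairs
(self-pairs excluded), inter = mean distance from the class's samples to all
other-class samples, margin = inter - intra. Singleton classes get NaN intra
(an undefined marker, not 0) with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from fleaselect.dataset import FeatureDataset


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    """Symmetric n x n Euclidean distance matrix with zero diagonal."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains missing or non-finite values")
    if X.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(X, metric="euclidean"))


def intra_class(D: np.ndarray, labels: np.ndarray, c) -> float:
    """Mean distance over unordered same-class pairs of class ``c``."""
    labels = np.asarray(labels)
    rows = np.flatnonzero(labels == c)
    if rows.size == 0:
        raise ValueError(f"class {c} not present in labels")
    if rows.size == 1:
        warnings.warn(
            f"class {c} has a single member; intra-class dissimilarity undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    sub = D[np.ix_(rows, rows)]
    iu = np.triu_indices(rows.size, k=1)
    return float(sub[iu].mean())


def inter_class(D: np.ndarray, labels: np.ndarray, c) -> float:
    """Mean distance from class-``c`` samples to all other-class samples."""
    labels = np.asarray(labels)
    rows = np.flatnonzero(labels == c)
    others = np.flatnonzero(labels != c)
    if rows.size == 0:
        raise ValueError(f"class {c} not present in labels")
    if others.size == 0:
        raise ValueError("inter-class dissimilarity needs at least two classes")
    return float(D[np.ix_(rows, others)].mean())


def dissimilarity_report(
    ds: FeatureDataset,
    per_class_accuracy: dict | None = None,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """One row per class: intra, inter, margin (= inter - intra), accuracy.

    When ``mask`` is given, distances are computed on the selected feature
    subspace only.
    """
    if ds.n_classes < 2:
        raise ValueError("dissimilarity report needs at least two classes")
    X = ds.features if mask is None else ds.features[:, np.asarray(mask, dtype=bool)]
    D = pairwise_distances(X)
    rows = []
    for c in ds.classes:
        intra = intra_class(D, ds.labels, c)
        inter = inter_class(D, ds.labels, c)
        row = {"class": c, "intra": intra, "inter": inter, "margin": inter - intra}
        if per_class_accuracy is not None:
            row["accuracy"] = per_class_accuracy.get(c, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def margin_accuracy_correlation(report: pd.DataFrame) -> float:
    """Spearman rank correlation between class margin and per-class accuracy."""
    if "accuracy" not in report.columns:
        raise ValueError("report has no accuracy column")
    rho, _ = spearmanr(report["margin"], report["accuracy"])
    return float(rho)
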