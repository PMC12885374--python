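"""Feature-matrix container with labels, plus delimited-text round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABEL_COLUMN = "label"


@dataclass
class FeatureDataset:
    """An n x t feature matrix with integer class labels.

    Parameters
    ----------
    features : ndarray of shape (n, t)
        Real-valued feature matrix; one row per sample.
    labels : ndarray of shape (n,)
        Non-negative integer class labels.
    feature_names : list of str, optional
        Column names; generated as ``f0000..`` when omitted.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        if self.labels.ndim != 1 or self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("labels must be a vector with one entry per feature row")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(int)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("labels must be integers")
            self.labels = as_int
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.feature_names is not None:
            self.feature_names = list(self.feature_names)
            if len(self.feature_names) != self.features.shape[1]:
                raise ValueError("feature_names length must equal feature count")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return self.classes.size

    def column_names(self) -> list[str]:
        if self.feature_names is not None:
            return self.feature_names
        width = max(4, len(str(self.n_features - 1)))
        return [f"f{j:0{width}d}" for j in range(self.n_features)]

    def select_features(self, mask: np.ndarray) -> "FeatureDataset":
        """Return a copy restricted to the columns where ``mask`` is true."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_features,):
            raise ValueError("mask length must equal feature count")
        names = [n for n, m in zip(self.column_names(), mask) if m]
        return FeatureDataset(self.features[:, mask], self.labels.copy(), names)

    def take(self, rows: np.ndarray) -> "FeatureDataset":
        """Return a copy restricted to the given row indices."""
        rows = np.asarray(rows, dtype=int)
        names = self.feature_names[:] if self.feature_names is not None else None
        return FeatureDataset(self.features[rows], self.labels[rows], names)

    def to_csv(self, path) -> None:
        """Write as CSV: header = feature names, final column ``label``."""
        df = pd.DataFrame(self.features, columns=self.column_names())
        df[LABEL_COLUMN] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureDataset":
        df = pd.read_csv(path)
        if LABEL_COLUMN not in df.columns:
            raise ValueError(f"dataset CSV must contain a '{LABEL_COLUMN}' column")
        labels = df[LABEL_COLUMN].to_numpy()
        feats = df.drop(columns=[LABEL_COLUMN])
        return cls(feats.to_numpy(dtype=float), labels, list(feats.columns))
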