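"""Seeded synthetic deep-feature datasets and image augmentation operators.

The generator plants a low-dimensional class structure inside a wide feature
matrix: an informative block whose class-conditional means sit on a scaled
simplex, rho-correlated redundant copies of informative columns, and pure
noise everywhere else. Ground truth (which columns are informative) travels
in a sidecar object, never inside the matrix itself.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import AffineTransform, resize, rotate, warp

from fleaselect.dataset import FeatureDataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic feature dataset (pure function of its fields)."""

    n_per_class: int
    n_classes: int = 8
    n_features: int = 2048
    n_informative: int = 16
    n_redundant: int = 0
    class_separation: float = 4.0
    noise_sd: float = 1.0
    redundancy_rho: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_class, self.n_classes, self.n_features, self.n_informative) < 1:
            raise ValueError("counts must be positive")
        if self.n_redundant < 0:
            raise ValueError("n_redundant must be non-negative")
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("n_informative + n_redundant must not exceed n_features")
        if not 0.0 <= self.redundancy_rho <= 1.0:
            raise ValueError("redundancy_rho must lie in [0, 1]")
        if self.class_separation < 0 or self.noise_sd < 0:
            raise ValueError("class_separation and noise_sd must be non-negative")


@dataclass
class SyntheticInfo:
    """Ground-truth sidecar: which columns carry planted signal."""

    informative_idx: np.ndarray
    redundant_idx: np.ndarray
    redundant_source: np.ndarray  # informative column each redundant column copies
    spec: SyntheticSpec

    def to_json(self, path) -> None:
        payload = {
            "spec": asdict(self.spec),
            "informative_idx": self.informative_idx.tolist(),
            "redundant_idx": self.redundant_idx.tolist(),
            "redundant_source": self.redundant_source.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticInfo":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            informative_idx=np.asarray(payload["informative_idx"], dtype=int),
            redundant_idx=np.asarray(payload["redundant_idx"], dtype=int),
            redundant_source=np.asarray(payload["redundant_source"], dtype=int),
            spec=SyntheticSpec(**payload["spec"]),
        )


def _class_centroids(k: int, d: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """k centroids in R^d with pairwise distance controlled by ``separation``.

    When d >= k - 1 the centroids form a regular simplex with edge length
    exactly ``separation``. Otherwise a random Gaussian layout is rescaled so
    the minimum pairwise distance equals ``separation``.
    """
    if separation == 0.0 or k == 1:
        return np.zeros((k, d))
    if d >= k - 1:
        # Regular simplex: identity corners centered, edge length sqrt(2), rescale.
        corners = np.eye(k)
        corners -= corners.mean(axis=0)
        corners *= separation / np.sqrt(2.0)
        # Drop one coordinate (centered corners span k-1 dims) and embed in d.
        q, _ = np.linalg.qr(corners.T)  # k x (k-1) basis not needed: project instead
        proj = corners @ q[:, : k - 1]
        out = np.zeros((k, d))
        out[:, : k - 1] = proj
        return out
    centers = rng.standard_normal((k, d))
    dists = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    min_dist = dists[~np.eye(k, dtype=bool)].min()
    if min_dist == 0.0:  # pragma: no cover - measure-zero event
        raise RuntimeError("degenerate random centroids; change the seed")
    return centers * (separation / min_dist)


def generate_features(spec: SyntheticSpec) -> tuple[FeatureDataset, SyntheticInfo]:
    """Generate one dataset according to ``spec``.

    Returns the dataset together with the ground-truth sidecar. Identical
    spec (including seed) yields a bit-identical dataset.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class * spec.n_classes
    t = spec.n_features
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)

    centroids = _class_centroids(spec.n_classes, spec.n_informative, spec.class_separation, rng)
    informative = centroids[labels] + spec.noise_sd * rng.standard_normal((n, spec.n_informative))

    X = spec.noise_sd * rng.standard_normal((n, t))

    # Column layout: informative first, then redundant, then noise; then
    # permute columns so planted structure is not positionally trivial.
    rho = spec.redundancy_rho
    redundant_source_local = np.arange(spec.n_redundant) % spec.n_informative
    if spec.n_redundant:
        src = informative[:, redundant_source_local]
        src_sd = src.std(axis=0, ddof=0)
        src_sd[src_sd == 0.0] = 1.0
        eps = rng.standard_normal((n, spec.n_redundant)) * src_sd
        redundant = rho * src + np.sqrt(1.0 - rho**2) * eps
        X[:, spec.n_informative : spec.n_informative + spec.n_redundant] = redundant
    X[:, : spec.n_informative] = informative

    col_perm = rng.permutation(t)
    X = X[:, col_perm]
    new_pos = np.empty(t, dtype=int)
    new_pos[col_perm] = np.arange(t)
    informative_idx = np.sort(new_pos[: spec.n_informative])
    redundant_idx = new_pos[spec.n_informative : spec.n_informative + spec.n_redundant]
    redundant_source = new_pos[redundant_source_local]
    order = np.argsort(redundant_idx)
    redundant_idx = redundant_idx[order]
    redundant_source = redundant_source[order]

    row_perm = rng.permutation(n)
    ds = FeatureDataset(X[row_perm], labels[row_perm])
    info = SyntheticInfo(informative_idx, redundant_idx, redundant_source, spec)
    return ds, info


def _largest_remainder_counts(sizes: np.ndarray, fraction: float) -> np.ndarray:
    """Per-class train counts by largest-remainder rounding of fraction*size."""
    quotas = fraction * sizes
    base = np.floor(quotas).astype(int)
    target = int(round(fraction * sizes.sum()))
    short = target - base.sum()
    remainders = quotas - base
    # Distribute leftover units to the largest remainders; ties -> lower class.
    order = np.lexsort((np.arange(sizes.size), -remainders))
    counts = base.copy()
    for idx in order[: max(short, 0)]:
        counts[idx] += 1
    # Keep at least one sample per class on each side.
    counts = np.clip(counts, 1, sizes - 1)
    while counts.sum() > target:
        candidates = np.where(counts > 1)[0]
        idx = candidates[np.argmin(remainders[candidates])]
        counts[idx] -= 1
    while counts.sum() < target:
        candidates = np.where(counts < sizes - 1)[0]
        idx = candidates[np.argmax(remainders[candidates])]
        counts[idx] += 1
    return counts


def train_validation_split(
    ds: FeatureDataset, train_fraction: float, seed: int
) -> tuple[FeatureDataset, FeatureDataset]:
    """Stratified disjoint split; train counts follow largest-remainder rounding."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    classes = ds.classes
    sizes = np.array([(ds.labels == c).sum() for c in classes])
    for c, size in zip(classes, sizes):
        if size < 2:
            raise ValueError(f"class {c} has only {size} member(s); cannot split")
    counts = _largest_remainder_counts(sizes, train_fraction)
    train_rows: list[np.ndarray] = []
    val_rows: list[np.ndarray] = []
    for c, k in zip(classes, counts):
        rows = np.flatnonzero(ds.labels == c)
        rows = rng.permutation(rows)
        train_rows.append(rows[:k])
        val_rows.append(rows[k:])
    return ds.take(np.concatenate(train_rows)), ds.take(np.concatenate(val_rows))


def augment_image(
    img: np.ndarray,
    rng: np.random.Generator,
    rotation_range: tuple[float, float] = (-5.0, 5.0),
    shear_range: tuple[float, float] = (-0.05, 0.05),
    flip_prob: float = 0.5,
    out_size: tuple[int, int] = (224, 224),
) -> np.ndarray:
    """Rotate, reflect, shear and resize one image.

    Order is fixed: rotation by U(rotation_range) degrees; independent
    horizontal/vertical reflection each with probability ``flip_prob``; shear
    by U(shear_range) degrees on each axis; resize to ``out_size``; grayscale
    inputs replicated to 3 channels. Off-canvas pixels are filled with zeros.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 2:
        img = img[:, :, None]
    if img.ndim != 3:
        raise ValueError("image must be HxW or HxWxC")
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("spatial dimensions must be at least 2x2")

    angle = rng.uniform(*rotation_range)
    flip_h = rng.random() < flip_prob
    flip_v = rng.random() < flip_prob
    shear_x = rng.uniform(*shear_range)
    shear_y = rng.uniform(*shear_range)

    if angle != 0.0:
        img = rotate(img, angle, preserve_range=True, mode="constant", cval=0.0)
    if flip_h:
        img = img[:, ::-1]
    if flip_v:
        img = img[::-1, :]
    if shear_x != 0.0 or shear_y != 0.0:
        sx, sy = np.tan(np.deg2rad([shear_x, shear_y]))
        tform = AffineTransform(matrix=np.array([[1.0, sx, 0.0], [sy, 1.0, 0.0], [0.0, 0.0, 1.0]]))
        img = warp(img, tform.inverse, preserve_range=True, mode="constant", cval=0.0)
    if img.shape[:2] != tuple(out_size):
        img = resize(img, out_size, preserve_range=True, anti_aliasing=True)
    if img.shape[2] == 1:
        img = np.repeat(img, 3, axis=2)
    return np.ascontiguousarray(img)


def save_dataset(ds: FeatureDataset, info: SyntheticInfo, csv_path, sidecar_path) -> None:
    """Write the feature CSV and its ground-truth JSON sidecar."""
    ds.to_csv(csv_path)
    info.to_json(sidecar_path)


def load_dataset(csv_path, sidecar_path=None) -> tuple[FeatureDataset, SyntheticInfo | None]:
    ds = FeatureDataset.from_csv(csv_path)
    info = SyntheticInfo.from_json(sidecar_path) if sidecar_path is not None else None
    return ds, info
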