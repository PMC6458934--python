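"""Tabular datasets: CSV loading, stratified design/test split, synthetic blobs.

The experimental protocol halves each dataset into a *design* subset, on which
the evolutionary search and the temporal-encoding limits are computed, and a
held-out *test* subset used only to score the final network.  The split is
stratified so that each class is evenly represented on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = ["Dataset", "load_csv", "stratified_split", "make_synthetic"]


@dataclass(frozen=True)
class Dataset:
    """Numeric feature matrix with integer class labels 0..K-1."""

    X: np.ndarray
    y: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("feature matrix and labels disagree in length")
        if np.isnan(X).any():
            raise ValueError("dataset contains missing values")
        if len(self.class_names) < 2:
            raise ValueError("dataset needs at least 2 classes")
        if y.min(initial=0) < 0 or (y.max(initial=0) >= len(self.class_names)):
            raise ValueError("labels must be contiguous 0..K-1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(self.X[idx], self.y[idx], self.class_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"f{i}" for i in range(self.n_features)])
        df["label"] = [self.class_names[k] for k in self.y]
        return df


def load_csv(
    path: Union[str, Path],
    label: Union[str, int] = -1,
    header: bool = True,
) -> Dataset:
    """Read a UCI-style numeric CSV.

    ``label`` selects the class column by name (requires a header) or by
    position (negative indices allowed).  Class names are remapped to
    contiguous integer ids in order of first appearance in the file.
    """
    df = pd.read_csv(path, header=0 if header else None)
    if isinstance(label, str):
        if label not in df.columns:
            raise ValueError(f"label column {label!r} not found in {path}")
        label_col = label
    else:
        label_col = df.columns[label]
    raw_labels = df[label_col].astype(str).tolist()
    features = df.drop(columns=[label_col])
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(f"{path} contains missing feature values")
    class_names: list[str] = []
    for name in raw_labels:
        if name not in class_names:
            class_names.append(name)
    y = np.array([class_names.index(name) for name in raw_labels], dtype=int)
    return Dataset(X, y, tuple(class_names))


def stratified_split(ds: Dataset, seed: int) -> tuple[Dataset, Dataset]:
    """Halve the dataset into (design, test), stratified per class.

    For an odd class count the extra sample goes to the design subset.
    The union of the two halves is the whole dataset and the partition is
    deterministic for a fixed seed.
    """
    counts = ds.class_counts()
    if (counts < 2).any():
        bad = int(np.argmin(counts))
        raise ValueError(
            f"class {ds.class_names[bad]!r} has {counts[bad]} sample(s); "
            "need at least 2 per class to split"
        )
    rng = np.random.default_rng(seed)
    design_idx: list[int] = []
    test_idx: list[int] = []
    for k in range(ds.n_classes):
        members = np.flatnonzero(ds.y == k)
        perm = rng.permutation(members)
        n_design = (len(members) + 1) // 2  # odd count: extra to design
        design_idx.extend(perm[:n_design])
        test_idx.extend(perm[n_design:])
    design_idx = np.sort(np.array(design_idx, dtype=int))
    test_idx = np.sort(np.array(test_idx, dtype=int))
    return ds.subset(design_idx), ds.subset(test_idx)


def make_synthetic(
    n_samples: int,
    n_features: int,
    n_classes: int,
    separation: float,
    seed: int,
) -> Dataset:
    """Gaussian-blob classification fixture with unit noise.

    Class centroids are placed on scaled coordinate axes so that (for
    ``n_classes <= n_features``) every pair of centroids is exactly
    ``separation`` apart; samples are centroid + standard-normal noise.
    Labels are balanced up to remainder and rows are shuffled, all
    deterministically per seed.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_features < 1:
        raise ValueError("need at least 1 feature")
    if n_samples < 2 * n_classes:
        raise ValueError("need at least 2 samples per class")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_classes, n_features))
    for k in range(n_classes):
        centers[k, k % n_features] = separation / np.sqrt(2.0)
    per_class = np.full(n_classes, n_samples // n_classes)
    per_class[: n_samples % n_classes] += 1
    y = np.repeat(np.arange(n_classes), per_class)
    X = centers[y] + rng.standard_normal((n_samples, n_features))
    order = rng.permutation(n_samples)
    return Dataset(
        X[order], y[order], tuple(f"class{k}" for k in range(n_classes))
    )
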