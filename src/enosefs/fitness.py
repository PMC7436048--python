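"""Wrapper objective: k-NN test error plus a subset-size penalty.

The fitness of a feature subset S out of F features is

    f = alpha * err_test(S) + beta * |S| / |F|,      beta = 1 - alpha

with alpha = 0.99 by default, so classification error dominates and subset
size only breaks near-ties.  err_test is the misclassification rate of a
k-nearest-neighbour classifier (k = 5, Euclidean distance) trained on the
70% train split and scored on the held-out 30%, computed on z-score
standardized columns (train-split statistics).  Lower fitness is better; an
empty subset scores the worst possible fitness 1.0 without touching the
classifier.

Ten-fold cross-validated error on the train split is available separately as
an over-fitting check; it is reported alongside, never folded into, the
fitness — k-NN has no fitted parameters, so "pick the best CV model" has no
operative meaning for this wrapper.

k-NN determinism contract: neighbours are ordered by (distance, train index);
vote ties are broken by the smallest mean neighbour distance among the tied
classes, then by the lowest class index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold, train_test_split

from .containers import FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_K = 5


@dataclass(frozen=True)
class FitnessWeights:
    """Weights of the error/size trade-off; size_weight is always 1 - accuracy_weight."""

    accuracy_weight: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy_weight <= 1.0:
            raise ValueError("accuracy_weight must lie in [0, 1]")

    @property
    def size_weight(self) -> float:
        return 1.0 - self.accuracy_weight


@dataclass
class FitnessResult:
    """Scalar fitness with its decomposition."""

    fitness: float
    error_rate: float
    n_selected: int
    n_total: int
    mask: np.ndarray


@dataclass
class DataSplit:
    """Row-disjoint stratified train/test split of one feature table."""

    train: FeatureTable
    test: FeatureTable
    split_fraction: float = 0.7
    split_seed: int = 0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.train.n_features != self.test.n_features:
            raise ValueError("train and test must share feature columns")

    @property
    def n_features(self) -> int:
        return self.train.n_features

    def standardized(self) -> tuple[np.ndarray, np.ndarray]:
        """Train/test matrices z-scored with train-column statistics (cached)."""
        if "std" not in self._cache:
            mu = self.train.values.mean(axis=0)
            sd = self.train.values.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            self._cache["std"] = (
                (self.train.values - mu) / sd,
                (self.test.values - mu) / sd,
            )
        return self._cache["std"]


def make_split(table: FeatureTable, split_fraction: float = 0.7, seed: int = 0) -> DataSplit:
    """Stratified split of a feature table at the given train fraction."""
    idx = np.arange(table.n_samples)
    tr, te = train_test_split(
        idx, train_size=split_fraction, random_state=seed, stratify=table.labels
    )
    return DataSplit(
        train=table.subset_rows(np.sort(tr)),
        test=table.subset_rows(np.sort(te)),
        split_fraction=split_fraction,
        split_seed=seed,
    )


def _knn_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray, k: int
) -> np.ndarray:
    """Deterministic k-NN labels; see the module docstring for tie-breaks."""
    if k > train_x.shape[0]:
        raise ValueError(f"k={k} exceeds number of training samples {train_x.shape[0]}")
    classes, y_idx = np.unique(train_y, return_inverse=True)
    d = cdist(test_x, train_x)
    # stable sort orders equal distances by train index
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    neigh_lab = y_idx[order]                       # (n_test, k)
    neigh_d = np.take_along_axis(d, order, axis=1)  # (n_test, k)
    onehot = neigh_lab[:, :, None] == np.arange(classes.size)[None, None, :]
    counts = onehot.sum(axis=1)                    # (n_test, C)
    with np.errstate(invalid="ignore"):
        mean_d = np.where(
            counts > 0, (onehot * neigh_d[:, :, None]).sum(axis=1) / np.maximum(counts, 1), np.inf
        )
    top = counts == counts.max(axis=1, keepdims=True)
    # among top-count classes pick smallest mean distance; argmin takes the
    # lowest class index on exact ties
    pick = np.where(top, mean_d, np.inf).argmin(axis=1)
    return classes[pick]


def knn_error_rate(
    train: FeatureTable, test: FeatureTable, mask: np.ndarray, k: int = DEFAULT_K
) -> float:
    """k-NN misclassification rate on the masked, train-standardized columns."""
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no features (empty-subset condition)")
    mu = train.values[:, mask].mean(axis=0)
    sd = train.values[:, mask].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    pred = _knn_predict(
        (train.values[:, mask] - mu) / sd, train.labels, (test.values[:, mask] - mu) / sd, k
    )
    return float(np.mean(pred != test.labels))


def evaluate_subset(
    mask: np.ndarray,
    split: DataSplit,
    weights: FitnessWeights = FitnessWeights(),
    k: int = DEFAULT_K,
) -> FitnessResult:
    """Apply the weighted fitness to the k-NN test error of one mask.

    The all-zero mask short-circuits to fitness 1.0 (worst) without invoking
    the classifier.  Deterministic: identical arguments give bit-identical
    results.
    """
    mask = np.asarray(mask).astype(np.int8)
    n_total = split.n_features
    if mask.shape[0] != n_total:
        raise ValueError("mask length must equal the number of feature columns")
    n_sel = int(mask.sum())
    if n_sel == 0:
        return FitnessResult(1.0, 1.0, 0, n_total, mask)
    train_x, test_x = split.standardized()
    sel = mask.astype(bool)
    pred = _knn_predict(train_x[:, sel], split.train.labels, test_x[:, sel], k)
    err = float(np.mean(pred != split.test.labels))
    fit = weights.accuracy_weight * err + weights.size_weight * n_sel / n_total
    return FitnessResult(float(fit), err, n_sel, n_total, mask)


def cross_validated_error(
    train: FeatureTable, mask: np.ndarray, folds: int = 10, k: int = DEFAULT_K
) -> float:
    """Mean stratified k-fold k-NN error on the train split (over-fitting check).

    Folds are reduced to the smallest class count when a class has fewer than
    ``folds`` members (logged).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no features")
    _, class_counts = np.unique(train.labels, return_counts=True)
    if class_counts.size < 2:
        raise ValueError("cross-validation requires at least two classes")
    eff_folds = min(folds, int(class_counts.min()))
    if eff_folds < folds:
        logger.info("reducing folds from %d to %d (smallest class)", folds, eff_folds)
    if eff_folds < 2:
        raise ValueError("smallest class has fewer than 2 members; cannot cross-validate")
    x = train.values[:, mask]
    errs = []
    for tr, te in StratifiedKFold(n_splits=eff_folds).split(x, train.labels):
        mu, sd = x[tr].mean(axis=0), x[tr].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        k_eff = min(k, tr.size)
        pred = _knn_predict((x[tr] - mu) / sd, train.labels[tr], (x[te] - mu) / sd, k_eff)
        errs.append(np.mean(pred != train.labels[te]))
    return float(np.mean(errs))
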