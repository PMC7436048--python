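"""Evaluation layer: macro F1, run-set fitness statistics, Wilcoxon comparisons.

Macro F1 averages the per-class harmonic mean of precision and recall with
equal class weights, F1 = (1/C) sum_k 2 Pre_k Rec_k / (Pre_k + Rec_k); a
class with Pre + Rec = 0 contributes 0.  Run-set statistics summarize the
final fitnesses of M independent seeded runs by their minimum (best), maximum
(worst), mean and population standard deviation.  Algorithm pairs are
compared with the paired Wilcoxon signed-rank test, since runs are matched by
seed/dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import wilcoxon
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .fitness import DEFAULT_K, DataSplit, _knn_predict

SVM_C = 2.0
SVM_GAMMA = 0.2
RF_TREES = 200


@dataclass
class ConfusionCounts:
    """Per-class true-positive/false-positive/false-negative counts."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    classes: np.ndarray


@dataclass
class RunSetStats:
    best: float
    worst: float
    mean: float
    std: float
    n_runs: int


def confusion_counts(true_labels, predicted_labels) -> ConfusionCounts:
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("label vectors must be equal-length and non-empty")
    classes = np.union1d(t, p)
    tp = np.array([np.sum((t == c) & (p == c)) for c in classes])
    fp = np.array([np.sum((t != c) & (p == c)) for c in classes])
    fn = np.array([np.sum((t == c) & (p != c)) for c in classes])
    return ConfusionCounts(tp, fp, fn, classes)


def macro_f1(true_labels, predicted_labels) -> float:
    """Unweighted mean over classes of per-class F1 (zero-denominator class -> 0)."""
    cc = confusion_counts(true_labels, predicted_labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        pre = np.where(cc.tp + cc.fp > 0, cc.tp / np.maximum(cc.tp + cc.fp, 1), 0.0)
        rec = np.where(cc.tp + cc.fn > 0, cc.tp / np.maximum(cc.tp + cc.fn, 1), 0.0)
        denom = pre + rec
        f1 = np.where(denom > 0, 2.0 * pre * rec / np.maximum(denom, 1e-300), 0.0)
    return float(f1.mean())


def run_set_stats(final_fitnesses) -> RunSetStats:
    """min / max / mean / population SD of the per-run final fitnesses."""
    f = np.asarray(final_fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one run")
    return RunSetStats(
        best=float(f.min()),
        worst=float(f.max()),
        mean=float(f.mean()),
        std=float(f.std()),  # ddof=0: population SD
        n_runs=int(f.size),
    )


def wilcoxon_compare(series_a, series_b, alternative: str = "two-sided") -> float:
    """Paired Wilcoxon signed-rank p-value between two matched run series.

    Exact null distribution when n <= 25 with no ties among |differences|,
    normal approximation with tie correction otherwise.  All-zero differences
    return p = 1 with a warning (no evidence either way).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need equal-length paired series of length >= 5")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
        return 1.0
    nz = d[d != 0]
    exact_ok = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
    method = "exact" if exact_ok else "approx"
    return float(wilcoxon(a, b, alternative=alternative, method=method).pvalue)


def score_subset_with_classifiers(
    mask,
    split: DataSplit,
    classifiers=("knn", "svm", "rf"),
    k: int = DEFAULT_K,
    rf_seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Test-split accuracy and macro F1 of a mask under k-NN, RBF-SVM and RF.

    All classifiers see the same train-standardized masked columns.  The
    k-NN entry is exactly 1 minus the wrapper's error rate.  An empty mask
    scores 0 everywhere without training anything.
    """
    mask = np.asarray(mask).astype(bool)
    out: dict[str, dict[str, float]] = {}
    if mask.sum() == 0:
        return {c: {"accuracy": 0.0, "macro_f1": 0.0} for c in classifiers}
    train_x, test_x = split.standardized()
    xtr, xte = train_x[:, mask], test_x[:, mask]
    ytr, yte = split.train.labels, split.test.labels
    for name in classifiers:
        if name == "knn":
            pred = _knn_predict(xtr, ytr, xte, k)
        elif name == "svm":
            pred = SVC(kernel="rbf", C=SVM_C, gamma=SVM_GAMMA).fit(xtr, ytr).predict(xte)
        elif name == "rf":
            pred = (
                RandomForestClassifier(n_estimators=RF_TREES, random_state=rf_seed)
                .fit(xtr, ytr)
                .predict(xte)
            )
        else:
            raise ValueError(f"unknown classifier {name!r}")
        out[name] = {
            "accuracy": float(np.mean(pred == yte)),
            "macro_f1": macro_f1(yte, pred),
        }
    return out
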