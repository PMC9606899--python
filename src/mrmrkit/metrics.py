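"""Confusion-matrix metrics and cross-validation / holdout protocols.

Binary metrics are accuracy AC = (TP+TN)/N, precision PR = TP/(TP+FP), recall
RE = TP/(TP+FN), F1 = 2*PR*RE/(PR+RE) = 2TP/(FN+2TP+FP) and false-positive
rate FPR = FP/(FP+TN). A zero denominator yields ``None`` (an explicit
undefined marker) rather than a silent 0 or 1. Multi-class problems are
reduced to one-vs-rest counts per class plus a macro average.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import train_test_split

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_metrics",
    "counts_from_predictions",
    "one_vs_rest_metrics",
    "kfold_split",
    "cv_accuracy",
    "holdout_split",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """AC/PR/RE/F1/FPR in [0,1]; ``None`` marks an undefined (0/0) metric."""

    AC: float | None
    PR: float | None
    RE: float | None
    F1: float | None
    FPR: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Compute the five confusion-matrix metrics from raw counts."""
    if counts.total < 1:
        raise ValueError("confusion counts are all zero")
    return MetricsReport(
        AC=_ratio(counts.TP + counts.TN, counts.total),
        PR=_ratio(counts.TP, counts.TP + counts.FP),
        RE=_ratio(counts.TP, counts.TP + counts.FN),
        F1=_ratio(2 * counts.TP, counts.FN + 2 * counts.TP + counts.FP),
        FPR=_ratio(counts.FP, counts.FP + counts.TN),
    )


def counts_from_predictions(y_true, y_pred, positive_label) -> ConfusionCounts:
    """One-vs-rest confusion counts treating ``positive_label`` as positive."""
    t = np.asarray(y_true) == positive_label
    p = np.asarray(y_pred) == positive_label
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred length mismatch")
    return ConfusionCounts(
        TP=int(np.sum(t & p)),
        FP=int(np.sum(~t & p)),
        TN=int(np.sum(~t & ~p)),
        FN=int(np.sum(t & ~p)),
    )


def one_vs_rest_metrics(y_true, y_pred) -> dict:
    """Per-class one-vs-rest MetricsReport plus an unweighted macro average.

    Undefined per-class metrics are skipped in the macro mean; a macro entry is
    ``None`` only if the metric is undefined for every class.
    """
    classes = sorted(set(np.asarray(y_true).tolist()))
    per_class = {
        c: confusion_metrics(counts_from_predictions(y_true, y_pred, c)) for c in classes
    }
    macro = {}
    for name in ("AC", "PR", "RE", "F1", "FPR"):
        vals = [getattr(r, name) for r in per_class.values() if getattr(r, name) is not None]
        macro[name] = float(np.mean(vals)) if vals else None
    return {"per_class": per_class, "macro": MetricsReport(**macro)}


def kfold_split(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """Stratified partition of 0..n-1 into ``k`` disjoint folds.

    Instances of each class are shuffled and dealt round-robin across folds,
    with the starting fold rotating between classes so overall fold sizes stay
    balanced. Per-class fold sizes differ by at most one; classes smaller than
    ``k`` simply leave some folds without that class. Deterministic given
    ``seed``.
    """
    y = np.asarray(labels)
    n = y.size
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for t, ix in enumerate(idx):
            folds[(t + offset) % k].append(int(ix))
        offset = (offset + idx.size) % k
    return [np.array(sorted(f), dtype=int) for f in folds]


def cv_accuracy(X, y, subset, k: int = 10, classifier=None, seed: int = 0,
                folds=None) -> float:
    """Unweighted mean k-fold CV accuracy of ``classifier`` on subset columns.

    Each fold: fit on the other k-1 folds restricted to ``subset`` columns,
    score the held-out fold. A fold whose training part has a single class and
    whose classifier cannot fit is marked degenerate and skipped (reported via
    the returned value being over the remaining folds).

    ``folds`` may pass a precomputed partition so repeated comparisons are
    paired on identical folds.
    """
    from sklearn.naive_bayes import GaussianNB

    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    X = np.asarray(X, dtype=float)[:, subset]
    y = np.asarray(y)
    if classifier is None:
        classifier = GaussianNB()
    if folds is None:
        folds = kfold_split(y, k, seed)
    accs = []
    for test_idx in folds:
        mask = np.ones(y.size, dtype=bool)
        mask[test_idx] = False
        clf = clone(classifier)
        try:
            clf.fit(X[mask], y[mask])
        except ValueError:
            continue  # degenerate fold: single-class training data
        accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
    if not accs:
        raise ValueError("all folds degenerate; cannot score")
    return float(np.mean(accs))


def holdout_split(n: int, labels, train_fraction: float = 0.7, seed: int = 0):
    """Stratified train/test index split, reproducible given ``seed``."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    idx = np.arange(n)
    y = np.asarray(labels)
    train, test = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed
    )
    return np.sort(train), np.sort(test)
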