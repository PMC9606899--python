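"""Greedy minimum-redundancy maximum-relevance (mRMR) feature selection.

The selector trades the mean mutual information between a feature subset S and
the class label c (Max-Relevance, D = (1/|S|) sum I(x_i; c)) against the mean
pairwise mutual information within S (Min-Redundancy,
R = (1/|S|^2) sum I(x_i; x_j), all ordered pairs including the diagonal). The
combined objective Phi = D - R is maximized incrementally: the first pick is
the feature most informative about the label, and each later step adds the
feature maximizing

    J(x_j) = I(x_j; c) - (1/|S|) sum_{x_i in S} I(x_i; x_j)

over the remaining candidates. Optionally, after every addition the k-fold
cross-validated accuracy of a classifier on S is compared with that of S minus
its newest member (on the identical fold partition, so the comparison is
paired); a drop terminates selection and discards the newest member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .mi import DiscretizationConfig, MICache, build_cache
from .metrics import cv_accuracy, kfold_split

__all__ = [
    "FeatureTable",
    "SelectionConfig",
    "SelectionStep",
    "SelectionResult",
    "relevance_D",
    "redundancy_R",
    "incremental_score",
    "MRMRSelector",
    "select_features",
]


@dataclass
class FeatureTable:
    """n instances by m numeric features plus one categorical label vector."""

    features: np.ndarray  # (n, m) finite reals
    labels: np.ndarray  # (n,) categorical
    feature_names: list[str] = None
    instance_ids: list[str] = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        n, m = self.features.shape
        if n < 2 or m < 1:
            raise ValueError(f"need n >= 2 instances and m >= 1 features, got {n} x {m}")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature matrix contains NaN or infinite values")
        if self.labels.shape != (n,):
            raise ValueError("labels length does not match number of instances")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(m)]
        if self.instance_ids is None:
            self.instance_ids = [str(i) for i in range(n)]
        if len(self.feature_names) != m:
            raise ValueError("feature_names length mismatch")
        if len(self.instance_ids) != n:
            raise ValueError("instance_ids length mismatch")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def label_codes(self) -> np.ndarray:
        """Labels as dense integer codes 0..K-1 (order of np.unique)."""
        _, codes = np.unique(self.labels, return_inverse=True)
        return codes


@dataclass(frozen=True)
class SelectionConfig:
    """All knobs of a selection run; mirrors MRMRSelector's parameters."""

    max_features: int | None = None
    cv_folds: int = 10
    stop_on_accuracy_drop: bool = True
    strict_decrease: bool = True
    classifier: object = None  # any fit/predict estimator; None -> GaussianNB
    seed: int = 0
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)


@dataclass(frozen=True)
class SelectionStep:
    """Trace of one greedy addition.

    ``J_score`` is the incremental criterion of the chosen feature (its
    relevance alone at k=1); D, R and Phi = D - R describe the subset *after*
    the addition; ``cv_accuracy`` is absent (None) when stopping is disabled.
    """

    k: int
    chosen: int
    J_score: float
    D: float
    R: float
    Phi: float
    cv_accuracy: float | None = None


@dataclass(frozen=True)
class SelectionResult:
    selected: list[int]
    steps: list[SelectionStep]
    stopped_reason: str  # accuracy_drop | max_features | exhausted


def relevance_D(subset, cache: MICache) -> float:
    """Mean relevance D of a subset: (1/|S|) sum I(x_i; c)."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    return float(np.mean(cache.relevance[subset]))


def redundancy_R(subset, cache: MICache) -> float:
    """Mean pairwise redundancy R: (1/|S|^2) over all ordered pairs, i = j included."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    total = 0.0
    for i in subset:
        for j in subset:
            total += cache.pairwise(i, j)
    return total / len(subset) ** 2


def incremental_score(candidate: int, selected, cache: MICache) -> float:
    """Incremental mRMR criterion J for ``candidate`` against ``selected``.

    Reduces to the candidate's relevance when nothing is selected yet.
    """
    selected = list(selected)
    if candidate in selected:
        raise ValueError(f"candidate {candidate} already selected")
    rel = float(cache.relevance[candidate])
    if not selected:
        return rel
    red = np.mean([cache.pairwise(i, candidate) for i in selected])
    return rel - float(red)


_TIE_TOL = 1e-9  # absorbs last-bit float jitter between mathematically equal scores


def _argmax_lowest_index(scores) -> int:
    """Position of the maximum; scores within _TIE_TOL of the maximum are
    treated as tied and the earliest (lowest feature index) wins."""
    top = max(scores)
    for i, s in enumerate(scores):
        if s >= top - _TIE_TOL:
            return i
    raise AssertionError("unreachable")


class MRMRSelector(SelectorMixin, BaseEstimator):
    """scikit-learn transformer running greedy mRMR with an optional CV stop.

    Parameters
    ----------
    max_features : int or None
        Cap on the number of selected features; None means unlimited.
    cv_folds : int
        Folds for the stopping rule's stratified cross-validation.
    stop_on_accuracy_drop : bool
        Terminate (discarding the newest feature) when CV accuracy drops.
    strict_decrease : bool
        If True, stop only on a strict accuracy decrease; if False, a tie
        also stops.
    classifier : estimator or None
        Classifier used by the stopping rule; any object with fit/predict.
        None selects Gaussian naive Bayes.
    n_bins, strategy
        Discretization of continuous features for MI estimation.
    random_state : int
        Seeds the fold partition; selection itself is deterministic.

    Attributes
    ----------
    selected_ : list of int
        Chosen feature indices, in selection order.
    steps_ : list of SelectionStep
        Full per-step trace (J, D, R, Phi, CV accuracy).
    stopped_reason_ : str
        One of ``accuracy_drop``, ``max_features``, ``exhausted``.
    """

    def __init__(self, max_features=None, cv_folds=10, stop_on_accuracy_drop=True,
                 strict_decrease=True, classifier=None, n_bins=10,
                 strategy="equal_frequency", random_state=0):
        self.max_features = max_features
        self.cv_folds = cv_folds
        self.stop_on_accuracy_drop = stop_on_accuracy_drop
        self.strict_decrease = strict_decrease
        self.classifier = classifier
        self.n_bins = n_bins
        self.strategy = strategy
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, m = X.shape
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains NaN or infinite values")
        classes, y_codes = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("selection requires at least 2 distinct classes")
        if self.stop_on_accuracy_drop and self.cv_folds > n:
            raise ValueError(f"cv_folds={self.cv_folds} exceeds n={n}")

        cfg = DiscretizationConfig(n_bins=self.n_bins, strategy=self.strategy)
        cache = build_cache(X, y_codes, cfg)
        self.cache_ = cache
        self.classes_ = classes
        self.n_features_in_ = m

        cap = m if self.max_features is None else min(self.max_features, m)
        folds = None
        if self.stop_on_accuracy_drop:
            folds = kfold_split(y_codes, self.cv_folds, self.random_state)

        selected: list[int] = []
        steps: list[SelectionStep] = []
        remaining = list(range(m))
        reason = "exhausted"
        acc_prev = None
        while remaining and len(selected) < cap:
            scores = [incremental_score(j, selected, cache) for j in remaining]
            best = _argmax_lowest_index(scores)
            j_star, j_score = remaining[best], float(scores[best])
            trial = selected + [j_star]
            acc = None
            if self.stop_on_accuracy_drop:
                acc = cv_accuracy(X, y_codes, trial, k=self.cv_folds,
                                  classifier=self.classifier, folds=folds)
                if acc_prev is not None:
                    dropped = acc < acc_prev if self.strict_decrease else acc <= acc_prev
                    if dropped:
                        reason = "accuracy_drop"
                        break
                acc_prev = acc
            selected = trial
            remaining.pop(best)
            D = relevance_D(selected, cache)
            R = redundancy_R(selected, cache)
            steps.append(SelectionStep(k=len(selected), chosen=j_star, J_score=j_score,
                                       D=D, R=R, Phi=D - R, cv_accuracy=acc))
        else:
            if remaining and len(selected) >= cap:
                reason = "max_features"

        self.selected_ = selected
        self.steps_ = steps
        self.stopped_reason_ = reason
        return self

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask

    def result_(self) -> SelectionResult:
        """Trace as a plain SelectionResult record."""
        return SelectionResult(selected=list(self.selected_), steps=list(self.steps_),
                               stopped_reason=self.stopped_reason_)


def select_features(table: FeatureTable, config: SelectionConfig = SelectionConfig()) -> SelectionResult:
    """Functional wrapper: run MRMRSelector on a FeatureTable."""
    sel = MRMRSelector(
        max_features=config.max_features,
        cv_folds=config.cv_folds,
        stop_on_accuracy_drop=config.stop_on_accuracy_drop,
        strict_decrease=config.strict_decrease,
        classifier=config.classifier,
        n_bins=config.discretization.n_bins,
        strategy=config.discretization.strategy,
        random_state=config.seed,
    )
    sel.fit(table.features, table.labels)
    return sel.result_()
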