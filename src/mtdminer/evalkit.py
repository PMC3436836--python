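"""Metrics, ROC AUC, n-fold cross-validation and the SVM baseline.

Definitions: Acc = (TP+TN)/(TP+TN+FP+FN), Sen = TP/(TP+FN),
Spe = TN/(TN+FP); a metric with zero denominator is reported as undefined
(None), not as 0. AUC is the area under the (1-specificity, sensitivity)
curve, computed by the rank (Mann-Whitney) equivalence so score ties earn
half credit.

Cross-validation randomly partitions the data into ``n_folds`` near-equal
bins; each instance is predicted exactly once and metrics are pooled over
all held-out predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import adtree as _adtree
from .errors import DataError


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)

    @staticmethod
    def from_predictions(y_true, y_pred) -> "ConfusionCounts":
        yt = np.asarray(y_true) > 0
        yp = np.asarray(y_pred) > 0
        return ConfusionCounts(
            TP=int((yt & yp).sum()), FP=int((~yt & yp).sum()),
            TN=int((~yt & ~yp).sum()), FN=int((yt & ~yp).sum()))


@dataclass
class Metrics:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None


def metrics(counts: ConfusionCounts) -> Metrics:
    """Acc, Sen, Spe; None where the denominator is zero."""
    n = counts.n
    acc = (counts.TP + counts.TN) / n if n else None
    sen = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else None
    spe = counts.TN / (counts.TN + counts.FP) if counts.TN + counts.FP else None
    return Metrics(accuracy=acc, sensitivity=sen, specificity=spe)


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic."""
    y = np.asarray(labels) > 0
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes required for AUC")
    ranks = rankdata(s)  # midranks handle ties
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class EvalReport:
    fold_test_indices: list[np.ndarray]
    fold_counts: list[ConfusionCounts]
    pooled: ConfusionCounts
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    auc: float
    scores: np.ndarray       # held-out decision score per instance
    predictions: np.ndarray  # held-out +-1 prediction per instance
    seed: int = 0

    @property
    def n_folds(self) -> int:
        return len(self.fold_test_indices)

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "seed": self.seed,
            "pooled": {"TP": self.pooled.TP, "FP": self.pooled.FP,
                       "TN": self.pooled.TN, "FN": self.pooled.FN},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "folds": [{"TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN}
                      for c in self.fold_counts],
        }


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------

@dataclass
class SVMConfig:
    gamma: float | str = "scale"
    C: float = 1.0

    def __post_init__(self) -> None:
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")


class ADTreeLearner:
    """Cross-validation adapter around :func:`mtdminer.adtree.train_adtree`."""

    def __init__(self, n_iterations: int = 6):
        self.n_iterations = n_iterations
        self.model_: _adtree.ADTreeModel | None = None

    def fit(self, X, y) -> "ADTreeLearner":
        self.model_ = _adtree.train_adtree(X, y,
                                           n_iterations=self.n_iterations)
        return self

    def decision_scores(self, X) -> np.ndarray:
        return _adtree.predict_margin(self.model_, X)


class SVMLearner:
    """Gaussian-kernel SVM with per-fit feature standardization."""

    def __init__(self, config: SVMConfig | None = None):
        self.config = config or SVMConfig()
        self.pipeline_ = None

    def fit(self, X, y) -> "SVMLearner":
        self.pipeline_ = train_svm(np.asarray(X, dtype=float),
                                   np.asarray(y), self.config)
        return self

    def decision_scores(self, X) -> np.ndarray:
        return self.pipeline_.decision_function(np.asarray(X, dtype=float))


def train_svm(X, y, config: SVMConfig | None = None):
    """Fit a maximum-margin Gaussian-kernel classifier (delegated solver).

    Features are z-scored with parameters learned on the given data only;
    returns a fitted pipeline exposing ``decision_function``.
    """
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    config = config or SVMConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", gamma=config.gamma, C=config.C)),
    ])
    pipe.fit(np.asarray(X, dtype=float), y)
    return pipe


def make_learner(name: str, **kwargs):
    if name == "adtree":
        return ADTreeLearner(**kwargs)
    if name == "svm":
        return SVMLearner(SVMConfig(**kwargs) if kwargs else None)
    raise DataError(f"unknown learner {name!r}")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _partition(n: int, n_folds: int, seed: int,
               stratify_labels=None) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        perm = rng.permutation(n)
        return [f for f in np.array_split(perm, n_folds)]
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    labels = np.asarray(stratify_labels)
    slot = 0
    for cls in np.unique(labels):
        members = np.nonzero(labels == cls)[0]
        for i in rng.permutation(members):
            folds[slot % n_folds].append(int(i))
            slot += 1
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validate(X, y, learner, n_folds: int = 20, seed: int = 0,
                   stratify: bool = False) -> EvalReport:
    """Seeded n-fold cross-validation with pooled held-out metrics.

    ``learner`` is a string ("adtree"/"svm") or a factory returning objects
    with ``fit(X, y)`` and ``decision_scores(X)``. If a training split ends
    up single-class the partition is reshuffled once with seed+1 before
    erroring out.
    """
    X = np.asarray(X, dtype=float)
    y01 = (np.asarray(y) > 0).astype(int)
    n = len(X)
    if n < n_folds:
        raise DataError(f"n={n} < n_folds={n_folds}")
    if len(np.unique(y01)) < 2:
        raise DataError("both classes required")

    if isinstance(learner, str):
        learner_name = learner
        factory = lambda: make_learner(learner_name)  # noqa: E731
    else:
        factory = learner

    for attempt_seed in (seed, seed + 1):
        folds = _partition(n, n_folds, attempt_seed,
                           stratify_labels=y01 if stratify else None)
        ok = all(len(np.unique(y01[np.setdiff1d(np.arange(n), f)])) == 2
                 for f in folds)
        if ok:
            break
    else:
        raise DataError("a training split contains a single class even "
                        "after reshuffling")

    scores = np.empty(n)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        est = factory()
        est.fit(X[train_idx], y01[train_idx])
        scores[test_idx] = est.decision_scores(X[test_idx])
    predictions = np.where(scores > 0, 1, -1)

    fold_counts = [ConfusionCounts.from_predictions(y01[f], predictions[f])
                   for f in folds]
    pooled = ConfusionCounts.from_predictions(y01, predictions)
    m = metrics(pooled)
    return EvalReport(
        fold_test_indices=[np.array(f) for f in folds],
        fold_counts=fold_counts, pooled=pooled,
        accuracy=m.accuracy, sensitivity=m.sensitivity,
        specificity=m.specificity,
        auc=roc_auc(y01, scores), scores=scores, predictions=predictions,
        seed=attempt_seed)


def best_threshold_accuracy(labels, scores) -> tuple[float, float]:
    """Accuracy at the score cut maximizing class separation, plus the cut."""
    y = np.asarray(labels) > 0
    s = np.asarray(scores, dtype=float)
    cuts = np.concatenate([[s.min() - 1.0],
                           (np.sort(np.unique(s))[:-1]
                            + np.sort(np.unique(s))[1:]) / 2.0,
                           [s.max() + 1.0]])
    best_acc, best_cut = -1.0, 0.0
    for c in cuts:
        acc = float(((s > c) == y).mean())
        if acc > best_acc:
            best_acc, best_cut = acc, float(c)
    return best_acc, best_cut
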