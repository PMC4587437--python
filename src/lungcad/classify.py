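"""Classification of lung ROIs on reduced features, with leave-M-out CV.

Four classifiers: K-nearest neighbour (K = 5, Euclidean), linear-kernel
SVM (C = 1), Gaussian naive Bayes, and a linear discriminant (Fisher LDA
with pooled covariance).  Evaluation uses leave-M-out cross-validation:
repeated stratified random holdouts of size M (exhaustive enumeration is
combinatorially infeasible beyond M = 1, where an exact leave-one-out mode
exists).  Inside every repeat the PLSR reduction is refitted on the
training split only, so no label information leaks into the held-out set.

Metrics, in percent:
    sensitivity = TP / (TP + FN), specificity = TN / (FP + TN),
    accuracy = (TP + TN) / (TP + FN + TN + FP).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .selection import plsr_fit, select_n_factors, transform

CLASSIFIER_KINDS = ("knn", "svm", "naive_bayes", "linear")
DEFAULT_KNN_K = 5
DEFAULT_SVM_C = 1.0
DEFAULT_N_REPEATS = 50


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def train_classifier(kind: str, X_train: np.ndarray, y_train: np.ndarray, params: dict | None = None):
    """Fit one of the four supported classifiers; deterministic given data."""
    params = params or {}
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain both classes")
    if kind == "knn":
        k = int(params.get("k", DEFAULT_KNN_K))
        model = KNeighborsClassifier(n_neighbors=min(k, len(y_train)), metric="euclidean")
    elif kind == "svm":
        model = SVC(kernel=params.get("kernel", "linear"), C=float(params.get("C", DEFAULT_SVM_C)))
    elif kind == "naive_bayes":
        model = GaussianNB()
    elif kind == "linear":
        model = LinearDiscriminantAnalysis(solver="svd")
    else:
        raise ValueError(f"unknown classifier kind: {kind!r}")
    return model.fit(X_train, y_train)


def confusion(y_true: Sequence[int], y_pred: Sequence[int], positive_label: int = 1) -> ConfusionCounts:
    """Confusion counts with the cancer class (label 1) as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty inputs")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    pos = y_true == positive_label
    pred_pos = y_pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def metrics(c: ConfusionCounts) -> tuple[float | None, float | None, float]:
    """(sensitivity%, specificity%, accuracy%); zero-denominator ratios are None."""
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    spec = 100.0 * c.tn / (c.fp + c.tn) if (c.fp + c.tn) else None
    acc = 100.0 * (c.tp + c.tn) / c.total
    return sens, spec, acc


@dataclasses.dataclass
class ClassifierSummary:
    accuracy_mean: float
    accuracy_sd: float
    sensitivity_mean: float | None
    sensitivity_sd: float | None
    specificity_mean: float | None
    specificity_sd: float | None
    confusion_total: ConfusionCounts


@dataclasses.dataclass
class EvalReport:
    """Per-classifier CV metrics for one holdout size M."""

    per_classifier: dict[str, ClassifierSummary]
    m: int
    n_train: int
    n_test: int
    n_repeats: int

    def to_dict(self) -> dict:
        out = {
            "M": self.m,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_repeats": self.n_repeats,
            "classifiers": {},
        }
        for kind, s in self.per_classifier.items():
            out["classifiers"][kind] = {
                "accuracy_pct": {"mean": s.accuracy_mean, "sd": s.accuracy_sd},
                "sensitivity_pct": {"mean": s.sensitivity_mean, "sd": s.sensitivity_sd},
                "specificity_pct": {"mean": s.specificity_mean, "sd": s.specificity_sd},
                "confusion": dataclasses.asdict(s.confusion_total),
            }
        return out


def _splits(y: np.ndarray, m: int, n_repeats: int, seed: int, exhaustive: bool):
    n = len(y)
    if exhaustive:
        if m != 1:
            raise ValueError("exhaustive mode is only available for M = 1 (leave-one-out)")
        for i in range(n):
            test = np.array([i])
            yield np.setdiff1d(np.arange(n), test), test
        return
    if m < 2:
        rng = np.random.default_rng(seed)
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            yield perm[m:], perm[:m]
        return
    sss = StratifiedShuffleSplit(n_splits=n_repeats, test_size=m, random_state=seed)
    yield from sss.split(np.zeros((n, 1)), y)


def leave_m_out_cv(
    X: np.ndarray,
    y: np.ndarray,
    m: int,
    n_repeats: int = DEFAULT_N_REPEATS,
    seed: int = 0,
    kinds: Sequence[str] = CLASSIFIER_KINDS,
    plsr_threshold: float = 0.90,
    max_factors: int | None = None,
    classifier_params: dict | None = None,
    exhaustive: bool = False,
) -> EvalReport:
    """Leave-M-out evaluation of the full reduce-then-classify stage.

    Per repeat: hold out M samples (stratified when M >= 2), fit PLSR on
    the training split, pick the factor count at the variance threshold,
    train every classifier on the training scores, and score the holdout.
    Reports mean +/- sd per metric per classifier plus pooled confusion
    counts; deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    n = len(y)
    if not 1 <= m < n:
        raise ValueError(f"M must satisfy 1 <= M < n = {n}")
    classifier_params = classifier_params or {}

    per_repeat: dict[str, list[tuple[float | None, float | None, float]]] = {k: [] for k in kinds}
    pooled: dict[str, ConfusionCounts] = {k: ConfusionCounts(0, 0, 0, 0) for k in kinds}
    n_splits = 0
    for train_idx, test_idx in _splits(y, m, n_repeats, seed, exhaustive):
        n_splits += 1
        limit = min(len(train_idx) - 1, X.shape[1])
        k_max = limit if max_factors is None else min(max_factors, limit)
        model = plsr_fit(X[train_idx], y[train_idx], max_factors=k_max)
        k_factors = select_n_factors(model, plsr_threshold)
        s_train = transform(model, X[train_idx], k_factors)
        s_test = transform(model, X[test_idx], k_factors)
        for kind in kinds:
            clf = train_classifier(kind, s_train, y[train_idx], classifier_params.get(kind))
            pred = clf.predict(s_test)
            c = confusion(y[test_idx], pred)
            pooled[kind] = ConfusionCounts(
                pooled[kind].tp + c.tp,
                pooled[kind].tn + c.tn,
                pooled[kind].fp + c.fp,
                pooled[kind].fn + c.fn,
            )
            per_repeat[kind].append(metrics(c))

    def mean_sd(values: list[float | None]) -> tuple[float | None, float | None]:
        vals = [v for v in values if v is not None]
        if not vals:
            return None, None
        return float(np.mean(vals)), float(np.std(vals))

    summaries = {}
    for kind in kinds:
        sens, spec, acc = zip(*per_repeat[kind])
        if exhaustive:
            # single sample per repeat: per-repeat rates are degenerate,
            # report the pooled leave-one-out confusion instead
            p_sens, p_spec, p_acc = metrics(pooled[kind])
            summaries[kind] = ClassifierSummary(
                accuracy_mean=p_acc,
                accuracy_sd=0.0,
                sensitivity_mean=p_sens,
                sensitivity_sd=0.0 if p_sens is not None else None,
                specificity_mean=p_spec,
                specificity_sd=0.0 if p_spec is not None else None,
                confusion_total=pooled[kind],
            )
        else:
            am, asd = mean_sd(list(acc))
            sm, ssd = mean_sd(list(sens))
            pm, psd = mean_sd(list(spec))
            summaries[kind] = ClassifierSummary(
                accuracy_mean=am,
                accuracy_sd=asd,
                sensitivity_mean=sm,
                sensitivity_sd=ssd,
                specificity_mean=pm,
                specificity_sd=psd,
                confusion_total=pooled[kind],
            )

    return EvalReport(
        per_classifier=summaries,
        m=m,
        n_train=n - m,
        n_test=m,
        n_repeats=n_splits,
    )
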