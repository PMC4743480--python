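"""Validation statistics and data-splitting schemes for binary CSPR models.

Implements the four classification statistics used throughout the pipeline
(accuracy, sensitivity, specificity and the Matthews correlation coefficient),
confusion-matrix accounting, the PCA-guided 85/15 train/test split and pooled
10-fold cross-validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion matrix: TP/FP/FN/TN counts.

    The positive class is whichever label was declared positive when the
    matrix was tallied; all four cells are nonnegative and partition the
    evaluated rows.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """The four model statistics.

    accuracy, sensitivity and specificity are percentages in [0, 100];
    MCC is dimensionless in [-1, 1].  A sensitivity or specificity whose
    denominator is zero is reported as NaN (missing) with a warning.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
        }


def confusion(predictions, truths, positive_class) -> ConfusionMatrix:
    """Tally a binary confusion matrix against a declared positive class.

    Every truth/prediction label must be either the positive class or the
    (single) other label present; unknown third labels raise.
    """
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    labels = set(predictions) | set(truths)
    extra = labels - {positive_class}
    if len(extra) > 1:
        raise ValueError(f"more than two labels present: {sorted(map(str, labels))}")
    tp = fp = fn = tn = 0
    for p, t in zip(predictions, truths):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Compute accuracy, sensitivity, specificity (percentages) and MCC.

    accuracy    = 100 * (TP + TN) / N
    sensitivity = 100 * TP / (TP + FN)        (true positive rate)
    specificity = 100 * TN / (TN + FP)        (true negative rate)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

    Any zero factor in the MCC denominator defines MCC = 0.  A zero
    sensitivity/specificity denominator yields NaN with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    accuracy = 100.0 * (tp + tn) / cm.total
    if tp + fn > 0:
        sensitivity = 100.0 * tp / (tp + fn)
    else:
        warnings.warn("no positive rows: sensitivity undefined", stacklevel=2)
        sensitivity = float("nan")
    if tn + fp > 0:
        specificity = 100.0 * tn / (tn + fp)
    else:
        warnings.warn("no negative rows: specificity undefined", stacklevel=2)
        specificity = float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, mcc=mcc)


@dataclass(frozen=True)
class SplitPlan:
    """Train/test row-id partition with its provenance (seed, method tag)."""

    train_ids: tuple
    test_ids: tuple
    seed: int
    method: str = "pca_stratified"

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def _train_size(n: int, train_fraction: float) -> int:
    # single rounding rule: |train| = floor(f*n + 0.5)
    return int(math.floor(train_fraction * n + 0.5))


def pca_random_split(X, labels, ids=None, train_fraction: float = 0.85,
                     seed: int = 0, n_strata: int = 10) -> SplitPlan:
    """PCA-guided stratified random split into train/test fractions.

    Per class: features are z-scored, projected onto the first principal
    component, PC1 is binned into up to ``n_strata`` equal-frequency strata,
    and the test fraction is sampled uniformly within each stratum so the
    test set covers the class's principal spread.  Classes too small to
    stratify (< 7 rows) fall back to a plain seeded random split.

    Returns a :class:`SplitPlan`; per class |train| = floor(f*n + 0.5).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for cls in pd.unique(labels):
        mask = labels == cls
        cls_ids = ids[mask]
        n_cls = len(cls_ids)
        n_train = _train_size(n_cls, train_fraction)
        n_test = n_cls - n_train
        if n_cls < 7:
            warnings.warn(
                f"class {cls!r} too small to stratify; plain random split",
                stacklevel=2)
            perm = rng.permutation(n_cls)
            test_idx = perm[:n_test]
        else:
            Xc = X[mask]
            mu, sd = Xc.mean(axis=0), Xc.std(axis=0)
            sd[sd == 0] = 1.0
            Z = (Xc - mu) / sd
            pc1 = PCA(n_components=1, svd_solver="full").fit_transform(Z)[:, 0]
            k = min(n_strata, n_cls)
            strata = pd.qcut(pd.Series(pc1).rank(method="first"), k,
                             labels=False).to_numpy()
            test_idx = _sample_within_strata(strata, n_test, rng)
        test_mask = np.zeros(n_cls, dtype=bool)
        test_mask[test_idx] = True
        test_ids.extend(cls_ids[test_mask])
        train_ids.extend(cls_ids[~test_mask])
    return SplitPlan(train_ids=tuple(train_ids), test_ids=tuple(test_ids),
                     seed=seed)


def _sample_within_strata(strata: np.ndarray, n_test: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of n_test picks across strata, then
    uniform sampling without replacement inside each stratum."""
    uniq, counts = np.unique(strata, return_counts=True)
    quota = counts * n_test / counts.sum()
    take = np.floor(quota).astype(int)
    rem = quota - take
    short = n_test - take.sum()
    for j in np.argsort(-rem)[:short]:
        take[j] += 1
    picks = []
    for s, t in zip(uniq, take):
        members = np.flatnonzero(strata == s)
        if t > 0:
            picks.extend(rng.choice(members, size=min(t, len(members)),
                                    replace=False))
    picks = np.asarray(picks, dtype=int)
    # pad if rounding starved a stratum beyond its size
    if len(picks) < n_test:
        pool = np.setdiff1d(np.arange(len(strata)), picks)
        picks = np.concatenate([picks, rng.choice(pool, n_test - len(picks),
                                                  replace=False)])
    return picks


@dataclass
class CVResult:
    """Pooled cross-validation outcome: one confusion matrix over all folds."""

    report: MetricsReport
    cm: ConfusionMatrix
    fold_test_indices: list = field(default_factory=list)


def kfold_cv(estimator, X, y, positive_class, k: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation with pooled predictions.

    Each row is predicted exactly once (by the model trained on the other
    k-1 folds); all predictions are pooled into a single confusion matrix
    and the four statistics are computed from it (not averaged per fold).
    """
    from sklearn.base import clone

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < k:
        raise ValueError(f"n={n} < k={k}")
    _, class_counts = np.unique(y, return_counts=True)
    if k > class_counts.min():
        # leave-one-out and near-LOO regimes cannot be stratified
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.empty(n, dtype=y.dtype)
    folds = []
    for train_idx, test_idx in splitter.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            warnings.warn("a class is absent from a training fold", stacklevel=2)
        model = clone(estimator)
        model.fit(X[train_idx], y[train_idx])
        preds[test_idx] = model.predict(X[test_idx])
        folds.append(test_idx)
    cm = confusion(preds, y, positive_class)
    return CVResult(report=metrics(cm), cm=cm, fold_test_indices=folds)
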