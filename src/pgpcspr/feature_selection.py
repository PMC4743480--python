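"""Collinearity-based descriptor selection.

Computes the Pearson intercorrelation matrix of the descriptor table and
greedily discards one member of every descriptor pair whose |r| meets the
cutoff (default 0.7): columns are scanned left to right, and each surviving
column removes any later column collinear with it.  The kept set therefore
contains no pair at or above the cutoff, and re-running the pruner on the
kept set is a no-op.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with its feature names."""

    names: tuple
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.names),
                            columns=list(self.names))


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of the greedy scan: kept names and (removed, partner, r)."""

    kept: tuple
    removed: tuple  # of (feature, partner, r)
    cutoff: float

    @property
    def removed_names(self) -> tuple:
        return tuple(f for f, _, _ in self.removed)


def pearson_matrix(X, names=None) -> CorrelationMatrix:
    """Pearson correlation matrix of a numeric table (>= 3 rows).

    Constant columns have undefined correlations; they are defined as 0
    against every other column (with a warning), keeping the diagonal 1.
    """
    if hasattr(X, "columns"):
        if names is None:
            names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, d = X.shape
    if n < 3:
        raise ValueError(f"need >= 3 rows to correlate, got {n}")
    if np.isnan(X).any():
        raise ValueError("missing values are not allowed")
    if names is None:
        names = [f"x{j}" for j in range(d)]
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant column(s) {[names[j] for j in np.flatnonzero(constant)]}: "
            "correlations defined as 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    if d == 1:
        R = np.array([[1.0]])
    R[np.isnan(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(names=tuple(names), values=R)


def prune_collinear(matrix: CorrelationMatrix, cutoff: float = 0.7) -> SelectionReport:
    """Greedy left-to-right removal of collinear features at |r| >= cutoff."""
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must be in (0, 1]")
    R = np.abs(matrix.values)
    d = len(matrix.names)
    alive = np.ones(d, dtype=bool)
    removed = []
    for i in range(d):
        if not alive[i]:
            continue
        for j in range(i + 1, d):
            if alive[j] and R[i, j] >= cutoff:
                alive[j] = False
                removed.append((matrix.names[j], matrix.names[i],
                                float(matrix.values[i, j])))
    kept = tuple(matrix.names[i] for i in range(d) if alive[i])
    return SelectionReport(kept=kept, removed=tuple(removed), cutoff=cutoff)


class CollinearityPruner(SelectorMixin, BaseEstimator):
    """Feature selector removing descriptors collinear at |r| >= cutoff.

    Parameters
    ----------
    cutoff : float, default 0.7
        Absolute Pearson-r threshold; of each collinear pair the later
        column (in table order) is discarded.

    Attributes
    ----------
    correlation_ : CorrelationMatrix
    report_ : SelectionReport
    support_ : boolean mask of kept columns
    """

    def __init__(self, cutoff: float = 0.7):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        names = ([str(c) for c in X.columns] if hasattr(X, "columns") else None)
        self.correlation_ = pearson_matrix(X, names=names)
        self.report_ = prune_collinear(self.correlation_, cutoff=self.cutoff)
        kept = set(self.report_.kept)
        self.support_ = np.array([n in kept for n in self.correlation_.names])
        self.n_features_in_ = len(self.correlation_.names)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if hasattr(X, "columns"):
            return X.loc[:, list(self.report_.kept)]
        return np.asarray(X)[:, self.support_]
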