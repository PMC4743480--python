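"""Gain-ratio decision-tree induction with rule extraction.

A C4.5-family inducer for numeric descriptors: binary splits chosen by
information gain ratio, candidate thresholds at midpoints between adjacent
distinct sorted values where the class composition changes (boundary points),
growth until purity or a minimum leaf size, and optional pessimistic-error
pruning at a configurable confidence level.  The fitted tree exposes its
if-then rules, the interpretable artifact the whole pipeline is built for.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

_EPS = 1e-12


@dataclass
class TreeNode:
    """One tree node.

    Internal nodes carry a feature index/name and a numeric threshold
    (rows with value <= threshold go left); leaves carry the majority
    class and the per-class counts of the training rows routed there.
    """

    distribution: dict
    feature: int | None = None
    feature_name: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    klass: object = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n(self) -> int:
        return sum(self.distribution.values())

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            yield from self.left.leaves()
            yield from self.right.leaves()


@dataclass
class Rule:
    """Conjunctive if-then rule: conditions -> class, with leaf support."""

    conditions: tuple  # of (feature_name, op in {"<=", ">"}, threshold)
    klass: object
    support: int

    def matches(self, row: dict) -> bool:
        for name, op, thr in self.conditions:
            v = row[name]
            if op == "<=" and not v <= thr:
                return False
            if op == ">" and not v > thr:
                return False
        return True


def _entropy(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) along the last axis of a count array."""
    total = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, counts / np.maximum(total, 1), 0.0)
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=-1)


def _pessimistic_upper(errors: float, n: float, confidence: float) -> float:
    """Upper confidence bound on the true error rate of a leaf.

    The C4.5 pessimistic estimate: for zero observed errors the exact
    binomial bound 1 - CF**(1/n); otherwise the normal-approximation
    upper limit at the one-sided CF level.
    """
    if n <= 0:
        return 0.0
    if errors == 0:
        return 1.0 - confidence ** (1.0 / n)
    z = norm.isf(confidence)
    f = errors / n
    z2 = z * z
    num = f + z2 / (2 * n) + z * np.sqrt(f / n - f * f / n + z2 / (4 * n * n))
    return min(1.0, num / (1.0 + z2 / n))


class GainRatioTreeClassifier(ClassifierMixin, BaseEstimator):
    """Binary-split decision tree classifier using the gain-ratio criterion.

    Parameters
    ----------
    min_leaf : int, default 2
        Minimum number of training rows in each child of a split.
    prune : bool, default True
        Apply bottom-up pessimistic-error pruning after growth.
    confidence : float, default 0.25
        Confidence level of the pessimistic error bound (smaller prunes
        more aggressively).
    feature_names : sequence of str, optional
        Column names used in extracted rules; defaults to x0..x{d-1} or,
        for DataFrame input, the DataFrame columns.

    Attributes
    ----------
    root_ : TreeNode
        The induced (and possibly pruned) tree.
    classes_ : ndarray
        Sorted class labels.
    feature_names_ : list of str
        Resolved feature names.
    n_leaves_ : int
    """

    def __init__(self, min_leaf: int = 2, prune: bool = True,
                 confidence: float = 0.25, feature_names=None):
        self.min_leaf = min_leaf
        self.prune = prune
        self.confidence = confidence
        self.feature_names = feature_names

    # ---- induction -----------------------------------------------------

    def fit(self, X, y):
        names = self.feature_names
        if names is None and hasattr(X, "columns"):
            names = [str(c) for c in X.columns]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D numeric table")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] < 1:
            raise ValueError("empty training set")
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        self.feature_names_ = (list(names) if names is not None
                               else [f"x{j}" for j in range(X.shape[1])])
        if len(self.feature_names_) != X.shape[1]:
            raise ValueError("feature_names length mismatch")
        self.n_features_in_ = X.shape[1]
        self.root_ = self._grow(X, y_codes)
        if self.prune:
            self._prune_node(self.root_)
        self.n_leaves_ = sum(1 for _ in self.root_.leaves())
        return self

    def _distribution(self, y_codes: np.ndarray) -> dict:
        counts = np.bincount(y_codes, minlength=len(self.classes_))
        return {self.classes_[c].item() if hasattr(self.classes_[c], "item")
                else self.classes_[c]: int(counts[c])
                for c in range(len(self.classes_))}

    def _leaf(self, y_codes: np.ndarray) -> TreeNode:
        counts = np.bincount(y_codes, minlength=len(self.classes_))
        klass = self.classes_[int(np.argmax(counts))]  # tie -> lower index
        return TreeNode(distribution=self._distribution(y_codes), klass=klass)

    def _grow(self, X: np.ndarray, y_codes: np.ndarray) -> TreeNode:
        if len(np.unique(y_codes)) <= 1 or len(y_codes) < 2 * self.min_leaf:
            return self._leaf(y_codes)
        split = best_split(X, y_codes, n_classes=len(self.classes_),
                           min_leaf=self.min_leaf)
        if split is None:
            return self._leaf(y_codes)
        j, thr, _ = split
        mask = X[:, j] <= thr
        node = TreeNode(distribution=self._distribution(y_codes),
                        feature=j, feature_name=self.feature_names_[j],
                        threshold=thr,
                        left=self._grow(X[mask], y_codes[mask]),
                        right=self._grow(X[~mask], y_codes[~mask]))
        node.klass = self._leaf(y_codes).klass
        return node

    # ---- pruning -------------------------------------------------------

    def _node_errors_as_leaf(self, node: TreeNode) -> float:
        n = node.n
        e = n - max(node.distribution.values())
        return n * _pessimistic_upper(e, n, self.confidence)

    def _prune_node(self, node: TreeNode) -> float:
        """Return the pessimistic error estimate of the (pruned) subtree."""
        if node.is_leaf:
            return self._node_errors_as_leaf(node)
        subtree = self._prune_node(node.left) + self._prune_node(node.right)
        as_leaf = self._node_errors_as_leaf(node)
        if as_leaf <= subtree + _EPS:
            node.left = node.right = None
            node.feature = node.feature_name = node.threshold = None
            return as_leaf
        return subtree

    # ---- prediction ----------------------------------------------------

    def predict(self, X):
        check_is_fitted(self, "root_")
        if hasattr(X, "columns"):
            missing = [n for n in self.feature_names_ if n not in X.columns]
            if missing:
                raise KeyError(f"missing feature(s): {missing}")
            X = X[self.feature_names_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        out = [self._route(self.root_, row).klass for row in X]
        return np.asarray(out, dtype=self.classes_.dtype)

    def predict_record(self, row: dict):
        """Predict a single record given as a feature-name mapping."""
        check_is_fitted(self, "root_")
        node = self.root_
        while not node.is_leaf:
            if node.feature_name not in row:
                raise KeyError(f"missing feature: {node.feature_name}")
            node = (node.left if row[node.feature_name] <= node.threshold
                    else node.right)
        return node.klass

    @staticmethod
    def _route(node: TreeNode, row: np.ndarray) -> TreeNode:
        while not node.is_leaf:
            node = node.left if row[node.feature] <= node.threshold else node.right
        return node

    # ---- rules ---------------------------------------------------------

    def extract_rules(self) -> list[Rule]:
        """One conjunctive rule per leaf, in left-to-right tree order.

        The rules are mutually exclusive and exhaustive over feature space:
        every point satisfies exactly one rule.
        """
        check_is_fitted(self, "root_")
        rules: list[Rule] = []

        def walk(node: TreeNode, conds: tuple):
            if node.is_leaf:
                rules.append(Rule(conditions=conds, klass=node.klass,
                                  support=node.n))
            else:
                walk(node.left, conds + ((node.feature_name, "<=", node.threshold),))
                walk(node.right, conds + ((node.feature_name, ">", node.threshold),))

        walk(self.root_, ())
        return rules

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "root_")

        def node_dict(node: TreeNode) -> dict:
            if node.is_leaf:
                return {"leaf": True, "class": str(node.klass),
                        "distribution": {str(k): v for k, v in
                                         node.distribution.items()}}
            return {"leaf": False, "feature": node.feature_name,
                    "threshold": node.threshold,
                    "distribution": {str(k): v for k, v in
                                     node.distribution.items()},
                    "left": node_dict(node.left),
                    "right": node_dict(node.right)}

        return {"algorithm": "gain_ratio_tree",
                "params": {"min_leaf": self.min_leaf, "prune": self.prune,
                           "confidence": self.confidence},
                "feature_names": self.feature_names_,
                "classes": [str(c) for c in self.classes_],
                "root": node_dict(self.root_)}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---- split search (shared with the exhaustive-oracle tests) -------------

def candidate_thresholds(x: np.ndarray, y_codes: np.ndarray) -> np.ndarray:
    """Boundary-point candidate thresholds for one feature.

    Midpoints between adjacent distinct sorted values whose class
    composition changes: a midpoint is a candidate unless the two value
    groups it separates are pure and share the same single class.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y_codes[order]
    vals, starts = np.unique(xs, return_index=True)
    if len(vals) < 2:
        return np.empty(0)
    ends = np.append(starts[1:], len(xs))
    pure_class = np.full(len(vals), -1)
    for g, (s, e) in enumerate(zip(starts, ends)):
        grp = ys[s:e]
        if (grp == grp[0]).all():
            pure_class[g] = grp[0]
    keep = ~((pure_class[:-1] >= 0)
             & (pure_class[:-1] == pure_class[1:]))
    return ((vals[:-1] + vals[1:]) / 2.0)[keep]


def _feature_scan(x: np.ndarray, y_codes: np.ndarray, n_classes: int,
                  min_leaf: int):
    """Boundary thresholds and their gain ratios for one feature.

    One sorted pass with cumulative class counts; zero-gain candidates
    stay eligible (growth stops at purity or min_leaf, and structures
    with no first-level gain — XOR-like — are only separable through a
    zero-gain root split).
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y_codes[order]
    vals, starts = np.unique(xs, return_index=True)
    if len(vals) < 2:
        return np.empty(0), np.empty(0)
    ends = np.append(starts[1:], n)
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    cum = onehot.cumsum(axis=0)
    run_counts = np.diff(np.vstack([np.zeros(n_classes), cum[ends - 1]]),
                         axis=0)
    run_pure = (run_counts > 0).sum(axis=1) == 1
    run_class = run_counts.argmax(axis=1)
    # boundary: adjacent value groups not both pure with the same class
    keep = ~(run_pure[:-1] & run_pure[1:]
             & (run_class[:-1] == run_class[1:]))
    left = cum[ends - 1][:-1][keep]
    if len(left) == 0:
        return np.empty(0), np.empty(0)
    thr = ((vals[:-1] + vals[1:]) / 2.0)[keep]
    nl = left.sum(axis=1)
    nr = n - nl
    total = cum[-1]
    parent = _entropy(total[None, :])[0]
    gain = np.maximum(
        parent - (nl / n) * _entropy(left) - (nr / n) * _entropy(total - left),
        0.0)
    pl, pr = nl / n, nr / n
    split_info = -(pl * np.log2(pl) + pr * np.log2(pr))
    gr = gain / split_info
    valid = (nl >= min_leaf) & (nr >= min_leaf)
    return thr[valid], gr[valid]


def split_scores(x: np.ndarray, y_codes: np.ndarray, thresholds: np.ndarray,
                 n_classes: int, min_leaf: int = 1):
    """Gain ratio of each given threshold (NaN where min_leaf violated)."""
    thr_all, gr_all = _feature_scan(x, y_codes, n_classes, min_leaf)
    out = np.full(len(thresholds), np.nan)
    for i, t in enumerate(np.asarray(thresholds, dtype=float)):
        hit = np.flatnonzero(np.isclose(thr_all, t))
        if len(hit):
            out[i] = gr_all[hit[0]]
    return out


def best_split(X: np.ndarray, y_codes: np.ndarray, n_classes: int,
               min_leaf: int = 1):
    """Best (feature, threshold, gain_ratio) over all boundary candidates.

    Ties break toward the lower column index, then the lower threshold.
    Returns None when no feature has a boundary candidate.
    """
    best = None
    for j in range(X.shape[1]):
        thrs, gr = _feature_scan(X[:, j], y_codes, n_classes, min_leaf)
        if len(thrs) == 0:
            continue
        i = int(np.argmax(gr))
        # within a feature, prefer the lowest threshold among exact ties
        i = int(np.flatnonzero(gr >= gr[i] - _EPS)[0])
        if best is None or gr[i] > best[2] + _EPS:
            best = (j, float(thrs[i]), float(gr[i]))
    return best


# ---- rule rendering / parsing -------------------------------------------

_RULE_RE = re.compile(
    r"^\s*(?:if (?P<conds>.+) then|always) (?P<klass>\S+)\s*\[n=(?P<n>\d+)\]\s*$")
_COND_RE = re.compile(r"^(?P<name>.+?) (?P<op><=|>) (?P<thr>[-+0-9.eE]+)$")


def render_rules(rules_or_model) -> str:
    """Render rules as indented if-then text, one line per leaf rule.

    Accepts a fitted :class:`GainRatioTreeClassifier` or a rule list.
    The format round-trips through :func:`parse_rules`.
    """
    rules = (rules_or_model.extract_rules()
             if hasattr(rules_or_model, "extract_rules") else rules_or_model)
    lines = []
    for r in rules:
        if r.conditions:
            conds = " and ".join(f"{n} {op} {thr!r}" for n, op, thr in r.conditions)
            lines.append(f"  if {conds} then {r.klass} [n={r.support}]")
        else:
            lines.append(f"  always {r.klass} [n={r.support}]")
    return "\n".join(lines)


def parse_rules(text: str) -> list[Rule]:
    """Inverse of :func:`render_rules`."""
    rules = []
    for line in text.splitlines():
        if not line.strip():
            continue
        m = _RULE_RE.match(line)
        if not m:
            raise ValueError(f"unparseable rule line: {line!r}")
        conds = []
        if m.group("conds"):
            for c in m.group("conds").split(" and "):
                cm = _COND_RE.match(c.strip())
                if not cm:
                    raise ValueError(f"unparseable condition: {c!r}")
                conds.append((cm.group("name"), cm.group("op"),
                              float(cm.group("thr"))))
        rules.append(Rule(conditions=tuple(conds), klass=m.group("klass"),
                          support=int(m.group("n"))))
    return rules


def train_decision_tree(X, y, min_leaf: int = 2, prune: bool = True,
                        confidence: float = 0.25,
                        feature_names=None) -> GainRatioTreeClassifier:
    """Thin functional wrapper over :class:`GainRatioTreeClassifier`."""
    return GainRatioTreeClassifier(min_leaf=min_leaf, prune=prune,
                                   confidence=confidence,
                                   feature_names=feature_names).fit(X, y)
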