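"""Class-imbalance correction by performance-driven FCM undersampling.

The majority (positive) class is split into k fuzzy C-means clusters,
k being derived from the class ratio; each cluster is joined with the full
negative class, scored by cross-validated decision-tree performance, and
the best-performing cluster (highest MCC, ties broken by accuracy, then
cluster size, then lower cluster id) becomes the representative positive
set.  This is undersampling by cluster selection: no synthetic rows are
ever created.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .descriptors import FeatureTable
from .fcm import FuzzyCMeans
from .metrics import MetricsReport, kfold_cv
from .tree import GainRatioTreeClassifier

log = logging.getLogger(__name__)


@dataclass
class ClusterEvaluation:
    """Cross-validated performance of one positive-class cluster."""

    cluster_id: int
    size: int
    metrics: MetricsReport
    selected: bool = False
    cv: str = "10-fold"


def choose_cluster_count(n_pos: int, n_neg: int) -> int:
    """Cluster count from the class ratio: k = max(2, ceil(n_pos/n_neg))."""
    if n_neg < 1:
        raise ValueError("need at least one negative sample")
    if n_pos < n_neg:
        raise ValueError("positive class is not the majority; skip balancing")
    return max(2, math.ceil(n_pos / n_neg))


class FCMUnderSampler(BaseEstimator):
    """Majority-class undersampler driven by FCM cluster performance.

    Parameters
    ----------
    k : int or "auto"
        Cluster count; "auto" derives it from the class ratio.
    m, tol, max_iter, n_init : FCM parameters (features are z-scored
        internally before clustering).
    estimator : classifier used to score clusters; defaults to the
        gain-ratio decision tree.
    cv : int, default 10
        Folds for cluster scoring (clusters smaller than ``cv`` fall
        back to leave-one-out, logged).
    random_state : int, default 0

    Attributes
    ----------
    evaluations_ : list of ClusterEvaluation (exactly one selected)
    selected_cluster_ : int
    cluster_labels_ : crisp cluster index per positive row
    k_ : the cluster count used
    """

    def __init__(self, k="auto", m: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 300, n_init: int = 5, estimator=None,
                 cv: int = 10, random_state: int = 0):
        self.k = k
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.estimator = estimator
        self.cv = cv
        self.random_state = random_state

    def fit_resample(self, positives: FeatureTable, negatives: FeatureTable
                     ) -> FeatureTable:
        """Cluster the positives, score each cluster, return the balanced
        table (selected cluster union all negatives)."""
        n_pos, n_neg = len(positives), len(negatives)
        if n_pos <= n_neg:
            raise ValueError("positives must outnumber negatives")
        if list(positives.columns) != list(negatives.columns):
            raise ValueError("positive/negative tables have different columns")
        k = (choose_cluster_count(n_pos, n_neg) if self.k == "auto"
             else int(self.k))
        pos_label = positives.labels[0]
        neg_label = negatives.labels[0]

        Xp = positives.X.to_numpy(dtype=float)
        mu, sd = Xp.mean(axis=0), Xp.std(axis=0)
        sd[sd == 0] = 1.0
        fcm = FuzzyCMeans(n_clusters=k, m=self.m, tol=self.tol,
                          max_iter=self.max_iter, n_init=self.n_init,
                          random_state=self.random_state).fit((Xp - mu) / sd)
        self.cluster_labels_ = fcm.labels_
        self.fcm_ = fcm
        self.k_ = k

        base = (self.estimator if self.estimator is not None
                else GainRatioTreeClassifier())
        self.evaluations_ = []
        for cid in range(k):
            members = np.flatnonzero(self.cluster_labels_ == cid)
            if len(members) == 0:
                log.warning("cluster %d is empty; skipped", cid)
                continue
            cluster_tbl = positives.subset(members)
            X = pd.concat([cluster_tbl.X, negatives.X], ignore_index=True)
            y = np.concatenate([cluster_tbl.labels, negatives.labels])
            n_eval = len(y)
            if len(members) < self.cv:
                folds, tag = n_eval, "leave-one-out"
                log.info("cluster %d has %d members (< %d): leave-one-out",
                         cid, len(members), self.cv)
            else:
                folds, tag = self.cv, f"{self.cv}-fold"
            res = kfold_cv(clone(base), X, y, positive_class=pos_label,
                           k=folds, seed=self.random_state)
            self.evaluations_.append(ClusterEvaluation(
                cluster_id=cid, size=len(members), metrics=res.report, cv=tag))

        if not self.evaluations_:
            raise RuntimeError("no non-empty cluster to evaluate")
        best = max(self.evaluations_,
                   key=lambda e: (e.metrics.mcc, e.metrics.accuracy, e.size,
                                  -e.cluster_id))
        best.selected = True
        self.selected_cluster_ = best.cluster_id

        keep = np.flatnonzero(self.cluster_labels_ == best.cluster_id)
        sel = positives.subset(keep)
        balanced = FeatureTable(
            X=pd.concat([sel.X, negatives.X], ignore_index=True),
            labels=np.concatenate([sel.labels, negatives.labels]),
            ids=list(sel.ids) + list(negatives.ids))
        self.balanced_ = balanced
        self.neg_label_ = neg_label
        return balanced

    def evaluation_frame(self) -> pd.DataFrame:
        """Cluster evaluation table (Table S1-shaped)."""
        rows = [{"cluster_id": e.cluster_id, "size": e.size,
                 "cv": e.cv, **e.metrics.as_dict(), "selected": e.selected}
                for e in self.evaluations_]
        return pd.DataFrame(rows)


def select_representative_cluster(positives: FeatureTable,
                                  negatives: FeatureTable,
                                  k="auto", m: float = 2.0,
                                  seed: int = 0, cv: int = 10
                                  ) -> tuple[list[ClusterEvaluation], FeatureTable]:
    """Functional wrapper over :class:`FCMUnderSampler`."""
    sampler = FCMUnderSampler(k=k, m=m, cv=cv, random_state=seed)
    balanced = sampler.fit_resample(positives, negatives)
    return sampler.evaluations_, balanced
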