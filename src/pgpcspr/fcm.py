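"""Fuzzy C-means clustering, implemented from its update equations.

FCM assigns each point a graded membership u_ij in [0, 1] to every cluster
(rows of the membership matrix sum to 1) and alternates the two updates

    u_ij = 1 / sum_c (d_ij / d_cj)^(2/(m-1))
    v_i  = sum_j u_ij^m x_j / sum_j u_ij^m

until the objective J = sum_ij u_ij^m ||x_j - v_i||^2 changes by less than a
tolerance.  The fuzzifier m > 1 controls membership softness; as m -> 1+ the
algorithm approaches crisp k-means.  Distances are Euclidean; callers are
expected to z-score features first (the balancing stage does).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class FCMResult:
    """Outcome of one FCM run: centers, memberships, objective, assignment."""

    centers: np.ndarray            # (k, d)
    membership: np.ndarray         # (n, k), rows sum to 1
    objective_trajectory: list     # J per iteration, non-increasing
    assignment: np.ndarray         # argmax membership per row
    n_iter: int


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy C-means clustering estimator.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k (>= 1).
    m : float, default 2.0
        Fuzzifier exponent (> 1); larger values give softer memberships.
    tol : float, default 1e-6
        Convergence tolerance on the change in the objective J.
    max_iter : int, default 300
        Iteration cap per restart.
    n_init : int, default 5
        Random membership restarts; the run with the lowest final J wins.
    random_state : int, default 0
    init_centers : array (k, d), optional
        Explicit initial centers; disables the random restarts.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (k, d)
    membership_ : ndarray of shape (n, k)
        Rows sum to 1 (within 1e-9).
    labels_ : ndarray of shape (n,)
        Crisp assignment (argmax membership).
    objective_trajectory_ : list of float
        Non-increasing J values of the winning restart.
    n_iter_ : int
    """

    def __init__(self, n_clusters: int = 2, m: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 300, n_init: int = 5, random_state: int = 0,
                 init_centers=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state
        self.init_centers = init_centers

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if X.shape[0] < self.n_clusters:
            raise ValueError(
                f"n={X.shape[0]} points cannot form k={self.n_clusters} clusters")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        rng = np.random.default_rng(self.random_state)
        best: FCMResult | None = None
        restarts = 1 if self.init_centers is not None else self.n_init
        for _ in range(restarts):
            res = self._run(X, rng)
            if best is None or res.objective_trajectory[-1] < best.objective_trajectory[-1]:
                best = res
        self.cluster_centers_ = best.centers
        self.membership_ = best.membership
        self.labels_ = best.assignment
        self.objective_trajectory_ = best.objective_trajectory
        self.n_iter_ = best.n_iter
        return self

    def _run(self, X: np.ndarray, rng: np.random.Generator) -> FCMResult:
        n, _ = X.shape
        k = self.n_clusters
        # seed centers at k distinct data points: a random membership
        # matrix would place every initial center at the global mean, a
        # degenerate fixed point the updates cannot escape in higher
        # dimensions
        if self.init_centers is not None:
            centers = np.asarray(self.init_centers, dtype=float)
            if centers.shape != (k, X.shape[1]):
                raise ValueError("init_centers must be (k, d)")
        else:
            centers = X[rng.choice(n, size=k, replace=False)]
        U = self._memberships(self._sqdist(X, centers))
        traj: list[float] = []
        it = 0
        for it in range(1, self.max_iter + 1):
            centers = self._centers(X, U)
            d2 = self._sqdist(X, centers)
            U = self._memberships(d2)
            J = float((U ** self.m * d2).sum())
            traj.append(J)
            if len(traj) >= 2 and abs(traj[-2] - traj[-1]) < self.tol:
                break
        centers = self._centers(X, U)
        return FCMResult(centers=centers, membership=U,
                         objective_trajectory=traj,
                         assignment=np.argmax(U, axis=1), n_iter=it)

    def _centers(self, X: np.ndarray, U: np.ndarray) -> np.ndarray:
        W = U ** self.m
        return (W.T @ X) / W.sum(axis=0)[:, None]

    @staticmethod
    def _sqdist(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        diff = X[:, None, :] - centers[None, :, :]
        return np.einsum("nkd,nkd->nk", diff, diff)

    def _memberships(self, d2: np.ndarray) -> np.ndarray:
        """Membership update; points coincident with a center get crisp
        membership split over the coincident centers (limit convention)."""
        exponent = 1.0 / (self.m - 1.0)
        zero = d2 <= 1e-300
        hit = zero.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = (1.0 / d2) ** exponent
            U = inv / inv.sum(axis=1, keepdims=True)
        if hit.any():
            U[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
        return U

    def predict(self, X):
        return np.argmax(self.soft_predict(X), axis=1)

    def soft_predict(self, X):
        """Membership matrix of new points against the fitted centers."""
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        return self._memberships(self._sqdist(X, self.cluster_centers_))

    def fit_result(self, X) -> FCMResult:
        """Fit and return the winning run as an :class:`FCMResult`."""
        self.fit(X)
        return FCMResult(centers=self.cluster_centers_,
                         membership=self.membership_,
                         objective_trajectory=self.objective_trajectory_,
                         assignment=self.labels_, n_iter=self.n_iter_)


def fcm_cluster(X, k: int, m: float = 2.0, tol: float = 1e-6,
                max_iter: int = 300, n_init: int = 5, seed: int = 0) -> FCMResult:
    """Functional wrapper over :class:`FuzzyCMeans`."""
    return FuzzyCMeans(n_clusters=k, m=m, tol=tol, max_iter=max_iter,
                       n_init=n_init, random_state=seed).fit_result(X)
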