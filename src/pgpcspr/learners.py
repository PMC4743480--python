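"""MLP and SVM learners behind the common train/predict contract.

Both delegate to scikit-learn; the pipeline-specific part is the inner
parameter-optimization loop: hyperparameters are chosen from a configurable
grid by stratified 10-fold cross-validated MCC on the training table, then
the winning configuration is refit on all training rows.  Features are
z-scored inside the model pipeline when ``standardize`` is set (both
learners want standardized inputs; the decision tree does not care).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import make_scorer, matthews_corrcoef
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .tree import GainRatioTreeClassifier

ALGORITHMS = ("tree", "mlp", "svm")


@dataclass
class LearnerConfig:
    """One learner: algorithm tag, hyperparameter grid, seed, scaling."""

    algorithm: str
    grid: dict = field(default_factory=dict)
    seed: int = 0
    standardize: bool = True
    cv: int = 10

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


def default_mlp_grid(n_features: int, n_classes: int = 2) -> dict:
    """One hidden layer sized (features+classes)/2 or features; two
    learning rates; 500 epochs."""
    a = max(2, (n_features + n_classes) // 2)
    return {"hidden_layer_sizes": [(a,), (n_features,)],
            "learning_rate_init": [0.3, 0.1]}


def default_svm_grid() -> dict:
    return {"kernel": ["rbf", "linear"],
            "C": [0.1, 1.0, 10.0, 100.0],
            "gamma": [0.01, 0.1, 1.0]}


def _wrap(est, standardize: bool, prefix: str):
    if standardize:
        return Pipeline([("scale", StandardScaler()), (prefix, est)])
    return Pipeline([(prefix, est)])


def _tune(pipe: Pipeline, grid: dict, prefix: str, X, y,
          cv: int, seed: int) -> GridSearchCV:
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    grid = {f"{prefix}__{k}": list(v) for k, v in grid.items()}
    if any(len(v) == 0 for v in grid.values()):
        raise ValueError("degenerate hyperparameter grid")
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    folds = min(cv, counts.min())
    search = GridSearchCV(
        pipe, grid,
        scoring=make_scorer(matthews_corrcoef),
        cv=StratifiedKFold(n_splits=max(2, folds), shuffle=True,
                           random_state=seed),
        refit=True, n_jobs=None)
    search.fit(np.asarray(X, dtype=float), y)
    return search


def train_mlp(X, y, config: LearnerConfig | None = None):
    """Grid-searched MLP classifier; returns the fitted search object
    (``.best_params_`` reports the chosen hyperparameters)."""
    config = config or LearnerConfig("mlp")
    n_features = np.asarray(X).shape[1]
    grid = config.grid or default_mlp_grid(n_features, len(np.unique(y)))
    est = MLPClassifier(max_iter=500, solver="sgd", random_state=config.seed)
    pipe = _wrap(est, config.standardize, "mlp")
    return _tune(pipe, grid, "mlp", X, y, config.cv, config.seed)


def train_svm(X, y, config: LearnerConfig | None = None):
    """Grid-searched SVM classifier (RBF/linear kernels by default)."""
    config = config or LearnerConfig("svm")
    grid = config.grid or default_svm_grid()
    est = SVC(random_state=config.seed)
    pipe = _wrap(est, config.standardize, "svm")
    return _tune(pipe, grid, "svm", X, y, config.cv, config.seed)


def make_learner(config: LearnerConfig):
    """Unfitted estimator for cross-validation under the common contract."""
    if config.algorithm == "tree":
        params = dict(config.grid) if config.grid else {}
        return GainRatioTreeClassifier(**params)
    if config.algorithm == "mlp":
        est = MLPClassifier(max_iter=500, solver="sgd",
                            random_state=config.seed)
    else:
        est = SVC(random_state=config.seed)
    if config.grid:
        first = {k: (v[0] if isinstance(v, (list, tuple)) else v)
                 for k, v in config.grid.items()}
        est.set_params(**first)
    return _wrap(est, config.standardize, config.algorithm)


def train_learner(X, y, config: LearnerConfig):
    """Dispatch on the algorithm tag; returns a fitted model with
    ``predict`` and, for tuned learners, ``best_params_``."""
    if config.algorithm == "tree":
        params = dict(config.grid) if config.grid else {}
        return GainRatioTreeClassifier(**params).fit(X, y)
    if config.algorithm == "mlp":
        return train_mlp(X, y, config)
    return train_svm(X, y, config)
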