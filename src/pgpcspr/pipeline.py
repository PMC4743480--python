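"""End-to-end pipeline orchestration and report rendering.

Runs the four stages in order — dataset preparation, descriptor/feature
selection, imbalance correction, multivariate analysis — writing every
intermediate artifact to the output directory, and renders the
paper-shaped outputs: the per-class census, the correlation/selection
report, the cluster-evaluation table, per-learner metric tables
(training / 10-fold CV / external) and the decision tree's if-then rules.
Reports are deterministic: rerunning the same config and seed reproduces
the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import curation
from .balancing import FCMUnderSampler
from .descriptors import FeatureTable, attach_quantum_block, build_feature_table
from .feature_selection import CollinearityPruner
from .learners import LearnerConfig, make_learner, train_learner
from .metrics import confusion, kfold_cv, metrics, pca_random_split
from .synthetic import Subpopulation, SyntheticSpec, generate_feature_table
from .tree import GainRatioTreeClassifier, render_rules

log = logging.getLogger(__name__)

TASKS = {
    "inhibitor": ("inhibitor", "non_inhibitor"),
    "substrate": ("substrate", "non_substrate"),
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """A pipeline stage failed on the data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """Flat, diffable pipeline configuration.

    Either ``input_csv`` (curated-schema compound list) or ``synthetic``
    must be given.  Thresholds are validated against their documented
    ranges before any stage runs.
    """

    seed: int
    out_dir: str = "pgpcspr_out"
    task: str = "inhibitor"
    input_csv: str | None = None
    quantum_csv: str | None = None
    synthetic: SyntheticSpec | None = None
    mw_limit: float = 1000.0
    correlation_cutoff: float = 0.7
    train_fraction: float = 0.85
    k_folds: int = 10
    fcm_m: float = 2.0
    learners: tuple = ("tree",)
    learner_grids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ConfigError(f"task must be one of {sorted(TASKS)}")
        if not (0.0 < self.correlation_cutoff <= 1.0):
            raise ConfigError("correlation_cutoff must be in (0, 1]")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.mw_limit <= 0:
            raise ConfigError("mw_limit must be positive")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        if self.fcm_m <= 1:
            raise ConfigError("fcm_m must be > 1")
        if self.input_csv is None and self.synthetic is None:
            raise ConfigError("either input_csv or synthetic must be set")
        for alg in self.learners:
            if alg not in ("tree", "mlp", "svm"):
                raise ConfigError(f"unknown learner {alg!r}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        if syn is not None:
            subs = tuple(Subpopulation(**s)
                         for s in syn.pop("pos_subpopulations", [{"weight": 1.0}]))
            pairs = tuple(tuple(p) for p in syn.pop("collinear_pairs", []))
            syn = SyntheticSpec(pos_subpopulations=subs, collinear_pairs=pairs,
                                **syn)
        try:
            return cls(synthetic=syn, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _round3(x: float) -> float:
    return float(f"{x:.3f}") if np.isfinite(x) else float("nan")


def _report_row(rep) -> dict:
    return {k: _round3(v) for k, v in rep.as_dict().items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written to
    ``report.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": {"config_hash": config.digest(),
                                   "seed": config.seed,
                                   "task": config.task}}
    pos_label, neg_label = TASKS[config.task]

    # stage 1: dataset preparation
    try:
        if config.synthetic is not None:
            table, truth = generate_feature_table(config.synthetic)
            truth.to_json(out / "ground_truth.json")
            pos_label = config.synthetic.pos_label
            neg_label = config.synthetic.neg_label
            census = {pos_label: int((table.labels == pos_label).sum()),
                      neg_label: int((table.labels == neg_label).sum()),
                      "total": len(table)}
        else:
            records = curation.read_records(config.input_csv)
            dataset = curation.curate(records, mw_limit=config.mw_limit)
            curation.write_curated(dataset, out)
            census = dataset.census
            table = build_feature_table(dataset)
            if config.quantum_csv:
                table = attach_quantum_block(table, config.quantum_csv)
            keep = np.isin(table.labels, [pos_label, neg_label])
            table = table.subset(keep)
    except (ValueError, KeyError) as exc:
        raise DataError(f"stage=data_preparation: {exc}") from exc
    report["census"] = census
    table.to_csv(out / "features.csv")
    log.info("stage data_preparation: %d rows, seed=%d", len(table), config.seed)

    # stage 2: feature selection
    pruner = CollinearityPruner(cutoff=config.correlation_cutoff).fit(table.X)
    pruner.correlation_.to_frame().to_csv(out / "correlation.csv")
    selection = {"kept": list(pruner.report_.kept),
                 "removed": [{"feature": f, "partner": p, "r": _round3(r)}
                             for f, p, r in pruner.report_.removed],
                 "cutoff": config.correlation_cutoff}
    (out / "selection.json").write_text(json.dumps(selection, indent=2) + "\n")
    report["selection"] = selection
    table = FeatureTable(X=pruner.transform(table.X), labels=table.labels,
                         ids=table.ids)
    log.info("stage feature_selection: kept %d of %d columns",
             len(pruner.report_.kept), pruner.n_features_in_)

    # stage 3: imbalance correction
    pos = table.subset(table.labels == pos_label)
    neg = table.subset(table.labels == neg_label)
    if len(pos) == 0 or len(neg) == 0:
        raise DataError(f"stage=balancing: task {config.task!r} needs both "
                        f"{pos_label!r} and {neg_label!r} rows")
    if len(pos) > len(neg):
        sampler = FCMUnderSampler(m=config.fcm_m, cv=config.k_folds,
                                  random_state=config.seed)
        balanced = sampler.fit_resample(pos, neg)
        eval_frame = sampler.evaluation_frame()
        eval_frame.to_csv(out / "cluster_evaluation.csv", index=False,
                          float_format="%.3f")
        report["balancing"] = {
            "skipped": False, "k": sampler.k_,
            "selected_cluster": sampler.selected_cluster_,
            "selected_size": int(eval_frame.loc[eval_frame.selected, "size"].iloc[0]),
            "evaluations": json.loads(
                eval_frame.round(3).to_json(orient="records"))}
    else:
        balanced = table
        report["balancing"] = {"skipped": True,
                               "reason": "positive class does not outnumber "
                                         "the negative class"}
        log.info("stage balancing skipped: %d positives vs %d negatives",
                 len(pos), len(neg))
    balanced.to_csv(out / "balanced.csv")

    # stage 4: multivariate analysis
    plan = pca_random_split(balanced.X.to_numpy(float), balanced.labels,
                            ids=np.arange(len(balanced)),
                            train_fraction=config.train_fraction,
                            seed=config.seed)
    pd.DataFrame({
        "row": list(plan.train_ids) + list(plan.test_ids),
        "role": ["train"] * len(plan.train_ids) + ["test"] * len(plan.test_ids),
    }).to_csv(out / "split.csv", index=False)
    train = balanced.subset(np.asarray(plan.train_ids, dtype=int))
    test = balanced.subset(np.asarray(plan.test_ids, dtype=int))

    report["models"] = {}
    for alg in config.learners:
        lc = LearnerConfig(algorithm=alg,
                           grid=config.learner_grids.get(alg, {}),
                           seed=config.seed, cv=config.k_folds,
                           standardize=alg != "tree")
        model = train_learner(train.X, train.labels, lc)
        rows = {}
        pred_tr = model.predict(train.X.to_numpy(float))
        rows["training"] = _report_row(
            metrics(confusion(pred_tr, train.labels, pos_label)))
        cv_res = kfold_cv(make_learner(lc) if alg == "tree" else model,
                          train.X, train.labels, positive_class=pos_label,
                          k=config.k_folds, seed=config.seed)
        rows["cv"] = _report_row(cv_res.report)
        pred_ext = model.predict(test.X.to_numpy(float))
        rows["external"] = _report_row(
            metrics(confusion(pred_ext, test.labels, pos_label)))
        entry: dict = {"metrics": rows}
        if isinstance(model, GainRatioTreeClassifier):
            rules_text = render_rules(model)
            (out / "rules.txt").write_text(rules_text + "\n")
            (out / "tree.json").write_text(model.to_json(indent=2) + "\n")
            entry["rules"] = rules_text.splitlines()
        elif hasattr(model, "best_params_"):
            entry["chosen_hyperparameters"] = {
                k.split("__", 1)[1]: v for k, v in model.best_params_.items()}
        report["models"][alg] = entry
        pd.DataFrame(rows).T.to_csv(out / f"metrics_{alg}.csv",
                                    float_format="%.3f")

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
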