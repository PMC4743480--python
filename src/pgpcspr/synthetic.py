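"""Synthetic feature tables and molecule fixtures.

Generates binary-labeled numeric descriptor tables with the statistical
structure the pipeline assumes — Gaussian class-conditional features with a
tunable class separation, planted collinear column pairs to exercise the
pruner, class imbalance at configurable ratios, and a positive class built
from subpopulations of differing label quality to exercise FCM cluster
selection — plus a small set of hand-verified molecule fixtures for the
descriptor stage.  All randomness flows from the single spec seed.

The generated columns mimic descriptor scales (a subset is rounded to
nonnegative integers, like the count descriptors) but make no attempt to
simulate realistic chemistry: the joint distributions are Gaussian
surrogates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import FeatureTable

# per-column scale palette cycled over the generated features:
# (mean, sd, integer-typed)
_SCALE_PALETTE = (
    (350.0, 120.0, False),   # MW-like
    (5.0, 3.0, True),        # rotatable-bond-like count
    (2.0, 1.5, True),        # ring-like count
    (2.0, 1.8, True),        # donor-like count
    (5.0, 2.5, True),        # acceptor-like count
    (2.5, 1.8, False),       # logP-like
    (80.0, 40.0, False),     # TPSA-like
    (0.15, 0.05, False),     # mean-charge-like
    (-5500.0, 1500.0, False),  # energy-like
    (4.0, 2.0, False),       # dipole-like
    (-9.0, 1.0, False),      # orbital-energy-like
)


@dataclass(frozen=True)
class Subpopulation:
    """One positive-class subpopulation: mixing weight and label quality."""

    weight: float
    label_noise_rate: float = 0.0


@dataclass
class SyntheticSpec:
    """Generator configuration.

    Parameters
    ----------
    n_pos, n_neg : class sizes (positive = majority class by convention
        of the imbalanced scenario).
    n_features : base feature count before planted collinear columns.
    delta : class mean separation, applied to every feature, in units of
        the pooled within-class SD.
    collinear_pairs : (source column name, target |r|) for each planted
        redundant column; target |r| must exceed the pruning cutoff
        (i.e. lie in (0.7, 1]).
    pos_subpopulations : mixture components of the positive class.
    subpop_separation : Euclidean offset (pooled-SD units, spread over
        all features) between adjacent subpopulations, so clustering
        can tell them apart.
    seed : the single source of randomness.
    """

    n_pos: int = 300
    n_neg: int = 200
    n_features: int = 11
    delta: float = 2.0
    collinear_pairs: tuple = ()
    pos_subpopulations: tuple = (Subpopulation(weight=1.0),)
    subpop_separation: float = 6.0
    seed: int = 0
    pos_label: str = "inhibitor"
    neg_label: str = "non_inhibitor"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        subs = tuple(s if isinstance(s, Subpopulation) else Subpopulation(**s)
                     for s in self.pos_subpopulations)
        self.pos_subpopulations = subs
        if abs(sum(s.weight for s in subs) - 1.0) > 1e-9:
            raise ValueError("subpopulation weights must sum to 1")
        if any(not (0.0 <= s.label_noise_rate <= 0.5) for s in subs):
            raise ValueError("label noise rates must be in [0, 0.5]")
        for src, r in self.collinear_pairs:
            if not (0.7 < abs(r) <= 1.0):
                raise ValueError(f"target |r| for {src} must be in (0.7, 1]")
        if len(self.collinear_pairs) > self.n_features:
            raise ValueError("more planted columns than base features")

    def feature_names(self) -> list[str]:
        return [f"f{j + 1:02d}" for j in range(self.n_features)]


@dataclass
class GroundTruth:
    """What the generator planted, serialized beside each table."""

    class_means: dict                 # label -> per-column mean (standardized units)
    planted_columns: dict             # planted name -> {"source", "target_r"}
    subpopulation: list               # subpop index per positive row (table order)
    noise_rows: list                  # positive row ids drawn from the negative dist.
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _allocate(n: int, weights: list[float]) -> np.ndarray:
    """Largest-remainder integer allocation of n rows across weights."""
    quota = np.asarray(weights) * n
    take = np.floor(quota).astype(int)
    rem = quota - take
    for j in np.argsort(-rem)[: n - take.sum()]:
        take[j] += 1
    return take


def generate_feature_table(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Generate one labeled feature table per the spec.

    Features are class-conditional Gaussians in standardized units
    (negative mean 0, positive mean ``delta``), mapped to descriptor-like
    scales; planted collinear columns are built as
    y = r*x_std + sqrt(1-r^2)*noise and appended after the base columns.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.feature_names()
    d = spec.n_features
    subs = spec.pos_subpopulations

    counts = _allocate(spec.n_pos, [s.weight for s in subs])
    sub_assign = np.repeat(np.arange(len(subs)), counts)
    rng.shuffle(sub_assign)

    Z_pos = rng.standard_normal((spec.n_pos, d)) + spec.delta
    S = len(subs)
    # subpopulation offsets are spread over every feature (a single-axis
    # offset would be normalized away by per-feature z-scoring downstream)
    # and ordered so that noisier subpopulations sit closer to the
    # negative class
    rank = np.argsort(np.argsort([-s.label_noise_rate for s in subs]))
    offsets = spec.subpop_separation * rank / np.sqrt(d)
    Z_pos += offsets[sub_assign][:, None]

    noise_mask = np.zeros(spec.n_pos, dtype=bool)
    for s_idx, s in enumerate(subs):
        members = np.flatnonzero(sub_assign == s_idx)
        n_noise = int(round(s.label_noise_rate * len(members)))
        if n_noise:
            flips = rng.choice(members, size=n_noise, replace=False)
            Z_pos[flips] = rng.standard_normal((n_noise, d))
            noise_mask[flips] = True

    Z_neg = rng.standard_normal((spec.n_neg, d))
    Z = np.vstack([Z_pos, Z_neg])
    labels = np.array([spec.pos_label] * spec.n_pos
                      + [spec.neg_label] * spec.n_neg)
    ids = [f"{'p' if i < spec.n_pos else 'n'}{i:04d}" for i in range(len(Z))]

    cols = {}
    for j, name in enumerate(names):
        mean, sd, is_int = _SCALE_PALETTE[j % len(_SCALE_PALETTE)]
        v = mean + sd * Z[:, j]
        if is_int:
            v = np.clip(np.round(v), 0, None)
        cols[name] = v

    planted = {}
    for src, r in spec.collinear_pairs:
        if src not in names:
            raise ValueError(f"unknown source column {src!r}")
        j = names.index(src)
        eps = rng.standard_normal(len(Z))
        y = r * Z[:, j] + np.sqrt(1.0 - r * r) * eps
        pname = f"{src}_col"
        mean, sd, _ = _SCALE_PALETTE[j % len(_SCALE_PALETTE)]
        cols[pname] = mean + sd * y     # never rounded: keeps target r intact
        planted[pname] = {"source": src, "target_r": r}

    table = FeatureTable(X=pd.DataFrame(cols), labels=labels, ids=ids)
    truth = GroundTruth(
        class_means={spec.pos_label: [spec.delta] * d,
                     spec.neg_label: [0.0] * d},
        planted_columns=planted,
        subpopulation=sub_assign.tolist(),
        noise_rows=[ids[i] for i in np.flatnonzero(noise_mask)],
        seed=spec.seed)
    return table, truth


def generate_imbalanced_scenario(spec: SyntheticSpec
                                 ) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Positive/negative tables for the undersampling stage.

    Requires a majority positive class and at least two positive
    subpopulations of which exactly one is label-clean (noise rate 0);
    that clean subpopulation carries its own geometric offset so cluster
    analysis can isolate it.
    """
    if spec.n_pos <= spec.n_neg:
        raise ValueError("imbalanced scenario needs n_pos > n_neg")
    subs = spec.pos_subpopulations
    if len(subs) < 2:
        raise ValueError("need >= 2 positive subpopulations")
    clean = [s for s in subs if s.label_noise_rate == 0.0]
    if not clean:
        raise ValueError("all subpopulations noisy: no recoverable ground truth")
    if len(clean) != 1:
        raise ValueError("exactly one subpopulation must be label-clean")
    table, truth = generate_feature_table(spec)
    pos = table.subset(table.labels == spec.pos_label)
    neg = table.subset(table.labels == spec.neg_label)
    return pos, neg, truth


# ---- molecule fixtures --------------------------------------------------

@dataclass
class ToyMolecule:
    name: str
    smiles: str
    expected: dict


def generate_toy_molecules() -> list[ToyMolecule]:
    """Hand-verified molecule fixtures for the descriptor stage.

    Expected values were derived by hand: MW from average atomic masses
    (implicit hydrogens included), ring count as the cyclomatic number,
    donors as H on N/O, acceptors as N+O+F atom counts, rotatable bonds
    under the non-terminal/acyclic/amide-excluded convention.  TPSA is
    given where the Ertl fragment sum is a short hand computation.
    """
    return [
        ToyMolecule("methane", "C",
                    {"MW": 16.04, "RBN": 0, "nCIC": 0, "nHDon": 0, "nHAcc": 0,
                     "TPSA": 0.0}),
        ToyMolecule("ethanol", "CCO",
                    {"MW": 46.07, "RBN": 0, "nCIC": 0, "nHDon": 1, "nHAcc": 1,
                     "TPSA": 20.23}),
        ToyMolecule("benzene", "c1ccccc1",
                    {"MW": 78.11, "RBN": 0, "nCIC": 1, "nHDon": 0, "nHAcc": 0,
                     "TPSA": 0.0}),
        ToyMolecule("phenol", "Oc1ccccc1",
                    {"MW": 94.11, "RBN": 0, "nCIC": 1, "nHDon": 1, "nHAcc": 1,
                     "TPSA": 20.23}),
        ToyMolecule("aniline", "Nc1ccccc1",
                    {"MW": 93.13, "RBN": 0, "nCIC": 1, "nHDon": 2, "nHAcc": 1,
                     "TPSA": 26.02}),
        ToyMolecule("acetic acid", "CC(=O)O",
                    {"MW": 60.05, "RBN": 0, "nCIC": 0, "nHDon": 1, "nHAcc": 2,
                     "TPSA": 37.30}),
        ToyMolecule("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
                    {"MW": 194.19, "RBN": 0, "nCIC": 2, "nHDon": 0, "nHAcc": 6}),
        ToyMolecule("aspirin", "CC(=O)Oc1ccccc1C(=O)O",
                    {"MW": 180.16, "RBN": 3, "nCIC": 1, "nHDon": 1, "nHAcc": 4}),
        ToyMolecule("pyridine", "c1ccncc1",
                    {"MW": 79.10, "RBN": 0, "nCIC": 1, "nHDon": 0, "nHAcc": 1,
                     "TPSA": 12.89}),
        ToyMolecule("diethyl ether", "CCOCC",
                    {"MW": 74.12, "RBN": 2, "nCIC": 0, "nHDon": 0, "nHAcc": 1,
                     "TPSA": 9.23}),
    ]
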