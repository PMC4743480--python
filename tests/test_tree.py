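"""Gain-ratio tree induction vs an exhaustive brute-force oracle."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgpcspr import GainRatioTreeClassifier, parse_rules, render_rules
from pgpcspr.tree import best_split


# ---- independent oracle: direct enumeration with textbook formulas ------

def _H(labels):
    n = len(labels)
    return -sum((c / n) * math.log2(c / n) for c in Counter(labels).values())


def oracle_best_split(X, y, min_leaf=1):
    """Exhaustive search over every boundary midpoint, recomputing
    entropy, gain and split information from their definitions."""
    n = len(y)
    best = None  # (gain_ratio, feature, threshold)
    for j in range(X.shape[1]):
        vals = sorted(set(X[:, j]))
        for a, b in zip(vals, vals[1:]):
            ga = [y[i] for i in range(n) if X[i, j] == a]
            gb = [y[i] for i in range(n) if X[i, j] == b]
            if len(set(ga)) == 1 and len(set(gb)) == 1 and ga[0] == gb[0]:
                continue  # not a class-composition boundary
            t = (a + b) / 2
            left = [y[i] for i in range(n) if X[i, j] <= t]
            right = [y[i] for i in range(n) if X[i, j] > t]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            gain = max(0.0, _H(list(y)) - (len(left) / n) * _H(left)
                       - (len(right) / n) * _H(right))
            pl, pr = len(left) / n, len(right) / n
            gr = gain / (-(pl * math.log2(pl) + pr * math.log2(pr)))
            if best is None or gr > best[0] + 1e-12:
                best = (gr, j, t)
    return best


def random_small_dataset(rng, max_rows=12, max_features=2):
    n = rng.integers(2, max_rows + 1)
    d = rng.integers(1, max_features + 1)
    X = rng.integers(0, 6, size=(n, d)).astype(float)
    y = rng.integers(0, 2, size=n)
    return X, y


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(60))
    def test_best_split_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_small_dataset(rng)
        expected = oracle_best_split(X, y)
        got = best_split(X, y, n_classes=2, min_leaf=1)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert got[0] == expected[1]
            assert got[1] == pytest.approx(expected[2])
            assert got[2] == pytest.approx(expected[0], abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_best_split_matches_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_small_dataset(rng)
        expected = oracle_best_split(X, y)
        got = best_split(X, y, n_classes=2, min_leaf=1)
        if expected is None:
            assert got is None
        else:
            assert (got[0], got[1]) == (expected[1], pytest.approx(expected[2]))


class TestInduction:
    def test_1d_toy_single_split(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        y = np.array(["A", "A", "B", "B"])
        t = GainRatioTreeClassifier().fit(X, y)
        assert not t.root_.is_leaf
        assert t.root_.threshold == 6.0
        assert (t.predict(X) == y).all()

    def test_single_class_single_leaf(self):
        t = GainRatioTreeClassifier().fit(np.arange(6.0)[:, None],
                                          np.array(["A"] * 6))
        assert t.root_.is_leaf
        assert t.n_leaves_ == 1

    def test_xor_like_depth_two(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]] * 2)
        y = np.array(["A", "B", "B", "A"] * 2)
        t = GainRatioTreeClassifier(min_leaf=1, prune=False).fit(X, y)
        assert (t.predict(X) == y).all()
        assert t.n_leaves_ >= 3  # one split cannot separate XOR

    def test_non_numeric_feature_is_an_error(self):
        with pytest.raises(ValueError):
            GainRatioTreeClassifier().fit(
                np.array([["a"], ["b"]], dtype=object), np.array([0, 1]))


class TestPrediction:
    def _mw_rule_model(self):
        # single-node tree equivalent to the substrate rule at 668.78
        X = np.array([[300.0], [500.0], [700.0], [800.0]])
        y = np.array(["NS", "NS", "S", "S"])
        return GainRatioTreeClassifier(feature_names=["MW"]).fit(X, y)

    def test_threshold_routing(self):
        model = self._mw_rule_model()
        assert model.root_.threshold == 600.0
        assert model.predict_record({"MW": 692.80}) == "S"
        assert model.predict_record({"MW": 600.0}) == "NS"  # boundary left
        assert model.predict_record({"MW": 100.0}) == "NS"

    def test_missing_feature_named_in_error(self):
        model = self._mw_rule_model()
        with pytest.raises(KeyError, match="MW"):
            model.predict_record({"TPSA": 10.0})


class TestPruning:
    def test_pruned_leaf_count_not_larger(self, noise_table):
        X, y = noise_table.X.to_numpy(float), noise_table.labels
        full = GainRatioTreeClassifier(prune=False).fit(X, y)
        pruned = GainRatioTreeClassifier(prune=True).fit(X, y)
        assert pruned.n_leaves_ <= full.n_leaves_
        assert pruned.n_leaves_ < full.n_leaves_  # noise trees do shrink

    def test_pruning_keeps_pure_training_predictions(self, separable_table):
        X, y = separable_table.X.to_numpy(float), separable_table.labels
        full = GainRatioTreeClassifier(prune=False).fit(X, y)
        if (full.predict(X) == y).all():  # consistent tree: predictions stable
            pruned = GainRatioTreeClassifier(prune=True).fit(X, y)
            assert (pruned.predict(X) == full.predict(X)).all()


class TestRules:
    def test_single_leaf_one_unconditional_rule(self):
        t = GainRatioTreeClassifier().fit(np.zeros((4, 1)), np.array(["A"] * 4))
        rules = t.extract_rules()
        assert len(rules) == 1 and rules[0].conditions == ()

    def test_single_split_two_covering_rules(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        t = GainRatioTreeClassifier().fit(X, np.array(["A", "A", "B", "B"]))
        rules = t.extract_rules()
        assert len(rules) == 2
        assert rules[0].conditions[0][1] == "<="
        assert rules[1].conditions[0][1] == ">"

    def test_rules_partition_feature_space(self, separable_table):
        t = GainRatioTreeClassifier().fit(separable_table.X,
                                          separable_table.labels)
        rules = t.extract_rules()
        rng = np.random.default_rng(0)
        lo = separable_table.X.min().to_numpy()
        hi = separable_table.X.max().to_numpy()
        probes = rng.uniform(lo - 1, hi + 1, size=(300, separable_table.X.shape[1]))
        names = list(separable_table.X.columns)
        for row in probes:
            record = dict(zip(names, row))
            hits = [r for r in rules if r.matches(record)]
            assert len(hits) == 1  # mutually exclusive and exhaustive
            assert hits[0].klass == t.predict_record(record)

    def test_render_parse_roundtrip(self, separable_table):
        t = GainRatioTreeClassifier().fit(separable_table.X,
                                          separable_table.labels)
        rules = t.extract_rules()
        back = parse_rules(render_rules(t))
        assert [(r.conditions, str(r.klass), r.support) for r in rules] \
            == [(r.conditions, r.klass, r.support) for r in back]
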