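"""Confusion-matrix accounting, the four statistics, splits and CV."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from pgpcspr import (ConfusionMatrix, GainRatioTreeClassifier, SyntheticSpec,
                     confusion, generate_feature_table, kfold_cv, metrics,
                     pca_random_split)


class TestConfusion:
    def test_all_correct(self):
        cm = confusion(["p", "p", "p", "n", "n"], ["p", "p", "p", "n", "n"], "p")
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (3, 2, 0, 0)

    def test_all_inverted(self):
        cm = confusion(["n", "n", "n", "p", "p"], ["p", "p", "p", "n", "n"], "p")
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (0, 0, 2, 3)

    def test_mixed_hand_tally(self):
        # hand-built 6-row case: truths p p p n n n, preds p n p p n n
        cm = confusion(["p", "n", "p", "p", "n", "n"],
                       ["p", "p", "p", "n", "n", "n"], "p")
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 2)
        assert cm.total == 6

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion(["p"], ["p", "n"], "p")

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="labels"):
            confusion(["p", "x"], ["p", "n"], "p")


class TestMetrics:
    def test_perfect_matrix(self):
        rep = metrics(ConfusionMatrix(tp=3, fp=0, fn=0, tn=4))
        assert rep.accuracy == 100.0
        assert rep.sensitivity == 100.0
        assert rep.specificity == 100.0
        assert rep.mcc == 1.0

    def test_total_inversion(self):
        rep = metrics(ConfusionMatrix(tp=0, fp=2, fn=2, tn=0))
        assert rep.mcc == -1.0
        assert rep.accuracy == 0.0

    def test_hand_derived_case(self):
        rep = metrics(ConfusionMatrix(tp=90, fp=10, fn=20, tn=80))
        assert rep.accuracy == pytest.approx(85.0)
        assert rep.sensitivity == pytest.approx(100 * 90 / 110)
        assert rep.specificity == pytest.approx(100 * 80 / 90)
        assert rep.mcc == pytest.approx(0.7035, abs=1e-4)

    def test_zero_denominator_mcc_is_zero(self):
        rep = metrics(ConfusionMatrix(tp=5, fp=5, fn=0, tn=0))
        assert rep.mcc == 0.0

    def test_no_negatives_specificity_missing(self):
        with pytest.warns(UserWarning, match="specificity"):
            rep = metrics(ConfusionMatrix(tp=3, fp=0, fn=1, tn=0))
        assert math.isnan(rep.specificity)

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=0))

    @given(tp=st.integers(0, 40), fp=st.integers(0, 40),
           fn=st.integers(0, 40), tn=st.integers(0, 40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_mcc_invariants(self, tp, fp, fn, tn):
        """FP=FN=0 gives MCC 1; swapping (TP<->FN, TN<->FP) negates MCC;
        class-label exchange (TP<->TN, FP<->FN) preserves MCC; and the
        formula agrees with sklearn's implementation."""
        if tp + fp + fn + tn == 0:
            return
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            rep = metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
            swapped = metrics(ConfusionMatrix(tp=fn, fp=tn, fn=tp, tn=fp))
            exchanged = metrics(ConfusionMatrix(tp=tn, fp=fn, fn=fp, tn=tp))
        assert -1.0 <= rep.mcc <= 1.0
        if fp == 0 and fn == 0 and tp > 0 and tn > 0:
            assert rep.mcc == 1.0
        assert swapped.mcc == pytest.approx(-rep.mcc, abs=1e-12)
        assert exchanged.mcc == pytest.approx(rep.mcc, abs=1e-12)
        y_true = [1] * tp + [1] * fn + [0] * fp + [0] * tn
        y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom > 0:
            assert rep.mcc == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-9)


class TestPcaSplit:
    def _table(self, n=100, seed=0, delta=2.0):
        spec = SyntheticSpec(n_pos=n // 2, n_neg=n // 2, delta=delta,
                             n_features=4, seed=seed)
        table, _ = generate_feature_table(spec)
        return table

    def test_sizes_85_15(self):
        t = self._table(200)
        plan = pca_random_split(t.X, t.labels, seed=1)
        assert len(plan.train_ids) == 170
        assert len(plan.test_ids) == 30
        assert set(plan.train_ids) | set(plan.test_ids) == set(range(200))

    def test_seed_changes_membership_not_sizes(self):
        t = self._table(100)
        p1 = pca_random_split(t.X, t.labels, seed=1)
        p2 = pca_random_split(t.X, t.labels, seed=2)
        assert len(p1.test_ids) == len(p2.test_ids)
        assert set(p1.test_ids) != set(p2.test_ids)

    def test_same_seed_reproducible(self):
        t = self._table(100)
        p1 = pca_random_split(t.X, t.labels, seed=5)
        p2 = pca_random_split(t.X, t.labels, seed=5)
        assert p1.test_ids == p2.test_ids

    def test_bimodal_pc1_both_modes_in_test(self):
        # one class whose PC1 is strongly bimodal: both modes must
        # contribute test rows
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-10, 1, (60, 3)), rng.normal(10, 1, (60, 3))])
        labels = np.array(["a"] * 120)
        plan = pca_random_split(X, labels, seed=0)
        test = np.asarray(plan.test_ids)
        assert (test < 60).any() and (test >= 60).any()

    def test_tiny_class_falls_back_to_plain_split(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(25, 3))
        labels = np.array(["a"] * 20 + ["b"] * 5)
        with pytest.warns(UserWarning, match="stratify"):
            plan = pca_random_split(X, labels, seed=0)
        assert len(plan.train_ids) + len(plan.test_ids) == 25


class TestKFoldCV:
    def test_leave_one_out_partition(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        y = np.array(["a"] * 5 + ["b"] * 5)
        res = kfold_cv(GainRatioTreeClassifier(), X, y, positive_class="a",
                       k=10, seed=0)
        seen = np.concatenate(res.fold_test_indices)
        assert sorted(seen) == list(range(10))

    def test_each_row_tested_once(self, separable_table):
        t = separable_table
        res = kfold_cv(GainRatioTreeClassifier(), t.X, t.labels,
                       positive_class="inhibitor", k=10, seed=0)
        seen = np.concatenate(res.fold_test_indices)
        assert sorted(seen) == list(range(len(t)))

    def test_separable_table_high_mcc(self, separable_table):
        t = separable_table
        res = kfold_cv(GainRatioTreeClassifier(), t.X, t.labels,
                       positive_class="inhibitor", k=10, seed=0)
        assert res.report.mcc >= 0.9

    def test_n_smaller_than_k_raises(self):
        with pytest.raises(ValueError):
            kfold_cv(GainRatioTreeClassifier(), np.zeros((5, 2)),
                     np.array(["a", "a", "b", "b", "a"]),
                     positive_class="a", k=10, seed=0)
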