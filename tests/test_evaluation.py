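"""Splits, folds, confusion bookkeeping and metric formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from randnet.evaluation import (
    ConfusionMatrix,
    confusion,
    kfold,
    metrics,
    split_train_test,
)


class TestSplit:
    def test_ninety_ten_arithmetic(self):
        train, test = split_train_test(7790, 0.9, seed=0)
        assert train.size == 7011 and test.size == 779

    def test_small_n(self):
        train, test = split_train_test(10, 0.9, seed=0)
        assert train.size == 9 and test.size == 1

    def test_deterministic_and_partitioning(self):
        a = split_train_test(100, 0.8, seed=5)
        b = split_train_test(100, 0.8, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert sorted(np.concatenate(a).tolist()) == list(range(100))

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(1, 0.9)
        with pytest.raises(ValueError):
            split_train_test(5, 0.05)


class TestKFold:
    def test_even_folds(self):
        folds = kfold(20, 10, seed=1)
        assert len(folds) == 10
        assert all(te.size == 2 for _, te in folds)

    @given(st.integers(10, 60), st.integers(2, 8), st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_union_disjoint_and_balanced(self, n, k, seed):
        folds = kfold(n, k, seed=seed)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(n))
        sizes = [te.size for _, te in folds]
        assert max(sizes) - min(sizes) <= 1
        for tr, te in folds:
            assert np.intersect1d(tr, te).size == 0
            assert tr.size + te.size == n

    def test_stratified_keeps_balance_within_one(self):
        y = np.repeat([0, 1, 2, 3], 25)
        folds = kfold(100, 5, seed=2, stratify_labels=y)
        for _, te in folds:
            counts = np.bincount(y[te], minlength=4)
            assert np.all(np.abs(counts - 5) <= 1)

    def test_more_folds_than_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold(3, 10)


def _brute_force_report(y_true, y_pred, n_classes=4):
    """Independent per-element recount of every metric."""
    out = []
    n = len(y_true)
    for c in range(n_classes):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        tn = n - tp - fp - fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out.append({"accuracy": (tp + tn) / n, "precision": prec,
                    "recall": rec, "f1": f1})
    return out


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.repeat([0, 1, 2, 3], 5)
        report = metrics(confusion(y, y))
        assert np.array_equal(np.diag(report.confusion.counts), [5, 5, 5, 5])
        for row in report.per_class:
            assert row["precision"] == row["recall"] == row["f1"] == 1.0
        assert report.overall["accuracy"] == 1.0

    def test_all_predicted_class_zero_on_balanced_input(self):
        y = np.repeat([0, 1, 2, 3], 10)
        pred = np.zeros_like(y)
        report = metrics(confusion(y, pred))
        c0 = report.per_class[0]
        assert c0["recall"] == 1.0
        assert c0["precision"] == pytest.approx(0.25)
        assert report.overall["accuracy"] == pytest.approx(0.25)
        # empty predicted classes: flagged undefined, reported as 0
        assert report.per_class[1]["precision"] == 0.0
        assert report.per_class[1]["undefined"]["precision"]

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_recount(self, seed):
        gen = np.random.default_rng(seed)
        y_true = gen.integers(0, 4, 200)
        y_pred = gen.integers(0, 4, 200)
        report = metrics(confusion(y_true, y_pred))
        expected = _brute_force_report(y_true, y_pred)
        for got, exp in zip(report.per_class, expected):
            for key in ("accuracy", "precision", "recall", "f1"):
                assert got[key] == pytest.approx(exp[key])
        assert report.overall["accuracy"] == pytest.approx(
            np.mean(y_true == y_pred))

    def test_sklearn_cross_check(self):
        from sklearn.metrics import precision_recall_fscore_support

        gen = np.random.default_rng(1)
        y_true = gen.integers(0, 4, 300)
        y_pred = gen.integers(0, 4, 300)
        report = metrics(confusion(y_true, y_pred))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(4), zero_division=0)
        for c in range(4):
            assert report.per_class[c]["precision"] == pytest.approx(p[c])
            assert report.per_class[c]["recall"] == pytest.approx(r[c])
            assert report.per_class[c]["f1"] == pytest.approx(f[c])

    def test_macro_f1_invariant_under_relabeling(self):
        gen = np.random.default_rng(2)
        y_true = gen.integers(0, 4, 150)
        y_pred = gen.integers(0, 4, 150)
        base = metrics(confusion(y_true, y_pred)).overall["f1"]
        perm = np.array([2, 3, 0, 1])
        permuted = metrics(confusion(perm[y_true], perm[y_pred])).overall["f1"]
        assert permuted == pytest.approx(base)

    def test_row_and_column_bookkeeping(self):
        gen = np.random.default_rng(3)
        y_true = gen.integers(0, 4, 120)
        y_pred = gen.integers(0, 4, 120)
        cm = confusion(y_true, y_pred)
        for c in range(4):
            tp, tn, fp, fn = cm.one_vs_rest(c)
            assert tp + fn == cm.counts[c, :].sum()
            assert tp + fp == cm.counts[:, c].sum()
            assert tp + tn + fp + fn == cm.total

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion([0, 5], [0, 1])

    def test_confusion_csv(self, tmp_path):
        cm = ConfusionMatrix(np.eye(4, dtype=int) * 3)
        path = tmp_path / "cm.csv"
        cm.to_csv(path)
        import pandas as pd

        back = pd.read_csv(path, index_col=0)
        assert np.array_equal(back.to_numpy(), cm.counts)
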