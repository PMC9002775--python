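"""Splits, cross-validation, confusion matrices and classification metrics.

Per-class metrics are one-vs-rest: for class *c*, TP are the diagonal
counts, FP the rest of column *c*, FN the rest of row *c*, and TN
everything else, giving

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Ratios with a zero denominator are reported as 0.0 and flagged.  Overall
precision/recall/F1 are macro (unweighted) averages; overall accuracy is
trace / total.  Both the one-vs-rest per-class accuracy and the class
recall (the confusion-matrix diagonal as a fraction of the row) are
exposed, since reports in this area use "class accuracy" for either.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "split_train_test",
    "kfold",
    "confusion",
    "metrics",
]

DEFAULT_CLASS_NAMES = [
    "normal",
    "complex_partial",
    "electrographic",
    "video_detected",
]


def split_train_test(
    n: int,
    train_fraction: float = 0.9,
    seed: int | None = None,
    shuffle: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index split; |train| = floor(n * fraction)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves an empty side; adjust the fraction")
    idx = np.arange(n)
    if shuffle:
        idx = np.random.default_rng(seed).permutation(n)
    return idx[:n_train], idx[n_train:]


def kfold(
    n: int,
    k: int = 10,
    seed: int | None = None,
    stratify_labels: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint (train, test) folds covering all indices; sizes differ by <= 1."""
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    if stratify_labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros(n), np.asarray(stratify_labels)))
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(n)))


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=lambda: list(DEFAULT_CLASS_NAMES))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(self.class_names) != self.counts.shape[0]:
            self.class_names = [f"class_{i}" for i in range(self.counts.shape[0])]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class c."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum() - tp)
        fn = int(self.counts[c, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, tn, fp, fn

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.counts, index=self.class_names,
                     columns=self.class_names).to_csv(path)


def confusion(
    y_true, y_pred, n_classes: int = 4, class_names: list[str] | None = None
) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} labels outside 0..{n_classes - 1}")
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(counts, class_names or
                           list(DEFAULT_CLASS_NAMES)[:n_classes])


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


@dataclass
class EvaluationReport:
    """Per-class and macro-averaged classification metrics."""

    confusion: ConfusionMatrix
    per_class: list[dict]
    overall: dict
    split_info: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.overall["accuracy"]

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.counts.tolist(),
            "class_names": self.confusion.class_names,
            "per_class": self.per_class,
            "overall": self.overall,
            "split_info": self.split_info,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:
        head = (f"{'class':<18}{'accuracy':>10}{'precision':>11}"
                f"{'recall':>9}{'F1':>9}")
        lines = [head, "-" * len(head)]
        for row in self.per_class:
            lines.append(
                f"{row['class']:<18}{row['accuracy']:>10.4f}"
                f"{row['precision']:>11.4f}{row['recall']:>9.4f}"
                f"{row['f1']:>9.4f}"
            )
        o = self.overall
        lines.append("-" * len(head))
        lines.append(
            f"{'overall (macro)':<18}{o['accuracy']:>10.4f}"
            f"{o['precision']:>11.4f}{o['recall']:>9.4f}{o['f1']:>9.4f}"
        )
        return "\n".join(lines)


def metrics(cm: ConfusionMatrix, split_info: dict | None = None) -> EvaluationReport:
    """One-vs-rest metrics per class plus macro-averaged overall metrics."""
    per_class = []
    for c, name in enumerate(cm.class_names):
        tp, tn, fp, fn = cm.one_vs_rest(c)
        acc, acc_undef = _safe_ratio(tp + tn, tp + tn + fp + fn)
        prec, prec_undef = _safe_ratio(tp, tp + fp)
        rec, rec_undef = _safe_ratio(tp, tp + fn)
        f1, f1_undef = _safe_ratio(2 * prec * rec, prec + rec)
        per_class.append({
            "class": name,
            "tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "accuracy": acc,
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "undefined": {
                "accuracy": acc_undef, "precision": prec_undef,
                "recall": rec_undef, "f1": f1_undef,
            },
        })
    total = cm.total
    overall_acc, _ = _safe_ratio(int(np.trace(cm.counts)), total)
    overall = {
        "accuracy": overall_acc,
        "accuracy_macro_ovr": float(np.mean([r["accuracy"] for r in per_class])),
        "precision": float(np.mean([r["precision"] for r in per_class])),
        "recall": float(np.mean([r["recall"] for r in per_class])),
        "f1": float(np.mean([r["f1"] for r in per_class])),
        "n_samples": total,
    }
    return EvaluationReport(cm, per_class, overall, split_info or {})
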