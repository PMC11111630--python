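"""Evaluation metrics: confusion matrix, one-vs-rest rates, Cohen's kappa,
and midrank (Mann-Whitney) ROC AUC with macro-averaging.

Per-class precision, sensitivity (recall), specificity and F1 are derived
one-vs-rest from TP/FP/FN/TN.  Two aggregates are reported: *weighted*
(true-class-frequency weights — the headline aggregate, under which
weighted recall coincides with accuracy) and *macro* (unweighted mean).
Zero-denominator rates are reported as 0 with a warning rather than
raising, so tiny evaluation batches remain usable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "basic_metrics",
    "kappa",
    "roc_auc",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[a, p] = number of samples with actual class a, predicted p."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {c.shape}")
        if (c < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]


@dataclass
class MetricsReport:
    accuracy: float
    kappa: float
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray
    precision_weighted: float
    precision_macro: float
    recall_weighted: float
    recall_macro: float
    specificity_weighted: float
    specificity_macro: float
    f1_weighted: float
    f1_macro: float
    confusion: np.ndarray
    n: int
    per_class_auc: np.ndarray | None = None
    macro_auc: float | None = None

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return [None if np.isnan(x) else float(x) for x in np.ravel(v)] \
                    if v.dtype.kind == "f" else v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        d = {k: conv(v) for k, v in self.__dict__.items()}
        d["confusion"] = self.confusion.tolist()
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary_row(self, labeled_scale: int | None = None) -> dict:
        """One-row summary in the conventional benchmark-table layout."""
        row = {
            "Labeled Scale": labeled_scale,
            "Accuracy": round(self.accuracy, 4),
            "Kappa": round(self.kappa, 4),
            "Recall": round(self.recall_weighted, 4),
            "Precision": round(self.precision_weighted, 4),
            "F1-score": round(self.f1_weighted, 4),
        }
        if labeled_scale is None:
            row.pop("Labeled Scale")
        return row


def confusion(
    true_labels: np.ndarray, predicted_labels: np.ndarray, n_classes: int
) -> ConfusionMatrix:
    y = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if y.shape != p.shape:
        raise ValueError(
            f"label vectors have mismatched lengths: {y.shape} vs {p.shape}"
        )
    for name, v in (("true", y), ("predicted", p)):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValueError(f"{name} labels out of range [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y, p), 1)
    return ConfusionMatrix(counts)


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    bad = den == 0
    if bad.any():
        warnings.warn(
            f"{what}: zero denominator for class(es) {np.flatnonzero(bad).tolist()}; "
            "reporting 0",
            stacklevel=3,
        )
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=~bad)
    return out


def basic_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy plus per-class / aggregated one-vs-rest rates from a matrix."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(np.float64)
    n = cm.n
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    tn = n - tp - fp - fn

    accuracy = float(tp.sum() / n)
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "sensitivity")
    specificity = _safe_div(tn, tn + fp, "specificity")
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")

    support = c.sum(axis=1) / n

    return MetricsReport(
        accuracy=accuracy,
        kappa=kappa(cm),
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        precision_weighted=float(precision @ support),
        precision_macro=float(precision.mean()),
        recall_weighted=float(recall @ support),
        recall_macro=float(recall.mean()),
        specificity_weighted=float(specificity @ support),
        specificity_macro=float(specificity.mean()),
        f1_weighted=float(f1 @ support),
        f1_macro=float(f1.mean()),
        confusion=cm.counts.copy(),
        n=n,
    )


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) with marginal chance agreement."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(np.float64)
    n = cm.n
    p_o = np.diag(c).sum() / n
    p_e = float(c.sum(axis=1) @ c.sum(axis=0)) / n**2
    if p_e >= 1.0:
        warnings.warn("kappa undefined (chance agreement 1); reporting 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties."""
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    ranks = rankdata(scores)
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(
    true_labels: np.ndarray, probs: np.ndarray
) -> tuple[np.ndarray, float]:
    """One-vs-rest AUC per class and the macro (unweighted) mean.

    A class with no positives or no negatives gets NaN and is excluded
    from the macro average (with a warning); if every class is degenerate
    the macro average is undefined and an error is raised.
    """
    y = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 2 or len(p) != len(y):
        raise ValueError("probs must be (n_samples, n_classes) matching labels")
    n_classes = p.shape[1]
    aucs = np.full(n_classes, np.nan)
    for c in range(n_classes):
        pos = y == c
        if pos.any() and (~pos).any():
            aucs[c] = _binary_auc(p[:, c], pos)
    defined = ~np.isnan(aucs)
    if not defined.any():
        raise ValueError("AUC undefined for every class (single-class input)")
    if not defined.all():
        warnings.warn(
            f"AUC undefined for class(es) {np.flatnonzero(~defined).tolist()}; "
            "excluded from macro average"
        )
    return aucs, float(aucs[defined].mean())


def evaluate_predictions(
    true_labels: np.ndarray,
    probs: np.ndarray,
    n_classes: int | None = None,
) -> MetricsReport:
    """Full report from true labels and predicted class probabilities."""
    p = np.asarray(probs, dtype=np.float64)
    if n_classes is None:
        n_classes = p.shape[1]
    preds = p.argmax(axis=1)
    report = basic_metrics(confusion(true_labels, preds, n_classes))
    try:
        report.per_class_auc, report.macro_auc = roc_auc(true_labels, p)
    except ValueError:
        report.per_class_auc, report.macro_auc = None, None
    return report
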