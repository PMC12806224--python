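"""Evaluation metrics for classification and regression tasks.

Conventions pinned here: AUROC is the exact Mann-Whitney rank-sum statistic
(ties count one half); AUPRC is average precision (no interpolation);
macro-F1 averages per-class F1 over all declared classes, counting a class
absent from both labels and predictions as 0; MCC returns 0 when any
marginal is empty. The Student-t loss is the log-kernel of a standardized
Student-t distribution of the residuals, mean over samples of
((nu+1)/2) * log(1 + r^2/nu) with nu configurable (default 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import f1_score, average_precision_score

__all__ = ["ConfusionCounts", "mcc", "mcc_from_labels", "accuracy", "f1_macro",
           "auroc", "auprc", "spearman", "regression_losses",
           "classification_report", "regression_report", "MetricsReport"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient from confusion counts.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 by convention
    when any marginal factor vanishes (a degenerate predictor or degenerate
    labels carry no correlation).
    """
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    tp, tn, fp, fn = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def mcc_from_labels(y_true, y_pred) -> float:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    c = ConfusionCounts(tp=int(((y_true == 1) & (y_pred == 1)).sum()),
                        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
                        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
                        fn=int(((y_true == 1) & (y_pred == 0)).sum()))
    return mcc(c)


def accuracy(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    _check_aligned(y_true, y_pred)
    return float((y_true == y_pred).mean())


def f1_macro(y_true, y_pred, n_classes: int) -> float:
    """Unweighted mean of per-class F1 over all ``n_classes`` classes."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    _check_aligned(y_true, y_pred)
    return float(f1_score(y_true, y_pred, labels=list(range(n_classes)),
                          average="macro", zero_division=0))


def auroc(labels, scores) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    _check_aligned(labels, scores)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = stats.rankdata(scores)          # average ranks handle ties
    rank_sum = ranks[labels == 1].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(labels, scores) -> float:
    """Average precision (area under the precision-recall step curve)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    _check_aligned(labels, scores)
    if (labels == 1).sum() == 0:
        raise ValueError("AUPRC undefined without positive labels")
    return float(average_precision_score(labels, scores))


def auroc_macro_ovr(labels, score_matrix) -> float:
    """One-vs-rest macro AUROC for multiclass scores (n, K)."""
    labels = np.asarray(labels).astype(int)
    score_matrix = np.asarray(score_matrix, dtype=float)
    vals = [auroc((labels == k).astype(int), score_matrix[:, k])
            for k in range(score_matrix.shape[1])
            if 0 < (labels == k).sum() < len(labels)]
    if not vals:
        raise ValueError("macro AUROC undefined: no two-class split exists")
    return float(np.mean(vals))


def auprc_macro_ovr(labels, score_matrix) -> float:
    """One-vs-rest macro average precision for multiclass scores (n, K)."""
    labels = np.asarray(labels).astype(int)
    score_matrix = np.asarray(score_matrix, dtype=float)
    vals = [auprc((labels == k).astype(int), score_matrix[:, k])
            for k in range(score_matrix.shape[1])
            if (labels == k).sum() > 0]
    if not vals:
        raise ValueError("macro AUPRC undefined: no positives in any class")
    return float(np.mean(vals))


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_aligned(x, y)
    if x.size < 2:
        raise ValueError("spearman requires at least 2 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def regression_losses(y_true, y_pred, nu: float = 1.0) -> tuple:
    """(MSE, MAE, Student-t loss) of the residuals.

    The Student-t loss is mean(((nu+1)/2) * log(1 + r^2 / nu)); it grows
    logarithmically in |r|, down-weighting outliers relative to MSE.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    _check_aligned(y_true, y_pred)
    r = y_true - y_pred
    mse = float(np.mean(r ** 2))
    mae = float(np.mean(np.abs(r)))
    student_t = float(np.mean((nu + 1.0) / 2.0 * np.log1p(r ** 2 / nu)))
    return mse, mae, student_t


def _check_aligned(a: np.ndarray, b: np.ndarray):
    if a.shape[0] != b.shape[0] or a.shape[0] == 0:
        raise ValueError(f"inputs misaligned or empty: {a.shape} vs {b.shape}")


# ------------------------------------------------------------------- reporting

class MetricsReport(dict):
    """A metric-name -> value mapping with JSON serialization."""

    def to_json(self, path=None) -> str:
        payload = json.dumps({k: (v if isinstance(v, (int, dict)) else float(v))
                              for k, v in self.items()}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def classification_report(y_true, scores, n_classes: int = 2) -> MetricsReport:
    """Metric set for classification tasks.

    Binary: accuracy, macro-F1, MCC, AUROC (scores = positive-class score).
    Multiclass: accuracy, macro-F1, macro AUROC and AUPRC (scores = (n, K)).
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if n_classes == 2 and scores.ndim == 1:
        y_pred = (scores > 0.5).astype(int)
        rep = MetricsReport(
            accuracy=accuracy(y_true, y_pred),
            f1_macro=f1_macro(y_true, y_pred, 2),
            mcc=mcc_from_labels(y_true, y_pred),
            auroc=auroc(y_true, scores),
        )
        rep["confusion"] = {
            "tp": int(((y_true == 1) & (y_pred == 1)).sum()),
            "tn": int(((y_true == 0) & (y_pred == 0)).sum()),
            "fp": int(((y_true == 0) & (y_pred == 1)).sum()),
            "fn": int(((y_true == 1) & (y_pred == 0)).sum()),
        }
        return rep
    y_pred = scores.argmax(axis=1)
    return MetricsReport(
        accuracy=accuracy(y_true, y_pred),
        f1_macro=f1_macro(y_true, y_pred, n_classes),
        auroc=auroc_macro_ovr(y_true, scores),
        auprc=auprc_macro_ovr(y_true, scores),
    )


def regression_report(y_true, y_pred, nu: float = 1.0) -> MetricsReport:
    mse, mae, student_t = regression_losses(y_true, y_pred, nu=nu)
    return MetricsReport(
        spearman=spearman(y_true, y_pred),
        mse=mse, mae=mae, student_t_loss=student_t,
    )
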