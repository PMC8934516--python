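"""Imbalanced binary-classification metrics and curves.

Interface prediction is heavily imbalanced, so besides accuracy the report
carries precision, recall, F1, the Matthews correlation coefficient and the
area under the ROC curve, computed from the standard confusion-count
formulas:

    Acc = (TP + TN) / (TP + TN + FP + FN)
    P   = TP / (TP + FP)
    R   = TP / (TP + FN)
    F1  = 2 P R / (P + R)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Degenerate denominators follow the usual conventions: P, R and F1 are 0
when undefined, and MCC is 0 when any factor under the root vanishes. AUC
is the Mann-Whitney statistic (ties receive half credit), identical to
trapezoidal integration of the threshold-sweep ROC curve. Curves can also
be vertically averaged across proteins on a fixed 101-point grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    precision_recall_curve as _sk_pr_curve,
    roc_auc_score,
    roc_curve as _sk_roc_curve,
)

CURVE_GRID_POINTS = 101


class EvaluationError(ValueError):
    """Raised on empty masks or single-class curve requests."""


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalReport:
    """Scalar metrics plus ROC and precision-recall point lists."""

    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auc_roc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    pr_points: list[tuple[float, float]] = field(default_factory=list)

    def to_row(self) -> dict[str, float]:
        """Scalar metrics in the report-table column order."""
        return {
            "F1": self.f1,
            "Accuracy": self.accuracy,
            "Precision": self.precision,
            "Recall": self.recall,
            "MCC": self.mcc,
            "AUC-ROC": self.auc_roc,
        }


def _apply_mask(
    labels: np.ndarray, scores: np.ndarray, mask: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise EvaluationError("labels and scores are not aligned")
    if mask is None:
        mask = np.ones(labels.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EvaluationError("mask selects no nodes")
    return labels[mask], scores[mask]


def confusion(
    labels: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
    mask: np.ndarray | None = None,
) -> ConfusionCounts:
    """Confusion counts at a score threshold (prediction = score >= t)."""
    y, s = _apply_mask(labels, scores, mask)
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def scalar_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float, float]:
    """(Acc, P, R, F1, MCC) from confusion counts, degenerate cases -> 0."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    total = counts.total
    if total == 0:
        raise EvaluationError("no evaluated nodes")
    acc = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    radicand = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(radicand) if radicand > 0 else 0.0
    return acc, precision, recall, f1, float(mcc)


def roc_auc(
    labels: np.ndarray,
    scores: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[float, list[tuple[float, float]]]:
    """AUC (Mann-Whitney, half credit for ties) and the (FPR, TPR) curve."""
    y, s = _apply_mask(labels, scores, mask)
    if np.unique(y).size < 2:
        raise EvaluationError("AUC undefined: mask contains a single class")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def pr_curve(
    labels: np.ndarray,
    scores: np.ndarray,
    mask: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """(recall, precision) pairs with recall nondecreasing along the list."""
    y, s = _apply_mask(labels, scores, mask)
    if not np.any(y == 1):
        raise EvaluationError("PR curve undefined: no positive nodes in mask")
    precision, recall, _ = _sk_pr_curve(y, s)
    points = sorted(zip(recall.tolist(), precision.tolist()))
    return points


def averaged_curves(
    per_protein_curves: Sequence[Sequence[tuple[float, float]] | None],
    kind: str = "roc",
) -> list[tuple[float, float]]:
    """Vertical average of per-protein curves on a fixed 101-point grid.

    Proteins whose curve is undefined (passed as ``None``) are skipped.
    ROC grids are pinned at (0, 0) and (1, 1).
    """
    defined = [c for c in per_protein_curves if c]
    if not defined:
        raise EvaluationError("no defined curves to average")
    grid = np.linspace(0.0, 1.0, CURVE_GRID_POINTS)
    stack = []
    for curve in defined:
        xs = np.array([p[0] for p in curve])
        ys = np.array([p[1] for p in curve])
        order = np.argsort(xs, kind="stable")
        xs, ys = xs[order], ys[order]
        if kind == "roc":
            if xs[0] > 0:
                xs, ys = np.r_[0.0, xs], np.r_[0.0, ys]
            if xs[-1] < 1:
                xs, ys = np.r_[xs, 1.0], np.r_[ys, 1.0]
        stack.append(np.interp(grid, xs, ys))
    mean = np.mean(stack, axis=0)
    if kind == "roc":
        mean[0], mean[-1] = 0.0, 1.0
    return list(zip(grid.tolist(), mean.tolist()))


def evaluate(
    labels: np.ndarray,
    scores: np.ndarray,
    mask: np.ndarray | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """Full report: counts, six scalar metrics, ROC and PR point lists."""
    counts = confusion(labels, scores, threshold, mask)
    acc, precision, recall, f1, mcc = scalar_metrics(counts)
    y, _ = _apply_mask(labels, scores, mask)
    if np.unique(y).size == 2:
        auc, roc_points = roc_auc(labels, scores, mask)
        pr_points = pr_curve(labels, scores, mask)
    else:
        auc, roc_points, pr_points = float("nan"), [], []
    return EvalReport(
        counts=counts,
        accuracy=acc,
        precision=precision,
        recall=recall,
        f1=f1,
        mcc=mcc,
        auc_roc=auc,
        roc_points=roc_points,
        pr_points=pr_points,
    )


def report_to_csv(rows: Sequence[dict], path: str | Path) -> Path:
    """Write scalar-metric rows (plus any id columns) as CSV."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(list(rows)).to_csv(path, index=False, float_format="%.6f")
    return path


def curve_to_csv(points: Sequence[tuple[float, float]], path: str | Path,
                 columns: tuple[str, str] = ("x", "y")) -> Path:
    import pandas as pd

    path = Path(path)
    pd.DataFrame(points, columns=list(columns)).to_csv(
        path, index=False, float_format="%.8f"
    )
    return path
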