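"""Superpixel-level classification metrics and voxel-level Dice overlap.

Classification metrics (precision, sensitivity, balanced error rate) score
the superpixel labels before region filtering; Dice scores the final 3D
voxel mask against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = ["ClassificationMetrics", "EvalReport", "classification_metrics", "dice"]


class ClassificationMetrics(NamedTuple):
    precision: float
    sensitivity: float
    ber: float


def classification_metrics(pred: np.ndarray, truth: np.ndarray) -> ClassificationMetrics:
    """precision = TP/(TP+FP); sensitivity = TP/(TP+FN);
    BER = (FN/(TP+FN) + FP/(FP+TN)) / 2.

    Empty denominators: the metric is 0 and the corresponding BER term is 0.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    fnr = fn / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    return ClassificationMetrics(precision, sensitivity, 0.5 * (fnr + fpr))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks give 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(a & b) / denom)


@dataclass
class EvalReport:
    """Per-case metrics plus cohort mean/std summary."""

    per_case: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["case", "precision", "sensitivity", "ber", "dice"]))

    def add_case(self, case: str, metrics: ClassificationMetrics, dice_score: float) -> None:
        self.per_case.loc[len(self.per_case)] = [
            case, metrics.precision, metrics.sensitivity, metrics.ber, dice_score,
        ]

    def summary(self) -> dict[str, dict[str, float]]:
        cols = ["precision", "sensitivity", "ber", "dice"]
        return {
            c: {"mean": float(self.per_case[c].mean()), "std": float(self.per_case[c].std(ddof=0))}
            for c in cols
        }
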