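"""Segmentation evaluation: Dice, Jaccard and confusion-matrix rates.

Dice(A,B) = 2|A∩B| / (|A|+|B|), Jaccard(A,B) = |A∩B| / |A∪B|, with the
identity Jaccard = Dice / (2 - Dice).  Confusion rates (precision,
accuracy, recall) are computed over a configurable evaluation region:
the breast mask by default, or the full frame (which inflates TN, the
mode matching whole-image accuracy figures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError


def _as_masks(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise UndefinedMetricError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = _as_masks(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise UndefinedMetricError("Dice undefined: both masks empty")
    return 2.0 * int((a & b).sum()) / denom


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a, b = _as_masks(a, b)
    union = int((a | b).sum())
    if union == 0:
        raise UndefinedMetricError("Jaccard undefined: both masks empty")
    return int((a & b).sum()) / union


@dataclass
class EvalReport:
    """Overlap metrics and confusion counts/rates for one prediction.

    Rates with a zero denominator are ``None`` and listed in ``undefined``.
    """

    dice: float
    jaccard: float
    TP: int
    FP: int
    TN: int
    FN: int
    precision: float | None
    accuracy: float | None
    recall: float | None
    undefined: list[str]

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "jaccard": self.jaccard,
            "TP": self.TP,
            "FP": self.FP,
            "TN": self.TN,
            "FN": self.FN,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "recall": self.recall,
            "undefined": list(self.undefined),
        }


def confusion_metrics(
    pred: np.ndarray, truth: np.ndarray, region: np.ndarray | None = None
) -> EvalReport:
    """Counts and rates restricted to ``region`` (default: full frame)."""
    pred, truth = _as_masks(pred, truth)
    if region is None:
        region = np.ones_like(pred, bool)
    region = np.asarray(region, bool)
    if not region.any():
        raise UndefinedMetricError("evaluation region is empty")
    p = pred[region]
    t = truth[region]
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    tn = int((~p & ~t).sum())
    undefined: list[str] = []

    def rate(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    precision = rate(tp, tp + fp, "precision")
    recall = rate(tp, tp + fn, "recall")
    accuracy = rate(tp + tn, tp + tn + fp + fn, "accuracy")
    return EvalReport(
        dice=dice(pred & region, truth & region) if (p.any() or t.any()) else float("nan"),
        jaccard=jaccard(pred & region, truth & region) if (p.any() or t.any()) else float("nan"),
        TP=tp,
        FP=fp,
        TN=tn,
        FN=fn,
        precision=precision,
        accuracy=accuracy,
        recall=recall,
        undefined=undefined,
    )
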