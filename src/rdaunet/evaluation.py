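"""Pixel-level segmentation metrics and model-comparison reports.

Five indicators are computed from the pixel confusion counts (TP = organoid
pixels classified as organoid, TN = background as background, FP =
background as organoid, FN = organoid as background):

    Acc       = (TP + TN) / (TP + TN + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    IoU       = TP / (TP + FP + FN)
    DSC       = 2 TP / (2 TP + FP + FN)

For counts pooled over a test set, DSC = 2 IoU / (1 + IoU) holds exactly,
hence DSC >= IoU -- a useful internal consistency check.  Metrics can be
pooled (one global confusion) or averaged per image; both are reported and
labelled since published tables do not always say which was used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts", "SegMetrics", "binarize", "confusion", "metrics",
    "evaluate_model", "comparison_report", "published_benchmark",
]


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

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class SegMetrics:
    acc: float
    precision: float
    recall: float
    iou: float
    dsc: float
    aggregation: str = "pooled"       # "pooled" | "per-image-mean"
    degenerate: bool = False          # any 0/0 ratio encountered (reported as 1)

    def as_dict(self) -> dict:
        return {"acc": self.acc, "precision": self.precision,
                "recall": self.recall, "iou": self.iou, "dsc": self.dsc}


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ties (p == threshold) go to foreground."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return (np.asarray(prob) >= threshold).astype(np.uint8)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return 1.0, True      # 0/0: empty prediction and truth agree perfectly
    return num / den, False


def metrics(counts: ConfusionCounts, aggregation: str = "pooled") -> SegMetrics:
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    acc = (tp + tn) / counts.total
    precision, d1 = _ratio(tp, tp + fp)
    recall, d2 = _ratio(tp, tp + fn)
    iou, d3 = _ratio(tp, tp + fp + fn)
    dsc, d4 = _ratio(2 * tp, 2 * tp + fp + fn)
    return SegMetrics(acc, precision, recall, iou, dsc, aggregation,
                      degenerate=d1 or d2 or d3 or d4)


def evaluate_model(model, dataset, threshold: float = 0.5):
    """Evaluate on ``dataset`` (iterable of (image, truth-mask) pairs).

    Returns ``(pooled, per_image_mean, per_image_table)``: metrics from the
    summed confusion, the per-image average of each metric, and a
    per-image DataFrame.
    """
    from .training import predict  # local import avoids a cycle

    if not dataset:
        raise ValueError("dataset is empty")
    rows, pooled = [], ConfusionCounts(0, 0, 0, 0)
    for i, (img, msk) in enumerate(dataset):
        prob = predict(model, img)
        c = confusion(binarize(prob, threshold), msk)
        pooled = pooled + c
        m = metrics(c, aggregation="per-image")
        rows.append({"image": i, **m.as_dict(), "degenerate": m.degenerate,
                     "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn})
    table = pd.DataFrame(rows)
    mean = table[["acc", "precision", "recall", "iou", "dsc"]].mean()
    per_image_mean = SegMetrics(*mean.tolist(), aggregation="per-image-mean",
                                degenerate=bool(table["degenerate"].any()))
    return metrics(pooled), per_image_mean, table


def comparison_report(table: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Pairwise differences (reference minus each other variant), in the
    units of ``table`` (percentage points for a table in percent).

    ``table`` is indexed by variant name with one column per metric; a
    metric missing for a variant propagates as NaN (absent, not zero).
    """
    if len(table) < 2:
        raise ValueError("need at least two variants to compare")
    if reference not in table.index:
        raise KeyError(f"reference variant {reference!r} not in table")
    others = table.drop(index=reference)
    diff = table.loc[reference] - others
    diff.index.name = f"{reference} minus"
    return diff.round(10)


def published_benchmark() -> pd.DataFrame:
    """Published test-set indicators (percent) for the eight model variants
    on the bladder-cancer organoid dataset; used to exercise the
    comparison-report arithmetic, not as a reproduction target."""
    data = {
        "U-Net":            [99.98, 76.50, 95.68, 84.74, 86.23],
        "Attention U-Net":  [99.14, 82.63, 93.75, 87.84, 88.72],
        "MultiResU-Net":    [99.02, 79.50, 94.73, 85.94, 87.28],
        "U-Net++":          [99.11, 82.30, 93.55, 87.67, 89.15],
        "RDAU-Net_w/A":     [99.27, 83.03, 97.09, 89.51, 90.13],
        "RDAU-Net_w/C":     [99.26, 83.53, 96.31, 89.47, 90.09],
        "RDAU-Net_w/D":     [99.17, 79.97, 97.27, 87.78, 88.68],
        "RDAU-Net":         [99.32, 86.73, 97.65, 90.14, 90.23],
    }
    return pd.DataFrame.from_dict(
        data, orient="index",
        columns=["acc", "precision", "recall", "dsc", "iou"])
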