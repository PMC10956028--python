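"""Segmentation, regression, and classification evaluation metrics.

Segmentation quality is scored with the Dice similarity coefficient

    Dice = 2 |GT ∩ PM| / (|GT| + |PM|)

between ground truth (GT) and predicted (PM) masks, and with the 95th
percentile Hausdorff distance

    HD95(PM, GT) = max( P95_{p in ∂PM} d(p, ∂GT),  P95_{g in ∂GT} d(g, ∂PM) )

over boundary points, in physical units.  Regression uses the mean
squared error MSE = (1/n) Σ (T_i - P_i)²; classification uses balanced
accuracy, the arithmetic mean of sensitivity TP/(TP+FN) and specificity
TN/(TN+FP), which sits at 0.5 for any trivial binary classifier
regardless of class prevalence.

Conventions: Dice of two empty masks is 1.0 (perfect agreement on
absence) and 0.0 when exactly one side is empty; undefined metrics
(empty boundary sets, zero denominators) return NaN so they are reported
as missing rather than as spurious zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .imagecore import LabelMap

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "dice",
    "hausdorff95",
    "mse",
    "balanced_accuracy",
    "multiclass_balanced_accuracy",
    "mean_multiclass_dice",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts: TP, TN, FP, FN."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("confusion counts must not all be zero")


def _class_mask(lm: LabelMap, class_id) -> np.ndarray:
    """Binarize one class; composite classes are label-set unions."""
    if isinstance(class_id, (set, frozenset, tuple, list)):
        return np.isin(lm.data, list(class_id))
    return lm.data == int(class_id)


def dice(gt: LabelMap, pred: LabelMap, class_id) -> float:
    """Dice overlap of one (possibly composite) class between two maps."""
    if gt.spatial_shape != pred.spatial_shape:
        raise ValueError(f"shape mismatch: {gt.spatial_shape} vs {pred.spatial_shape}")
    a = _class_mask(gt, class_id)
    b = _class_mask(pred, class_id)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Class pixels with at least one non-class face-neighbour."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)  # faces only
    eroded = ndimage.binary_erosion(mask, structure, border_value=0)
    return mask & ~eroded


def hausdorff95(
    gt: LabelMap, pred: LabelMap, class_id, spacing: Optional[Sequence[float]] = None
) -> float:
    """95th-percentile symmetric boundary distance in physical units.

    Returns NaN when either class set is empty (undefined rather than 0).
    Percentiles interpolate linearly between order statistics so the
    result is continuous in the distance multiset.
    """
    if gt.spatial_shape != pred.spatial_shape:
        raise ValueError(f"shape mismatch: {gt.spatial_shape} vs {pred.spatial_shape}")
    if spacing is None:
        spacing = gt.spacing
    spacing = tuple(float(s) for s in spacing)
    a = _class_mask(gt, class_id)
    b = _class_mask(pred, class_id)
    if not a.any() or not b.any():
        return math.nan
    ba = _boundary(a)
    bb = _boundary(b)

    def directed(src: np.ndarray, dst: np.ndarray) -> float:
        # exact Euclidean distance to the nearest dst boundary pixel
        dist = ndimage.distance_transform_edt(~dst, sampling=spacing)
        return float(np.percentile(dist[src], 95))

    return max(directed(ba, bb), directed(bb, ba))


def mse(targets: Sequence[float], predictions: Sequence[float]) -> float:
    """Mean squared error between targets and predictions."""
    t = np.asarray(targets, dtype=np.float64)
    p = np.asarray(predictions, dtype=np.float64)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("mse needs at least one sample")
    return float(np.mean((t - p) ** 2))


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """Arithmetic mean of sensitivity and specificity; NaN if undefined."""
    pos = counts.TP + counts.FN
    neg = counts.TN + counts.FP
    if pos == 0 or neg == 0:
        return math.nan
    return 0.5 * (counts.TP / pos + counts.TN / neg)


def multiclass_balanced_accuracy(gt_classes: Sequence[int], pred_classes: Sequence[int]) -> float:
    """Macro-average of per-class recall; reduces to balanced accuracy
    for two classes.  Classes absent from the ground truth are excluded
    from the average."""
    gt = np.asarray(gt_classes)
    pred = np.asarray(pred_classes)
    if gt.shape != pred.shape:
        raise ValueError("gt and pred must have equal length")
    recalls = []
    for cls in np.unique(gt):
        sel = gt == cls
        recalls.append(float(np.mean(pred[sel] == cls)))
    if not recalls:
        return math.nan
    return float(np.mean(recalls))


def mean_multiclass_dice(gt: LabelMap, pred: LabelMap, classes: Sequence) -> float:
    """Mean Dice over a list of classes (background excluded by the
    caller); entries may be composite label-set unions, e.g. a "whole
    tumor" class formed from several sub-region labels."""
    if not classes:
        raise ValueError("classes must be non-empty")
    return float(np.mean([dice(gt, pred, c) for c in classes]))


@dataclass
class MetricReport:
    """Accumulating per-fold, per-subject, per-class metric table.

    Serializes to a CSV with columns outer_fold, inner_fold, subject_id,
    metric, class, value for reporting and debugging.
    """

    rows: List[dict] = field(default_factory=list)

    def add(
        self,
        metric: str,
        value: float,
        outer_fold: int = 0,
        inner_fold: int = 0,
        subject_id: str = "",
        class_id: Union[int, str] = "",
    ) -> None:
        self.rows.append(
            {
                "outer_fold": outer_fold,
                "inner_fold": inner_fold,
                "subject_id": subject_id,
                "metric": metric,
                "class": class_id,
                "value": value,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["outer_fold", "inner_fold", "subject_id", "metric", "class", "value"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def aggregate(self, metric: str) -> float:
        """Mean of one metric over all rows that carry it (NaNs excluded)."""
        frame = self.to_frame()
        vals = frame.loc[frame["metric"] == metric, "value"].astype(float)
        return float(vals.mean())
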