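"""Detection and counting metrics.

Detection quality is scored by matching predicted plant boxes to
ground-truth boxes (greedy, by descending intersection-over-union; a
pair counts as a true positive when IoU >= iou_min, and at most one
prediction may claim each ground truth).  From the TP/FP/FN counts:

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * precision * recall / (precision + recall)

Segmentation quality is the foreground–background dice

    FBD = 2 |P_sg ∩ P_gt| / (|P_sg| + |P_gt|)

and counting quality the signed and absolute difference in count over N
plants:

    DiC     = mean(GT_i - LF_i)        (positive = undercounting)
    ABS_DiC = mean(|GT_i - LF_i|)

Per-frame records aggregate to unweighted group means (per scene, per
plant, day/night, or method) plus an overall mean row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import BBox, Detection

__all__ = [
    "GroundTruthScene",
    "ConfusionCounts",
    "match_detections",
    "prf",
    "fbd",
    "dic_abs_dic",
    "aggregate",
]

logger = logging.getLogger(__name__)


@dataclass
class GroundTruthScene:
    """Reference annotation for one frame."""

    boxes: list[BBox]
    leaf_counts: list[int]
    mask: np.ndarray | None = None  # optional foreground ground truth

    def __post_init__(self) -> None:
        if len(self.boxes) != len(self.leaf_counts):
            raise ValueError("one leaf count per ground-truth box required")
        if any(c < 0 for c in self.leaf_counts):
            raise ValueError("leaf counts must be >= 0")


@dataclass(frozen=True)
class ConfusionCounts:
    """Absolute TP/FP/FN for one frame."""

    tp: int
    fp: int
    fn: int

    def normalized(self) -> tuple[float, float, float]:
        """Fractions of the ground-truth plant count (TP + FN)."""
        n = self.tp + self.fn
        if n == 0:
            return (0.0, float(self.fp), 0.0)
        return (self.tp / n, self.fp / n, self.fn / n)


def match_detections(
    pred: Detection | list[BBox],
    gt: GroundTruthScene | list[BBox],
    iou_min: float = 0.5,
) -> ConfusionCounts:
    """Greedy one-to-one box matching by descending IoU."""
    if not 0 < iou_min <= 1:
        raise ValueError("iou_min must be in (0, 1]")
    pred_boxes = pred.boxes if isinstance(pred, Detection) else list(pred)
    gt_boxes = gt.boxes if isinstance(gt, GroundTruthScene) else list(gt)
    pairs = [
        (p.iou(g), i, j)
        for i, p in enumerate(pred_boxes)
        for j, g in enumerate(gt_boxes)
        if p.iou(g) >= iou_min
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        tp += 1
    return ConfusionCounts(tp=tp, fp=len(pred_boxes) - tp, fn=len(gt_boxes) - tp)


def prf(counts: ConfusionCounts | tuple[float, float, float]) -> tuple[float, float, float]:
    """(recall, precision, F1) from TP/FP/FN; zero denominators yield 0."""
    if isinstance(counts, ConfusionCounts):
        tp, fp, fn = counts.tp, counts.fp, counts.fn
    else:
        tp, fp, fn = counts
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        logger.warning("recall undefined (no ground truth); reporting 0")
        recall = 0.0
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        logger.warning("precision undefined (no predictions); reporting 0")
        precision = 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return (recall, precision, f1)


def fbd(p_sg: np.ndarray, p_gt: np.ndarray) -> float:
    """Foreground–background dice of two masks; two empty masks give 1."""
    p_sg = np.asarray(p_sg, dtype=bool)
    p_gt = np.asarray(p_gt, dtype=bool)
    if p_sg.shape != p_gt.shape:
        raise ValueError(f"mask shapes differ: {p_sg.shape} vs {p_gt.shape}")
    total = int(p_sg.sum()) + int(p_gt.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((p_sg & p_gt).sum()) / total


def dic_abs_dic(
    gt_counts: list[int] | np.ndarray, lf_counts: list[int] | np.ndarray
) -> tuple[float, float, float, float]:
    """(DiC, ABS_DiC, sd(DiC), sd(ABS_DiC)) over paired leaf counts.

    Standard deviations are the sample kind (ddof=1); a single pair
    reports 0 spread.
    """
    gt = np.asarray(gt_counts, dtype=np.float64)
    lf = np.asarray(lf_counts, dtype=np.float64)
    if gt.shape != lf.shape or gt.ndim != 1 or gt.size == 0:
        raise ValueError("gt_counts and lf_counts must be equal-length, non-empty")
    diff = gt - lf
    ddof = 1 if gt.size > 1 else 0
    return (
        float(diff.mean()),
        float(np.abs(diff).mean()),
        float(diff.std(ddof=ddof)),
        float(np.abs(diff).std(ddof=ddof)),
    )


_GROUP_KEYS = {"scene": "scene", "plant": "plant", "day_night": "day_night", "method": "method"}


def aggregate(records: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Unweighted group means of the numeric metric columns.

    ``records`` holds one row per frame (or per plant) with a grouping
    column (scene / plant / day_night / method) and numeric metric
    columns.  Returns one row per group plus an ``overall`` row that is
    the unweighted mean of the group means.
    """
    key = _GROUP_KEYS.get(grouping)
    if key is None:
        raise ValueError(f"unknown grouping {grouping!r}")
    if key not in records.columns:
        raise ValueError(f"records lack a {key!r} column")
    numeric = records.select_dtypes(include=[np.number])
    groups = records[key]
    empty = records[key].isna()
    if empty.any():
        logger.warning("dropping %d records with missing %s", int(empty.sum()), key)
        numeric = numeric[~empty]
        groups = groups[~empty]
    table = numeric.groupby(groups).mean()
    table.index.name = key
    overall = table.mean(axis=0).to_frame().T
    overall.index = pd.Index(["overall"], name=key)
    return pd.concat([table, overall])
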