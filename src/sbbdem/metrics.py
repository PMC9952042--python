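"""Detection and segmentation evaluation.

Boxes use a 0-based, half-open pixel convention: a box (x, y, w, h) covers
columns [x, x+w) and rows [y, y+h).  Detection matching is the standard
PASCAL-style protocol — detections sorted by descending confidence, greedy
one-to-one assignment to ground truths at an IoU threshold.

Two readings of "mAP" are reported: the area under the all-point
interpolated precision-recall curve (the headline metric) and the literal
precision ratio TP / (TP + FP) at fixed confidence/IoU thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "BoundingBox",
    "Detection",
    "MatchResult",
    "PRCurve",
    "SegEval",
    "box_iou",
    "match_detections",
    "mean_average_precision",
    "detection_rate",
    "cs_accuracy",
    "mask_eval",
    "roc_auc",
    "tight_box",
]


@dataclass(frozen=True)
class BoundingBox:
    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"degenerate box: w={self.w}, h={self.h}")

    @property
    def area(self) -> int:
        return self.w * self.h


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    cs: float  # confidence score
    image_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.cs <= 1.0):
            raise ValueError(f"confidence score must be in [0, 1], got {self.cs}")


@dataclass(frozen=True)
class MatchResult:
    """TP/FP flags per detection (confidence-sorted) and FN bookkeeping."""

    det_is_tp: tuple[bool, ...]
    det_cs: tuple[float, ...]
    matched_gt: tuple[int, ...]  # gt index per detection, -1 for FP
    n_gt: int

    @property
    def tp(self) -> int:
        return sum(self.det_is_tp)

    @property
    def fp(self) -> int:
        return len(self.det_is_tp) - self.tp

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp


@dataclass(frozen=True)
class PRCurve:
    recall: tuple[float, ...]
    precision: tuple[float, ...]
    ap: float


@dataclass(frozen=True)
class SegEval:
    iou_mass: float
    iou_background: float
    mean_iou: float
    accuracy: float


def tight_box(mask: np.ndarray) -> BoundingBox:
    """Tight axis-aligned bounding box of a non-empty binary mask."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return BoundingBox(
        x=int(cols[0]), y=int(rows[0]),
        w=int(cols[-1] - cols[0] + 1), h=int(rows[-1] - rows[0] + 1),
    )


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes (Jaccard index)."""
    ix = max(0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
    iy = max(0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[BoundingBox],
    iou_min: float = 0.5,
    cs_min: float = 0.5,
) -> MatchResult:
    """Greedy confidence-descending matching with one-to-one GT assignment."""
    kept = [d for d in dets if d.cs >= cs_min]
    order = sorted(range(len(kept)), key=lambda i: -kept[i].cs)
    gt_taken = [False] * len(gts)
    flags: list[bool] = []
    cs_list: list[float] = []
    matched: list[int] = []
    for i in order:
        d = kept[i]
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if gt_taken[j]:
                continue
            iou = box_iou(d.box, g)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_min:
            gt_taken[best_j] = True
            flags.append(True)
            matched.append(best_j)
        else:
            flags.append(False)
            matched.append(-1)
        cs_list.append(d.cs)
    return MatchResult(tuple(flags), tuple(cs_list), tuple(matched), n_gt=len(gts))


def mean_average_precision(
    dets: Sequence[Detection],
    gts: Sequence[BoundingBox],
    iou_min: float = 0.5,
    cs_min: float = 0.5,
    interpolation: str = "all-point",
) -> tuple[PRCurve, float]:
    """PR-AUC average precision plus the literal precision ratio TP/(TP+FP).

    The curve is built by sweeping the confidence ranking of the surviving
    detections; AP integrates the interpolated precision envelope
    (all-point by default, 11-point selectable).  The second return value
    is the fixed-threshold precision ratio; it is NaN when no detection
    survives the confidence cut.
    """
    if len(gts) == 0:
        raise ValueError("no ground truths: recall undefined")
    match = match_detections(dets, gts, iou_min=iou_min, cs_min=cs_min)

    if len(match.det_is_tp) == 0:
        return PRCurve(recall=(), precision=(), ap=0.0), float("nan")

    tps = np.cumsum(np.asarray(match.det_is_tp, dtype=float))
    fps = np.cumsum(~np.asarray(match.det_is_tp))
    recall = tps / len(gts)
    precision = tps / (tps + fps)

    if interpolation == "all-point":
        # precision envelope: max precision at recall >= r
        env = np.maximum.accumulate(precision[::-1])[::-1]
        r_prev = 0.0
        ap = 0.0
        for r, p in zip(recall, env):
            ap += (r - r_prev) * p
            r_prev = r
    elif interpolation == "11-point":
        ap = float(
            np.mean([
                max((p for r, p in zip(recall, precision) if r >= level), default=0.0)
                for level in np.linspace(0.0, 1.0, 11)
            ])
        )
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")

    eq_ratio = float(match.tp / (match.tp + match.fp)) if (match.tp + match.fp) else float("nan")
    return PRCurve(tuple(recall), tuple(precision), float(ap)), eq_ratio


def detection_rate(per_image: Sequence[MatchResult]) -> float:
    """Percentage of images with at least one true-positive detection."""
    if len(per_image) == 0:
        raise ValueError("need at least one image")
    hit = sum(1 for m in per_image if m.tp > 0)
    return 100.0 * hit / len(per_image)


def cs_accuracy(per_image: Sequence[MatchResult], per_box: bool = False) -> float:
    """Mean confidence of true positives over detected images, as a percentage.

    Default: the best (highest-confidence) TP per detected image is
    averaged; ``per_box=True`` averages over every TP box instead.
    """
    values: list[float] = []
    for m in per_image:
        tp_cs = [c for c, ok in zip(m.det_cs, m.det_is_tp) if ok]
        if not tp_cs:
            continue
        if per_box:
            values.extend(tp_cs)
        else:
            values.append(max(tp_cs))
    if not values:
        raise ValueError("no detected images: CS accuracy undefined")
    return 100.0 * float(np.mean(values))


def mask_eval(pred: np.ndarray, gt: np.ndarray) -> SegEval:
    """Pixelwise segmentation metrics: per-class IoU, mean IoU, accuracy."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    tn = int((~pred & ~gt).sum())
    iou_mass = tp / (tp + fp + fn) if (tp + fp + fn) else 1.0
    iou_bg = tn / (tn + fp + fn) if (tn + fp + fn) else 1.0
    acc = (tp + tn) / (tp + fp + fn + tn)
    return SegEval(iou_mass, iou_bg, (iou_mass + iou_bg) / 2.0, acc)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (rank statistic with midrank tie handling)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
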