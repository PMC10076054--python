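"""Object-detection metrics: IoU matching, average precision, count errors.

The validation protocol standard for crop-head detectors: detections are
greedily matched to ground truth in descending confidence order at a
fixed IoU threshold (0.5 by default), precision-recall is swept over
confidence, AP is the area under the all-point-interpolated precision
envelope, and per-image head counts are compared by MAE and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from fieldheads.geo_io import Detection

__all__ = [
    "MatchResult",
    "iou",
    "match",
    "average_precision",
    "count_errors",
]


def iou(a: Detection | tuple, b: Detection | tuple) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ax0, ay0, ax1, ay1 = _corners(a)
    bx0, by0, bx1, by1 = _corners(b)
    if ax1 <= ax0 or ay1 <= ay0 or bx1 <= bx0 or by1 <= by0:
        raise ValueError("degenerate box")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def _iou_matrix(dets: Sequence[Detection], gts: Sequence[Detection]) -> np.ndarray:
    """Pairwise IoU, detections x ground truths (same arithmetic as
    :func:`iou`, vectorized)."""
    if not dets or not gts:
        return np.zeros((len(dets), len(gts)))
    a = np.array([_corners(d) for d in dets])[:, None, :]
    b = np.array([_corners(g) for g in gts])[None, :, :]
    iw = np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0])
    ih = np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1])
    inter = np.where((iw > 0) & (ih > 0), iw * ih, 0.0)
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    return inter / (area_a + area_b - inter)


def _corners(box) -> tuple[float, float, float, float]:
    if isinstance(box, Detection):
        return box.x_min, box.y_min, box.x_max, box.y_max
    return tuple(float(v) for v in box)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one image's detections against ground truth.

    Arrays are aligned with the detections sorted by descending
    confidence (``order`` maps back to the caller's indexing).  ``matched_gt``
    is -1 for false positives; ``n_gt`` includes unmatched (FN) boxes.
    """

    order: np.ndarray
    confidence: np.ndarray
    is_tp: np.ndarray
    matched_gt: np.ndarray
    iou_value: np.ndarray
    n_gt: int

    @property
    def n_tp(self) -> int:
        return int(self.is_tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.is_tp).sum())

    @property
    def n_fn(self) -> int:
        return self.n_gt - self.n_tp


def match(
    dets: Sequence[Detection],
    gts: Sequence[Detection],
    iou_thresh: float = 0.5,
) -> MatchResult:
    """Greedy confidence-ordered matching at a fixed IoU threshold.

    Each detection, in descending confidence order (stable for ties),
    claims the still-unmatched ground-truth box of highest IoU >= the
    threshold; IoU ties go to the lower ground-truth index.  Unclaimed
    detections are false positives, unclaimed ground truths false
    negatives.
    """
    order = np.argsort([-d.confidence for d in dets], kind="stable")
    taken = np.zeros(len(gts), dtype=bool)
    is_tp = np.zeros(len(dets), dtype=bool)
    matched = np.full(len(dets), -1, dtype=int)
    ious = np.zeros(len(dets), dtype=float)
    iou_matrix = _iou_matrix(dets, gts)
    for pos, di in enumerate(order):
        row = np.where(taken, -1.0, iou_matrix[di])
        best_j = int(np.argmax(row)) if row.size else -1
        if best_j >= 0 and row[best_j] >= iou_thresh:
            taken[best_j] = True
            is_tp[pos] = True
            matched[pos] = best_j
            ious[pos] = row[best_j]
    return MatchResult(
        order=order,
        confidence=np.array([dets[i].confidence for i in order], dtype=float),
        is_tp=is_tp,
        matched_gt=matched,
        iou_value=ious,
        n_gt=len(gts),
    )


def average_precision(result: MatchResult) -> tuple[float, np.ndarray]:
    """All-point-interpolated average precision and the PR curve.

    Sweeping the confidence ranking, precision is replaced by its running
    maximum from the right (the precision envelope) and AP is the sum of
    envelope precision times recall increments — the single-threshold
    form of the COCO protocol.  Returns ``(ap, points)`` with points as an
    (n, 2) array of (recall, precision).
    """
    if result.n_gt == 0:
        raise ValueError("average precision is undefined with zero ground truths")
    if result.is_tp.size == 0:
        return 0.0, np.zeros((0, 2))
    tp_cum = np.cumsum(result.is_tp)
    fp_cum = np.cumsum(~result.is_tp)
    recall = tp_cum / result.n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - prev_r) * envelope))
    return ap, np.stack([recall, precision], axis=1)


def count_errors(
    pred_counts: Sequence[float], true_counts: Sequence[float]
) -> tuple[float, float]:
    """Per-image head-count MAE and RMSE."""
    pred = np.asarray(pred_counts, dtype=float)
    true = np.asarray(true_counts, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lists must have equal length")
    if pred.size == 0:
        raise ValueError("need at least one image")
    diff = pred - true
    return float(np.mean(np.abs(diff))), float(np.sqrt(np.mean(diff**2)))
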