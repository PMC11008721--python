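"""Detection and line-fit evaluation metrics.

Detection quality follows the single-class object-detection convention:
greedy one-to-one matching of detections to ground-truth boxes in descending
confidence at an IoU threshold, yielding TP/FP/FN counts, precision, recall,
F1 (reported as percentages) and average precision as the area under the
monotone precision envelope of the PR curve.

Line-fit quality is the angular error Δθ = |arctan a1 − arctan a2| between a
fitted and a reference row line, averaged over rows; fit wall-time is
averaged over images.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .rowfit import Detection

__all__ = [
    "ConfusionCounts",
    "PRCurve",
    "LineEvalResult",
    "box_iou",
    "match_detections",
    "precision_recall_f1",
    "average_precision",
    "angular_difference",
    "aggregate_line_eval",
    "timed_call",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class PRCurve:
    precisions: np.ndarray
    recalls: np.ndarray
    ap: float


@dataclass
class LineEvalResult:
    angular_errors_rad: list[float]
    fit_times_ms: list[float]
    mean_angular_error_rad: float = 0.0
    mean_angular_error_deg: float = 0.0
    mean_fit_time_ms: float = 0.0
    n_rows: int = 0
    n_images: int = 0


def box_iou(a: Detection, b: Detection) -> float:
    iw = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    ih = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = iw * ih
    union = a.width * a.height + b.width * b.height - inter
    return inter / union if union > 0 else 0.0


def _greedy_match(dets: list[Detection], gts: list[Detection], iou_min: float) -> list[bool]:
    """TP flag per detection (given in ranked order), one-to-one greedy."""
    taken = [False] * len(gts)
    flags: list[bool] = []
    for d in dets:
        best, best_iou = -1, iou_min
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            iou = box_iou(d, g)
            if iou >= best_iou and iou > 0:
                if iou > best_iou or best < 0:
                    best, best_iou = j, iou
        if best >= 0:
            taken[best] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags


def match_detections(
    dets: list[Detection],
    gts: list[Detection],
    iou_min: float = 0.5,
    conf_min: float = 0.0,
) -> ConfusionCounts:
    """Greedy one-to-one matching in descending confidence.

    A detection is a true positive if it overlaps an as-yet-unmatched
    ground-truth box with IoU >= iou_min (taking the highest-IoU candidate);
    unmatched detections are false positives, unmatched ground truths false
    negatives.
    """
    kept = sorted((d for d in dets if d.confidence >= conf_min),
                  key=lambda d: -d.confidence)
    flags = _greedy_match(kept, gts, iou_min)
    tp = sum(flags)
    return ConfusionCounts(tp=tp, fp=len(flags) - tp, fn=len(gts) - tp)


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """P, R and F1 as percentages; zero denominators yield 0 with a warning."""
    if min(c.tp, c.fp, c.fn) < 0:
        raise ValueError("counts must be nonnegative")
    if c.tp + c.fp == 0 or c.tp + c.fn == 0:
        warnings.warn("degenerate confusion counts: zero denominator, reporting 0",
                      stacklevel=2)
    p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return 100.0 * p, 100.0 * r, 100.0 * f1


def average_precision(
    dets: list[Detection],
    gts: list[Detection],
    iou_min: float = 0.5,
    image_ids: list[int] | None = None,
    gt_image_ids: list[int] | None = None,
    n_interp: int | None = None,
) -> PRCurve:
    """Area under the PR curve (all-points interpolation by default).

    Detections are ranked by confidence across all images; TP/FP flags come
    from greedy per-image matching; precision is replaced by its monotone
    envelope from the right and integrated over recall.  ``n_interp`` (e.g.
    101) switches to fixed-grid interpolated AP.
    """
    if not gts:
        raise ValueError("average precision undefined without ground-truth boxes")
    if image_ids is None:
        image_ids = [0] * len(dets)
    if gt_image_ids is None:
        gt_image_ids = [0] * len(gts)
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    # greedy matching per image, in global rank order
    taken: dict[int, list[bool]] = {}
    gts_by_img: dict[int, list[Detection]] = {}
    for g, gid in zip(gts, gt_image_ids):
        gts_by_img.setdefault(gid, []).append(g)
    for gid, glist in gts_by_img.items():
        taken[gid] = [False] * len(glist)
    flags = np.zeros(len(dets), dtype=bool)
    for rank, i in enumerate(order):
        d = dets[i]
        gid = image_ids[i]
        glist = gts_by_img.get(gid, [])
        best, best_iou = -1, iou_min
        for j, g in enumerate(glist):
            if taken[gid][j]:
                continue
            iou = box_iou(d, g)
            if iou >= best_iou and iou > 0 and (iou > best_iou or best < 0):
                best, best_iou = j, iou
        if best >= 0:
            taken[gid][best] = True
            flags[rank] = True
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recalls = tp_cum / len(gts)
    precisions = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    env = np.maximum.accumulate(precisions[::-1])[::-1] if len(precisions) else precisions
    if n_interp is not None:
        grid = np.linspace(0.0, 1.0, n_interp)
        interp = np.array([env[recalls >= r].max() if np.any(recalls >= r) else 0.0
                           for r in grid])
        ap = float(interp.mean())
    else:
        prev_r = np.concatenate([[0.0], recalls[:-1]]) if len(recalls) else recalls
        ap = float(np.sum((recalls - prev_r) * env))
    return PRCurve(precisions=precisions, recalls=recalls, ap=ap)


def angular_difference(a1: float, a2: float, degrees: bool = False) -> float:
    """Angular error between two lines given by slopes.

    Δθ = |arctan(a1) − arctan(a2)|, wrapped to [0, π/2] since lines are
    undirected (a near-vertical slope of +50 and one of −50 differ by a small
    angle, not by nearly π).
    """
    d = abs(math.atan(a1) - math.atan(a2))
    d = min(d, math.pi - d)
    return math.degrees(d) if degrees else d


def aggregate_line_eval(
    angular_errors_rad: list[float],
    fit_times_ms: list[float],
) -> LineEvalResult:
    """Mean angular error over rows and mean fit time over images."""
    if not angular_errors_rad or not fit_times_ms:
        raise ValueError("need at least one row error and one image time")
    n_a = float(np.mean(angular_errors_rad))
    t = float(np.mean(fit_times_ms))
    return LineEvalResult(
        angular_errors_rad=list(angular_errors_rad),
        fit_times_ms=list(fit_times_ms),
        mean_angular_error_rad=n_a,
        mean_angular_error_deg=math.degrees(n_a),
        mean_fit_time_ms=t,
        n_rows=len(angular_errors_rad),
        n_images=len(fit_times_ms),
    )


def timed_call(fn, *args, **kwargs) -> tuple[object, float]:
    """Run fn and return (result, wall-time in ms); hardware-dependent, for reporting only."""
    t0 = time.perf_counter()
    out = fn(*args, **kwargs)
    return out, 1000.0 * (time.perf_counter() - t0)
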