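"""Object-detection evaluation: PR curves, average precision, mAP.

Implements the PASCAL VOC protocol: predictions sorted by descending
confidence, greedy per-image matching to the unmatched ground-truth box of
highest IoU above threshold, duplicates counted as false positives, and AP
as the area under the precision envelope (all-point interpolation) or the
classic 11-point mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .imagedata import Box, BoxAnnotationSet, ImageDataError


def box_iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two half-open boxes; 0 when disjoint."""
    if a.area == 0 or b.area == 0:
        raise ImageDataError("degenerate zero-area box")
    ix = max(0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


@dataclass
class PRCurve:
    """Precision/recall accumulated after each prediction, by falling score."""

    points: List[Tuple[float, float, float]]  # (score, precision, recall)
    n_gt: int


def _gather(annsets: Sequence[BoxAnnotationSet], class_name: str):
    out = []
    for i, s in enumerate(annsets):
        for b in s.boxes:
            if b.class_name == class_name:
                out.append((b.image_id if b.image_id is not None else str(i), b))
    return out


def detection_pr_curve(preds: Sequence[BoxAnnotationSet],
                       gts: Sequence[BoxAnnotationSet],
                       class_name: str,
                       iou_threshold: float = 0.5) -> PRCurve:
    """Build the per-class PR curve over one or more images (VOC matching)."""
    pred_boxes = _gather(preds, class_name)
    gt_boxes = _gather(gts, class_name)
    for _, b in pred_boxes:
        if b.score is None:
            raise ImageDataError(f"prediction without score: {b}")
    n_gt = len(gt_boxes)

    gt_by_image: Dict[str, List[Box]] = {}
    for img, b in gt_boxes:
        gt_by_image.setdefault(img, []).append(b)
    matched = {img: [False] * len(v) for img, v in gt_by_image.items()}

    order = sorted(range(len(pred_boxes)),
                   key=lambda i: -pred_boxes[i][1].score)
    tp = fp = 0
    points = []
    for i in order:
        img, pb = pred_boxes[i]
        best_iou, best_j = 0.0, -1
        for j, gb in enumerate(gt_by_image.get(img, [])):
            iou = box_iou(pb, gb)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold and not matched[img][best_j]:
            matched[img][best_j] = True
            tp += 1
        else:
            fp += 1
        precision = tp / (tp + fp)
        recall = tp / n_gt if n_gt else 0.0
        points.append((float(pb.score), precision, recall))
    return PRCurve(points, n_gt)


def average_precision(curve: PRCurve,
                      interpolation: str = "all_point") -> float:
    """AP from a PR curve.

    ``all_point``: area under the precision envelope (precision at recall r
    replaced by the max precision at any recall >= r).  ``eleven_point``:
    mean interpolated precision at recalls 0, 0.1, ..., 1.0.
    """
    if interpolation not in ("all_point", "eleven_point"):
        raise ImageDataError(f"unknown interpolation {interpolation!r}")
    if not curve.points or curve.n_gt == 0:
        return 0.0
    recalls = np.array([p[2] for p in curve.points])
    precisions = np.array([p[1] for p in curve.points])
    # precision envelope and recall with sentinels
    mrec = np.concatenate([[0.0], recalls, [recalls[-1]]])
    mpre = np.concatenate([[0.0], precisions, [0.0]])
    for i in range(mpre.size - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    if interpolation == "eleven_point":
        ap = 0.0
        for r in np.linspace(0, 1, 11):
            above = mpre[1:-1][recalls >= r - 1e-12]
            ap += above.max() if above.size else 0.0
        return float(ap / 11)
    idx = np.flatnonzero(mrec[1:] != mrec[:-1]) + 1
    return float(np.sum((mrec[idx] - mrec[idx - 1]) * mpre[idx]))


def mean_average_precision(preds: Sequence[BoxAnnotationSet],
                           gts: Sequence[BoxAnnotationSet],
                           classes: Sequence[str],
                           iou_threshold: float = 0.5,
                           interpolation: str = "all_point"
                           ) -> Tuple[float, Dict[str, float]]:
    """Unweighted mean of per-class APs over classes with ground truth.

    Classes with zero GT boxes anywhere are excluded with a warning.
    """
    if not classes:
        raise ImageDataError("classes must be non-empty")
    per_class: Dict[str, float] = {}
    for cls in classes:
        curve = detection_pr_curve(preds, gts, cls, iou_threshold)
        if curve.n_gt == 0:
            warnings.warn(f"class {cls!r} has no ground-truth boxes; excluded",
                          stacklevel=2)
            continue
        per_class[cls] = average_precision(curve, interpolation)
    if not per_class:
        raise ImageDataError("no class has ground-truth boxes")
    return float(np.mean(list(per_class.values()))), per_class
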