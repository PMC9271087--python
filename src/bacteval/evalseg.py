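"""Segmentation evaluation and morphometry.

Semantic IoU, one-to-one instance matching at an IoU threshold,
precision/recall (recall is the cell counting accuracy), per-dataset
reports, and per-cell morphometry (area, Crofton perimeter, circularity)
with per-track normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .imagedata import GrayImage, ImageDataError, InstanceLabelMap


def _as_labels(x) -> np.ndarray:
    if isinstance(x, InstanceLabelMap):
        return x.labels
    arr = np.asarray(x)
    if arr.dtype == bool:
        return arr.astype(np.int64)
    return arr


# ---------------------------------------------------------------------------
# Semantic IoU
# ---------------------------------------------------------------------------


def semantic_iou(pred, gt) -> float:
    """Foreground intersection-over-union of two masks or label maps.

    Instance maps are binarised (any positive label counts as foreground).
    Defined as 1.0 when both masks are empty.
    """
    p = _as_labels(pred) > 0
    g = _as_labels(gt) > 0
    if p.shape != g.shape:
        raise ImageDataError(f"shape mismatch {p.shape} vs {g.shape}")
    union = np.count_nonzero(p | g)
    if union == 0:
        return 1.0
    return np.count_nonzero(p & g) / union


# ---------------------------------------------------------------------------
# Instance matching
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    """One-to-one instance matches at a fixed IoU threshold."""

    pairs: List[Tuple[int, int, float]]  # (gt_id, pred_id, iou)
    unmatched_gt: List[int]
    unmatched_pred: List[int]
    iou_threshold: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)


def _pairwise_iou(gt: np.ndarray, pred: np.ndarray):
    """IoU for every overlapping (gt, pred) object pair via a joint histogram."""
    gt_ids, gt_inv = np.unique(gt, return_inverse=True)
    pr_ids, pr_inv = np.unique(pred, return_inverse=True)
    joint = np.zeros((gt_ids.size, pr_ids.size), dtype=np.int64)
    np.add.at(joint, (gt_inv.ravel(), pr_inv.ravel()), 1)
    gt_sizes = joint.sum(axis=1)
    pr_sizes = joint.sum(axis=0)
    entries = []
    for i, gid in enumerate(gt_ids):
        if gid == 0:
            continue
        for j, pid in enumerate(pr_ids):
            if pid == 0 or joint[i, j] == 0:
                continue
            inter = joint[i, j]
            union = gt_sizes[i] + pr_sizes[j] - inter
            entries.append((int(gid), int(pid), inter / union))
    return entries, gt_ids[gt_ids > 0], pr_ids[pr_ids > 0]


def match_instances(pred: InstanceLabelMap, gt: InstanceLabelMap,
                    iou_threshold: float = 0.5) -> MatchResult:
    """Greedily match predicted to ground-truth objects in descending IoU.

    At thresholds >= 0.5 each object can overlap at most one counterpart
    above threshold, so the greedy matching is the unique optimal one.
    Ties are broken by (gt_id, pred_id) order.
    """
    if not 0 < iou_threshold < 1:
        raise ImageDataError("iou_threshold must be in (0, 1)")
    g, p = _as_labels(gt), _as_labels(pred)
    if g.shape != p.shape:
        raise ImageDataError(f"shape mismatch {g.shape} vs {p.shape}")
    entries, gt_ids, pr_ids = _pairwise_iou(g, p)
    cand = [(gid, pid, iou) for gid, pid, iou in entries if iou >= iou_threshold]
    cand.sort(key=lambda e: (-e[2], e[0], e[1]))
    used_gt, used_pred = set(), set()
    pairs = []
    for gid, pid, iou in cand:
        if gid in used_gt or pid in used_pred:
            continue
        pairs.append((gid, pid, iou))
        used_gt.add(gid)
        used_pred.add(pid)
    unmatched_gt = [int(g_) for g_ in gt_ids if g_ not in used_gt]
    unmatched_pred = [int(p_) for p_ in pr_ids if p_ not in used_pred]
    return MatchResult(pairs, unmatched_gt, unmatched_pred, iou_threshold)


@dataclass
class PrecisionRecall:
    precision: float
    recall: float
    precision_defined: bool = True

    def __iter__(self):
        return iter((self.precision, self.recall))


def instance_precision_recall(m: MatchResult) -> PrecisionRecall:
    """Precision (specificity over predictions) and recall (counting accuracy).

    Degenerate conventions: no predictions and no GT -> (1.0, 1.0); no
    predictions with GT present -> recall 0 and precision undefined
    (``precision_defined=False``, value NaN - explicit, never silent).
    """
    tp, fp, fn = m.tp, m.fp, m.fn
    n_pred = tp + fp
    n_gt = tp + fn
    if n_pred == 0 and n_gt == 0:
        return PrecisionRecall(1.0, 1.0)
    if n_pred == 0:
        return PrecisionRecall(float("nan"), 0.0, precision_defined=False)
    precision = tp / n_pred
    recall = 1.0 if n_gt == 0 else tp / n_gt
    if n_gt == 0:
        # predictions exist but there is nothing to find: recall is vacuous
        return PrecisionRecall(precision, 1.0)
    return PrecisionRecall(precision, recall)


def evaluate_segmentation_set(pred_maps: Sequence[InstanceLabelMap],
                              gt_maps: Sequence[InstanceLabelMap],
                              iou_threshold: float = 0.5) -> pd.DataFrame:
    """Per-image IoU / precision / recall plus an unweighted mean +- sd row.

    The returned frame has one row per image and two summary rows
    (``mean``, ``sd``); sample standard deviation, 0 with an ``n=1`` note
    for single images.  CSV-serialisable as-is.
    """
    if len(pred_maps) != len(gt_maps):
        raise ImageDataError(
            f"pred/gt list length mismatch: {len(pred_maps)} vs {len(gt_maps)}")
    rows = []
    for i, (p, g) in enumerate(zip(pred_maps, gt_maps)):
        m = match_instances(p, g, iou_threshold)
        pr = instance_precision_recall(m)
        rows.append({
            "image": str(i),
            "iou": semantic_iou(p, g),
            "precision": pr.precision,
            "recall": pr.recall,
            "tp": m.tp, "fp": m.fp, "fn": m.fn,
        })
    df = pd.DataFrame(rows)
    metrics = ["iou", "precision", "recall"]
    n = len(rows)
    mean_row = {"image": "mean", **{k: df[k].mean() for k in metrics}}
    sd_row = {"image": "sd" if n > 1 else "sd(n=1)",
              **{k: (df[k].std(ddof=1) if n > 1 else 0.0) for k in metrics}}
    return pd.concat([df, pd.DataFrame([mean_row, sd_row])], ignore_index=True)


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------


@dataclass
class MorphRecord:
    """Per-cell shape descriptors.

    Area/perimeter are physical (nm-derived) when a pixel size is supplied,
    else in px units.  Circularity is 4*pi*A/P^2 with the Crofton 4-direction
    perimeter estimator, clamped to <= 1 (raw value retained).
    """

    object_id: int
    area: float
    perimeter: float
    circularity: float
    circularity_raw: float
    centroid: Tuple[float, float]  # (x, y)


def morphometry(labels: InstanceLabelMap,
                pixel_size_nm: Optional[float] = None) -> List[MorphRecord]:
    """Measure area, perimeter and circularity for every labelled cell."""
    scale = (pixel_size_nm or 1.0)
    records = []
    for rp in regionprops(labels.labels):
        area = rp.area * scale ** 2
        perim = rp.perimeter_crofton * scale  # 4-direction Crofton estimator
        raw = 4 * math.pi * area / perim ** 2 if perim > 0 else float("inf")
        cy, cx = rp.centroid
        records.append(MorphRecord(
            object_id=int(rp.label),
            area=float(area),
            perimeter=float(perim),
            circularity=min(raw, 1.0),
            circularity_raw=float(raw),
            centroid=(float(cx), float(cy)),
        ))
    return records


def normalize_track_features(trace: Sequence[float]) -> List[float]:
    """Normalise a per-track feature trace to its first value."""
    trace = list(trace)
    if not trace:
        raise ImageDataError("empty trace")
    if trace[0] == 0:
        raise ImageDataError("first trace value is zero; cannot normalise")
    return [v / trace[0] for v in trace]
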