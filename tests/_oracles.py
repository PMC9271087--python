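"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths of the package: pixel counting by
explicit set arithmetic, instance matching by exhaustive one-to-one
assignment, AP by per-threshold confusion counting, and SSIM by literal
per-pixel window evaluation via stride tricks.
"""

from __future__ import annotations

import itertools
from typing import List, Sequence, Tuple

import numpy as np


def iou_pixel_sets(a: np.ndarray, b: np.ndarray) -> float:
    """Foreground IoU by explicit pixel-set arithmetic."""
    sa = set(zip(*np.nonzero(a > 0)))
    sb = set(zip(*np.nonzero(b > 0)))
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


def pairwise_iou_table(gt: np.ndarray, pred: np.ndarray):
    """IoU for every (gt_id, pred_id) pair by per-object pixel sets."""
    gt_ids = [int(v) for v in np.unique(gt) if v > 0]
    pr_ids = [int(v) for v in np.unique(pred) if v > 0]
    gt_sets = {g: set(zip(*np.nonzero(gt == g))) for g in gt_ids}
    pr_sets = {p: set(zip(*np.nonzero(pred == p))) for p in pr_ids}
    table = {}
    for g in gt_ids:
        for p in pr_ids:
            inter = len(gt_sets[g] & pr_sets[p])
            if inter:
                table[(g, p)] = inter / len(gt_sets[g] | pr_sets[p])
    return table, gt_ids, pr_ids


def optimal_match_count(gt: np.ndarray, pred: np.ndarray,
                        iou_threshold: float) -> int:
    """Maximum number of one-to-one matches with IoU >= threshold,
    by exhaustive search over assignments."""
    table, gt_ids, pr_ids = pairwise_iou_table(gt, pred)
    cand = {k: v for k, v in table.items() if v >= iou_threshold}
    gt_with = sorted({g for g, _ in cand})

    def best(idx: int, used_pred: frozenset) -> int:
        if idx == len(gt_with):
            return 0
        g = gt_with[idx]
        out = best(idx + 1, used_pred)  # leave g unmatched
        for p in pr_ids:
            if (g, p) in cand and p not in used_pred:
                out = max(out, 1 + best(idx + 1, used_pred | {p}))
        return out

    return best(0, frozenset())


# ---------------------------------------------------------------------------
# Detection AP oracle
# ---------------------------------------------------------------------------


def ap_bruteforce(preds: Sequence[Tuple[str, float, Tuple[int, int, int, int]]],
                  gts: Sequence[Tuple[str, Tuple[int, int, int, int]]],
                  iou_threshold: float) -> float:
    """All-point AP by re-running the VOC match from scratch for every
    top-k prediction prefix and integrating the precision envelope directly.

    Boxes are ``(image_key, score, (xmin, ymin, xmax, ymax))`` for
    predictions and ``(image_key, box)`` for ground truth.
    """
    n_gt = len(gts)
    if n_gt == 0:
        return 0.0
    order = sorted(range(len(preds)), key=lambda i: -preds[i][1])

    def box_iou(a, b):
        ix = max(0, min(a[2], b[2]) - max(a[0], b[0]))
        iy = max(0, min(a[3], b[3]) - max(a[1], b[1]))
        inter = ix * iy
        if inter == 0:
            return 0.0
        aa = (a[2] - a[0]) * (a[3] - a[1])
        bb = (b[2] - b[0]) * (b[3] - b[1])
        return inter / (aa + bb - inter)

    def confusion_topk(k: int) -> int:
        """TP among the k highest-score predictions (greedy VOC matching)."""
        taken = [False] * n_gt
        tp = 0
        for i in order[:k]:
            img, _, pbox = preds[i]
            best_iou, best_j = 0.0, -1
            for j, (gimg, gbox) in enumerate(gts):
                if gimg != img or taken[j]:
                    continue
                iou = box_iou(pbox, gbox)
                if iou > best_iou:
                    best_iou, best_j = iou, j
            if best_j >= 0 and best_iou >= iou_threshold:
                taken[best_j] = True
                tp += 1
        return tp

    recalls, precisions = [], []
    for k in range(1, len(preds) + 1):
        tp = confusion_topk(k)
        precisions.append(tp / k)
        recalls.append(tp / n_gt)

    # area under the precision envelope, integrated rectangle by rectangle
    ap = 0.0
    prev_r = 0.0
    for r in sorted(set(recalls)):
        p_at = max(p for p, rr in zip(precisions, recalls) if rr >= r)
        ap += (r - prev_r) * p_at
        prev_r = r
    return ap


# ---------------------------------------------------------------------------
# SSIM oracle
# ---------------------------------------------------------------------------


def ssim_direct(pred: np.ndarray, gt: np.ndarray, data_range: float,
                window: int = 11, sigma: float = 1.5,
                k1: float = 0.01, k2: float = 0.03) -> float:
    """Single-scale SSIM mean by literal per-pixel window evaluation."""
    r = window // 2
    xk = np.arange(-r, r + 1, dtype=np.float64)
    k1d = np.exp(-(xk ** 2) / (2 * sigma ** 2))
    kern = np.outer(k1d, k1d)
    kern /= kern.sum()

    def windows(a):
        # symmetric pad == scipy.ndimage mode='reflect'
        p = np.pad(a.astype(np.float64), r, mode="symmetric")
        return np.lib.stride_tricks.sliding_window_view(p, (window, window))

    wx = windows(pred)
    wy = windows(gt)
    mu_x = np.einsum("ijkl,kl->ij", wx, kern)
    mu_y = np.einsum("ijkl,kl->ij", wy, kern)
    ex2 = np.einsum("ijkl,kl->ij", wx * wx, kern)
    ey2 = np.einsum("ijkl,kl->ij", wy * wy, kern)
    exy = np.einsum("ijkl,kl->ij", wx * wy, kern)
    var_x = ex2 - mu_x ** 2
    var_y = ey2 - mu_y ** 2
    cov = exy - mu_x * mu_y
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    smap = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)
            / ((mu_x ** 2 + mu_y ** 2 + c1) * (var_x + var_y + c2)))
    return float(smap.mean())
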