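"""Semantic-to-instance post-processing for segmentation networks.

Implements the multi-label (cytosol + boundary) workflow used to separate
touching bacterial cells: tri-mask construction from instance annotations,
boundary subtraction followed by thresholding and marker-based watershed to
recover instances from semantic predictions, plain probability-map
thresholding, and paired rotation/flip augmentation.

The boundary class is the 1-px inner rim of each object (pixels with at
least one 8-neighbour outside the object).  Where two objects touch, the
contact pixels are boundary on both sides, so no cytosol region ever spans
two objects - this is what keeps touching cells separable.
"""

from __future__ import annotations

from typing import List, Tuple, Union

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .imagedata import (GrayImage, ImageDataError, InstanceLabelMap,
                        SemanticTriMask, relabel_sequential)
from .synthgen import _inner_rims

_CONN8 = np.ones((3, 3), dtype=bool)

# defaults for probability-map post-processing; the thresholds are
# conventions (the upstream tooling does not publish its settings)
TAU_SEED = 0.5
TAU_FG = 0.5
DEFAULT_MIN_SIZE_PX = 10


def make_trimask(labels: InstanceLabelMap) -> SemanticTriMask:
    """Build the 3-class training target: 0 background, 1 cytosol, 2 boundary.

    Equivalent to drawing each annotated cell at grey value 1 with its 1-px
    boundary at grey value 2.
    """
    arr = labels.labels
    out = np.zeros(arr.shape, dtype=np.uint8)
    out[arr > 0] = 1
    out[_inner_rims(arr)] = 2
    return SemanticTriMask(out)


def _instances_from(seed_img: np.ndarray, elevation: np.ndarray,
                    support: np.ndarray, min_size_px: int) -> InstanceLabelMap:
    """Shared core: seed components -> marker-based watershed over support."""
    markers, n = ndimage.label(seed_img, structure=_CONN8)
    if n and min_size_px > 1:
        sizes = np.bincount(markers.ravel())
        small = np.flatnonzero(sizes < min_size_px)
        markers[np.isin(markers, small[small > 0])] = 0
    if markers.max() == 0:
        return InstanceLabelMap(np.zeros(seed_img.shape, dtype=np.int64))
    ws = watershed(elevation, markers=markers, mask=support, connectivity=1)
    relabelled, _ = relabel_sequential(InstanceLabelMap(ws.astype(np.int64)))
    return relabelled


def trimask_to_instances(
    pred: Union[SemanticTriMask, Tuple[GrayImage, GrayImage]],
    min_size_px: int = DEFAULT_MIN_SIZE_PX,
    tau_seed: float = TAU_SEED,
    tau_fg: float = TAU_FG,
) -> InstanceLabelMap:
    """Recover instances from a tri-mask or (cytosol, boundary) probability pair.

    The boundary channel is subtracted from the cytosol channel to obtain
    seeds; seed components of at least ``min_size_px`` become watershed
    markers; marker-based watershed on the inverted cytosol support then
    assigns every foreground pixel (boundary included) to exactly one marker.
    """
    if min_size_px < 1:
        raise ImageDataError("min_size_px must be >= 1")
    if isinstance(pred, SemanticTriMask):
        tri = pred.values
        seed = tri == 1
        support = tri > 0
        elevation = 1.0 - seed.astype(np.float64)
    else:
        p_cyto, p_bound = pred
        a, b = p_cyto.pixels, p_bound.pixels
        if a.shape != b.shape:
            raise ImageDataError("cytosol/boundary probability shape mismatch")
        if a.min() < 0 or a.max() > 1 or b.min() < 0 or b.max() > 1:
            raise ImageDataError("probability maps must lie in [0, 1]")
        seed = (a - b) >= tau_seed
        support = (a + b) >= tau_fg
        elevation = -a
    return _instances_from(seed, elevation, support, min_size_px)


def probmap_to_instances(prob: GrayImage, threshold: float,
                         min_size_px: int = DEFAULT_MIN_SIZE_PX
                         ) -> InstanceLabelMap:
    """Threshold a single probability map into instances (8-connectivity).

    Touching cells merge into one component by construction - the known
    limitation of single-channel thresholding at high cell density.
    """
    arr = prob.pixels
    if arr.min() < 0 or arr.max() > 1:
        raise ImageDataError("probability map values must lie in [0, 1]")
    if not 0 < threshold < 1:
        raise ImageDataError("threshold must be in (0, 1)")
    if min_size_px < 1:
        raise ImageDataError("min_size_px must be >= 1")
    comp, n = ndimage.label(arr >= threshold, structure=_CONN8)
    if n and min_size_px > 1:
        sizes = np.bincount(comp.ravel())
        small = np.flatnonzero(sizes < min_size_px)
        comp[np.isin(comp, small[small > 0])] = 0
    relabelled, _ = relabel_sequential(InstanceLabelMap(comp.astype(np.int64)))
    return relabelled


# ---------------------------------------------------------------------------
# Paired augmentation
# ---------------------------------------------------------------------------

_AUG_OPS = ("rot90", "rot180", "rot270", "flip_h", "flip_v")


def _apply(op: str, arr: np.ndarray) -> np.ndarray:
    if op == "rot90":
        return np.rot90(arr, 1)
    if op == "rot180":
        return np.rot90(arr, 2)
    if op == "rot270":
        return np.rot90(arr, 3)
    if op == "flip_h":
        return arr[:, ::-1]
    if op == "flip_v":
        return arr[::-1, :]
    raise ImageDataError(f"unknown augmentation op {op!r}")


def augment_pair(image: GrayImage, target, ops) -> List[dict]:
    """Apply identical rotations/flips to an image and its target.

    Returns a list of records ``{"op", "image", "target", "transposed"}``;
    the unmodified original is always first.  The three rotations give the
    common 4x dataset increase.
    """
    t_arr = target.labels if isinstance(target, InstanceLabelMap) else (
        target.values if isinstance(target, SemanticTriMask) else target.pixels)
    if image.pixels.shape != t_arr.shape:
        raise ImageDataError("image and target must share shape")
    bad = set(ops) - set(_AUG_OPS)
    if bad:
        raise ImageDataError(f"unknown augmentation ops: {sorted(bad)}")

    def wrap(arr: np.ndarray):
        if isinstance(target, InstanceLabelMap):
            return InstanceLabelMap(np.ascontiguousarray(arr))
        if isinstance(target, SemanticTriMask):
            return SemanticTriMask(np.ascontiguousarray(arr))
        return GrayImage(np.ascontiguousarray(arr))

    out = [{"op": "identity", "image": image, "target": target,
            "transposed": False}]
    square = image.pixels.shape[0] == image.pixels.shape[1]
    for op in [o for o in _AUG_OPS if o in set(ops)]:
        img_a = np.ascontiguousarray(_apply(op, image.pixels))
        tgt_a = _apply(op, t_arr)
        out.append({
            "op": op,
            "image": GrayImage(img_a, pixel_size_nm=image.pixel_size_nm),
            "target": wrap(tgt_a),
            "transposed": (not square) and op in ("rot90", "rot270"),
        })
    return out
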