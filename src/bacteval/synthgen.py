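"""Deterministic synthetic bacterial scene, time-lapse and benchmark generator.

Provides ground truth for every post-processing and evaluation operation in
the toolkit: rod-shaped cells (E. coli-like spherocylinders), cocci
(S. aureus-like ellipses) and chains (B. subtilis-like collinear rods),
rendered as membrane stains, bimodal cytosolic fluorescence with septal
enrichment (FtsZ-like), or stylised bright field; corrupted with a mixed
Poisson-Gaussian noise model; grown and divided over time with optional
photobleaching; and stitched into multi-condition detection benchmarks.

Every generator is a pure function of its spec: the seed fully determines
the output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .imagedata import Box, BoxAnnotationSet, GrayImage, InstanceLabelMap, TimeSeries


class SynthError(ValueError):
    """Raised for invalid generator specs or unreachable placement targets."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Parameters of a random bacterial scene.

    ``length_px`` / ``width_px`` are (mean, sd) of the cell long/short axis in
    pixels.  Either ``n_cells`` or ``area_density`` (fraction of the image
    covered, in (0, 0.6]) must be given.  With ``allow_touching=False``,
    placed objects remain pairwise disjoint even after 1-px dilation.
    """

    morphology: str = "rod"  # rod | coccus | chain
    n_cells: Optional[int] = 10
    area_density: Optional[float] = None
    length_px: Tuple[float, float] = (24.0, 4.0)
    width_px: Tuple[float, float] = (7.0, 0.5)
    allow_touching: bool = False
    image_height: int = 256
    image_width: int = 256
    seed: int = 0
    best_effort: bool = False

    def __post_init__(self) -> None:
        if self.morphology not in ("rod", "coccus", "chain"):
            raise SynthError(f"unknown morphology {self.morphology!r}")
        if self.n_cells is None and self.area_density is None:
            raise SynthError("one of n_cells / area_density is required")
        if self.area_density is not None and not 0 < self.area_density <= 0.6:
            raise SynthError("area_density must be in (0, 0.6]")
        if self.n_cells is not None and self.n_cells < 1:
            raise SynthError("n_cells must be positive")
        if self.image_height < 8 or self.image_width < 8:
            raise SynthError("image must be at least 8x8")
        if self.seed < 0:
            raise SynthError("seed must be non-negative")


@dataclass
class RenderSpec:
    """Intensity model used to turn a label map into a clean image.

    ``membrane``          bright 1-px inner rim over a dimmer interior.
    ``cytosolic_bimodal`` dim cytosol plus a bright 2-px mid-cell septal band
                          (FtsZ-like) in ``septum_fraction`` of the cells.
    ``brightfield``       interiors darker than background with a 1-px bright
                          halo outside each object (stylised defocus ring,
                          not an optical simulation).
    """

    modality: str = "membrane"
    background_level: float = 0.05
    cell_level: float = 0.5
    boundary_or_septum_level: float = 1.0
    psf_sigma_px: float = 0.0
    septum_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.modality not in ("membrane", "cytosolic_bimodal", "brightfield"):
            raise SynthError(f"unknown modality {self.modality!r}")
        if min(self.background_level, self.cell_level,
               self.boundary_or_septum_level) < 0:
            raise SynthError("intensity levels must be non-negative")
        if self.psf_sigma_px < 0:
            raise SynthError("psf_sigma_px must be non-negative")
        if self.modality == "membrane" and not (
                self.boundary_or_septum_level > self.cell_level):
            raise SynthError("membrane render requires boundary level > cell level")
        if self.modality == "cytosolic_bimodal" and not (
                self.boundary_or_septum_level > self.cell_level
                > self.background_level):
            raise SynthError(
                "cytosolic_bimodal requires septum > cytosol > background levels")
        if self.modality == "brightfield" and not (
                self.cell_level < self.background_level):
            raise SynthError("brightfield requires cell level < background level")
        if not 0.0 <= self.septum_fraction <= 1.0:
            raise SynthError("septum_fraction must be in [0, 1]")


@dataclass
class NoiseSpec:
    """Mixed Poisson-Gaussian noise model (shot noise then read noise).

    ``photons_per_unit`` scales clean intensity to expected photon counts for
    the Poisson stage; ``None`` disables the shot-noise stage entirely (pure
    additive read noise on the clean signal).  ``read_noise_sd`` is the sd of
    the additive Gaussian stage applied after the Poisson draw; ``offset``
    models the camera baseline.  The output is clipped at zero.
    """

    photons_per_unit: Optional[float] = 100.0
    read_noise_sd: float = 1.0
    offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photons_per_unit is not None and self.photons_per_unit < 0:
            raise SynthError("photons_per_unit must be non-negative or None")
        if self.read_noise_sd < 0 or self.offset < 0:
            raise SynthError("read_noise_sd and offset must be non-negative")
        if self.seed < 0:
            raise SynthError("seed must be non-negative")


@dataclass
class GrowthSpec:
    """Growth/division/photobleaching model for simulated time-lapses.

    ``exponential_elongation`` grows the long axis by ``elongation_rate`` per
    frame at fixed width (exponential growth).  ``stationary_release`` also
    expands the short axis at half that rate, emulating cells resuming growth
    from stationary phase by expanding in all directions, so circularity
    decreases only slightly while area grows.  Bleaching scales clean frame t
    by ``2**(-t / bleach_t_half_frames)`` so the parameter is the literal
    half time.
    """

    mode: str = "exponential_elongation"
    elongation_rate: float = 0.05
    division_length_px: float = 36.0
    bleach_t_half_frames: Optional[float] = None
    n_frames: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("exponential_elongation", "stationary_release"):
            raise SynthError(f"unknown growth mode {self.mode!r}")
        if self.elongation_rate < 0:
            raise SynthError("elongation_rate must be non-negative")
        if self.n_frames < 2:
            raise SynthError("n_frames must be at least 2")
        if self.bleach_t_half_frames is not None and self.bleach_t_half_frames <= 0:
            raise SynthError("bleach_t_half_frames must be positive")


# ---------------------------------------------------------------------------
# Cell geometry and rasterisation
# ---------------------------------------------------------------------------


@dataclass
class _Cell:
    """Geometric state of one cell: a (possibly flat-ended) spherocylinder.

    ``length`` is the end-to-end long axis, ``width`` the short axis.
    ``cap_minus`` / ``cap_plus`` say whether the end at negative/positive
    axial coordinate carries a hemispherical cap; a flat end arises at the
    division plane when a mother cell splits.
    """

    cy: float
    cx: float
    theta: float  # orientation of the long axis, radians
    length: float
    width: float
    shape: str = "rod"  # rod | ellipse
    cap_minus: bool = True
    cap_plus: bool = True

    @property
    def direction(self) -> Tuple[float, float]:
        return (math.sin(self.theta), math.cos(self.theta))  # (dy, dx)

    def footprint_slices(self, h: int, w: int, pad: int = 2):
        r = self.length / 2 + self.width / 2 + pad
        y0 = max(int(math.floor(self.cy - r)), 0)
        y1 = min(int(math.ceil(self.cy + r)) + 1, h)
        x0 = max(int(math.floor(self.cx - r)), 0)
        x1 = min(int(math.ceil(self.cx + r)) + 1, w)
        return slice(y0, y1), slice(x0, x1)

    def rasterise(self, h: int, w: int) -> Tuple[slice, slice, np.ndarray]:
        """Return (row slice, col slice, boolean mask) on the image grid."""
        sy, sx = self.footprint_slices(h, w)
        yy, xx = np.mgrid[sy, sx]
        dy, dx = self.direction
        py = yy - self.cy
        px = xx - self.cx
        s = py * dy + px * dx          # axial coordinate
        r = -py * dx + px * dy         # radial coordinate
        half_l = self.length / 2
        half_w = self.width / 2
        if self.shape == "ellipse":
            mask = (s / half_l) ** 2 + (r / max(half_w, 1e-9)) ** 2 <= 1.0
            return sy, sx, mask
        body = half_l - half_w  # axial half-extent of the rectangular body
        if body < 0:
            body = 0.0
        s_body = np.clip(s, -body, body)
        dist_capped = np.hypot(s - s_body, r)
        mask = np.zeros(s.shape, dtype=bool)
        # rectangular body
        mask |= (np.abs(s) <= body) & (np.abs(r) <= half_w)
        # plus end
        if self.cap_plus:
            mask |= (s > body) & (dist_capped <= half_w)
        else:
            mask |= (s > body) & (s <= half_l) & (np.abs(r) <= half_w)
        # minus end
        if self.cap_minus:
            mask |= (s < -body) & (dist_capped <= half_w)
        else:
            mask |= (s < -body) & (s >= -half_l) & (np.abs(r) <= half_w)
        return sy, sx, mask

    def analytic_area(self) -> float:
        half_w = self.width / 2
        if self.shape == "ellipse":
            return math.pi * (self.length / 2) * half_w
        body = max(self.length - self.width, 0.0)
        area = body * self.width
        for cap in (self.cap_minus, self.cap_plus):
            area += math.pi * half_w ** 2 / 2 if cap else half_w * self.width
        return area


def _paint(cells: Sequence[_Cell], h: int, w: int) -> np.ndarray:
    """Paint cells into a label map; overlap pixels go to the later label."""
    labels = np.zeros((h, w), dtype=np.int64)
    for i, cell in enumerate(cells, start=1):
        sy, sx, mask = cell.rasterise(h, w)
        labels[sy, sx][mask] = i
    return labels


def _sample_cell(rng: np.random.Generator, spec: SceneSpec) -> _Cell:
    l_mean, l_sd = spec.length_px
    w_mean, w_sd = spec.width_px
    width = max(float(rng.normal(w_mean, w_sd)), 3.0)
    if spec.morphology == "coccus":
        # sampled below 1.2 with margin so the *rasterised* object's
        # moment-measured axial ratio also stays <= 1.2
        ratio = float(rng.uniform(1.0, 1.15))
        length = width * ratio
        shape = "ellipse"
    else:
        length = max(float(rng.normal(l_mean, l_sd)), 1.5 * width)
        shape = "rod"
    cy = float(rng.uniform(0, spec.image_height))
    cx = float(rng.uniform(0, spec.image_width))
    theta = float(rng.uniform(0, math.pi))
    return _Cell(cy, cx, theta, length, width, shape=shape)


def _chain_from(first: _Cell, k: int) -> List[_Cell]:
    """k collinear flat-junction rods forming a B. subtilis-like chain."""
    cells = []
    dy, dx = first.direction
    for j in range(k):
        offset = (j - (k - 1) / 2) * first.length
        cells.append(replace(
            first,
            cy=first.cy + dy * offset,
            cx=first.cx + dx * offset,
            cap_minus=(j == 0),
            cap_plus=(j == k - 1),
        ))
    return cells


def _mean_cell_area(spec: SceneSpec) -> float:
    l_mean, _ = spec.length_px
    w_mean, _ = spec.width_px
    if spec.morphology == "coccus":
        a = w_mean * 1.1 / 2
        return math.pi * a * (w_mean / 2)
    return (l_mean - w_mean) * w_mean + math.pi * (w_mean / 2) ** 2


_DILATE = np.ones((3, 3), dtype=bool)


def _moment_axis_ratio(mask: np.ndarray) -> float:
    """Major/minor axis ratio of a pixel blob from its second moments."""
    ys, xs = np.nonzero(mask)
    y = ys - ys.mean()
    x = xs - xs.mean()
    cov = np.array([[np.mean(y * y) + 1 / 12, np.mean(y * x)],
                    [np.mean(y * x), np.mean(x * x) + 1 / 12]])
    evals = np.linalg.eigvalsh(cov)
    return float(math.sqrt(max(evals[1], 1e-12) / max(evals[0], 1e-12)))


def place_cells(spec: SceneSpec) -> List[_Cell]:
    """Rejection-sample cell placements satisfying the touching constraint."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    if spec.n_cells is not None:
        target = spec.n_cells
    else:
        target = max(int(spec.area_density * h * w / _mean_cell_area(spec)), 1)

    occupied = np.zeros((h, w), dtype=bool)
    blocked = np.zeros((h, w), dtype=bool)  # occupied after 1-px dilation
    placed: List[_Cell] = []
    budget = 100 * target
    attempts = 0
    while len(placed) < target and attempts < budget:
        attempts += 1
        cand = _sample_cell(rng, spec)
        if spec.morphology == "chain":
            k = min(int(rng.integers(2, 7)), target - len(placed))
            group = _chain_from(cand, max(k, 1))
        else:
            group = [cand]
        group_mask = np.zeros((h, w), dtype=bool)
        ok = True
        for cell in group:
            sy, sx, mask = cell.rasterise(h, w)
            if mask.sum() == 0:
                ok = False
                break
            group_mask[sy, sx] |= mask
        if not ok:
            continue
        # reject cells clipped by the image border: footprint must not touch it
        border = np.zeros((h, w), dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        if (group_mask & border).any():
            continue
        # the coccus contract is on the rasterised object: its
        # moment-measured axial ratio must stay <= 1.2 despite pixelation
        if spec.morphology == "coccus" and _moment_axis_ratio(group_mask) > 1.2:
            continue
        test = blocked if not spec.allow_touching else occupied
        if (group_mask & test).any():
            continue
        placed.extend(group)
        occupied |= group_mask
        if not spec.allow_touching:
            blocked |= ndimage.binary_dilation(group_mask, structure=_DILATE)
        else:
            blocked |= group_mask
    if len(placed) < target and not spec.best_effort:
        raise SynthError(
            f"placed only {len(placed)}/{target} cells within "
            f"{budget} attempts; set best_effort=True to accept"
        )
    return placed


def generate_scene(spec: SceneSpec) -> Tuple[GrayImage, InstanceLabelMap]:
    """Generate a random scene: unit-foreground clean image + label map."""
    cells = place_cells(spec)
    labels = _paint(cells, spec.image_height, spec.image_width)
    clean = (labels > 0).astype(np.float64)
    return GrayImage(clean), InstanceLabelMap(labels)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _inner_rims(labels: np.ndarray) -> np.ndarray:
    """1-px inner rim of each object (8-connectivity neighbour test)."""
    rims = np.zeros(labels.shape, dtype=bool)
    for sl, lab in _iter_objects(labels):
        mask = labels[sl] == lab
        eroded = ndimage.binary_erosion(mask, structure=_DILATE, border_value=0)
        rims[sl] |= mask & ~eroded
    return rims


def _iter_objects(labels: np.ndarray):
    objs = ndimage.find_objects(labels)
    for idx, sl in enumerate(objs, start=1):
        if sl is None:
            continue
        # pad one pixel so erosion sees the true object border
        y0 = max(sl[0].start - 1, 0)
        y1 = min(sl[0].stop + 1, labels.shape[0])
        x0 = max(sl[1].start - 1, 0)
        x1 = min(sl[1].stop + 1, labels.shape[1])
        yield (slice(y0, y1), slice(x0, x1)), idx


def _septum_band(labels: np.ndarray, lab: int, sl) -> np.ndarray:
    """2-px band through the object's centroid, orthogonal to its long axis."""
    mask = labels[sl] == lab
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    y = ys - cy
    x = xs - cx
    # principal axis from second moments
    cov = np.array([[np.mean(y * y), np.mean(y * x)],
                    [np.mean(y * x), np.mean(x * x)]])
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    proj = y * major[0] + x * major[1]
    band = np.zeros_like(mask)
    band[ys[np.abs(proj) < 1.0], xs[np.abs(proj) < 1.0]] = True
    return band


def render_modality(labels: InstanceLabelMap, rspec: RenderSpec) -> GrayImage:
    """Render a label map as a clean image under the requested modality."""
    arr = labels.labels
    out = np.full(arr.shape, rspec.background_level, dtype=np.float64)
    fg = arr > 0
    if rspec.modality == "membrane":
        out[fg] = rspec.cell_level
        out[_inner_rims(arr)] = rspec.boundary_or_septum_level
    elif rspec.modality == "cytosolic_bimodal":
        out[fg] = rspec.cell_level
        ids = np.unique(arr)
        ids = ids[ids > 0]
        n_septa = int(math.ceil(rspec.septum_fraction * ids.size))
        chosen = set(ids[:n_septa].tolist())  # deterministic: lowest labels
        for sl, lab in _iter_objects(arr):
            if lab in chosen:
                band = _septum_band(arr, lab, sl)
                region = out[sl]
                region[band] = rspec.boundary_or_septum_level
    else:  # brightfield
        out[fg] = rspec.cell_level
        halo = ndimage.binary_dilation(fg, structure=_DILATE) & ~fg
        out[halo] = 1.3 * rspec.background_level
    if rspec.psf_sigma_px > 0:
        out = ndimage.gaussian_filter(out, rspec.psf_sigma_px)
    return GrayImage(out)


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------


def corrupt(clean: GrayImage, nspec: NoiseSpec) -> GrayImage:
    """Apply the Poisson-Gaussian noise model to a clean image.

    ``out = Poisson(photons_per_unit * clean) + N(0, read_noise_sd) + offset``
    clipped at zero.  With ``photons_per_unit=None`` the Poisson stage is
    skipped and read noise is added to the clean signal directly.
    """
    arr = clean.pixels.astype(np.float64)
    if arr.min() < 0:
        raise SynthError("corrupt() requires a non-negative clean image")
    rng = np.random.default_rng(nspec.seed)
    if nspec.photons_per_unit is None:
        signal = arr.copy()
    else:
        signal = rng.poisson(nspec.photons_per_unit * arr).astype(np.float64)
    if nspec.read_noise_sd > 0:
        signal = signal + rng.normal(0.0, nspec.read_noise_sd, size=arr.shape)
    out = np.clip(signal + nspec.offset, 0.0, None)
    return GrayImage(out)


def make_snr_pair(labels: InstanceLabelMap, rspec: RenderSpec,
                  low: NoiseSpec, high: NoiseSpec
                  ) -> Tuple[GrayImage, GrayImage]:
    """Render one clean frame and corrupt it at two noise levels.

    Both outputs are normalised back to the clean intensity scale (offset
    subtracted, divided by the photon budget) so PSNR against the clean frame
    is directly comparable; by construction ``psnr(low) < psnr(high)``.
    """
    if low.photons_per_unit is None and high.photons_per_unit is None:
        if not low.read_noise_sd > high.read_noise_sd:
            raise SynthError(
                "read-noise-only pair requires low.read_noise_sd > high.read_noise_sd")
    elif low.photons_per_unit is None or high.photons_per_unit is None:
        raise SynthError("mixed shot-noise/no-shot-noise pairs are not comparable")
    elif not low.photons_per_unit < high.photons_per_unit:
        raise SynthError("requires low.photons_per_unit < high.photons_per_unit")
    clean = render_modality(labels, rspec)
    out = []
    for nspec in (low, high):
        noisy = corrupt(clean, nspec).pixels - nspec.offset
        if nspec.photons_per_unit is not None:
            noisy = noisy / nspec.photons_per_unit
        out.append(GrayImage(np.clip(noisy, 0.0, None)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Time-lapse simulation
# ---------------------------------------------------------------------------


def _grow(cell: _Cell, rate: float, mode: str) -> _Cell:
    dl = cell.length * rate
    dy, dx = cell.direction
    cy, cx = cell.cy, cell.cx
    # a flat end marks the former division plane: growth extends away from it
    if cell.cap_minus and not cell.cap_plus:
        cy -= dy * dl / 2
        cx -= dx * dl / 2
    elif cell.cap_plus and not cell.cap_minus:
        cy += dy * dl / 2
        cx += dx * dl / 2
    width = cell.width * (1 + rate / 2) if mode == "stationary_release" else cell.width
    return replace(cell, cy=cy, cx=cx, length=cell.length + dl, width=width)


def _divide(cell: _Cell) -> Tuple[_Cell, _Cell]:
    """Split at the mid-plane into two touching flat-junction daughters."""
    dy, dx = cell.direction
    off = cell.length / 4
    a = replace(cell, cy=cell.cy - dy * off, cx=cell.cx - dx * off,
                length=cell.length / 2, cap_plus=False)
    b = replace(cell, cy=cell.cy + dy * off, cx=cell.cx + dx * off,
                length=cell.length / 2, cap_minus=False)
    return a, b


def simulate_timelapse(spec: SceneSpec, gspec: GrowthSpec, rspec: RenderSpec,
                       nspec: NoiseSpec
                       ) -> Tuple[TimeSeries, List[InstanceLabelMap], List[float]]:
    """Simulate a growing, dividing, optionally bleaching time-lapse.

    Returns the noisy series, per-frame ground-truth label maps, and the
    bleaching scale factor applied to each clean frame (all ones when
    ``bleach_t_half_frames`` is unset).
    """
    cells = place_cells(spec)
    if gspec.elongation_rate == 0 and all(
            c.length < gspec.division_length_px for c in cells):
        warnings.warn("zero elongation and no cell at division length: "
                      "the series will be static", stacklevel=2)
    h, w = spec.image_height, spec.image_width
    frames: List[GrayImage] = []
    gt_labels: List[InstanceLabelMap] = []
    trace: List[float] = []
    for t in range(gspec.n_frames):
        labels = InstanceLabelMap(_paint(cells, h, w))
        clean = render_modality(labels, rspec).pixels
        scale = 1.0
        if gspec.bleach_t_half_frames is not None:
            scale = 2.0 ** (-t / gspec.bleach_t_half_frames)
        frame_seed = int((nspec.seed * 1_000_003 + t) % (2 ** 31))
        noisy = corrupt(GrayImage(clean * scale), replace(nspec, seed=frame_seed))
        frames.append(noisy)
        gt_labels.append(labels)
        trace.append(scale)
        # advance state for the next frame
        grown = [_grow(c, gspec.elongation_rate, gspec.mode) for c in cells]
        nxt: List[_Cell] = []
        for c in grown:
            if c.shape == "rod" and c.length >= gspec.division_length_px:
                nxt.extend(_divide(c))
            else:
                nxt.append(c)
        cells = nxt
    series = TimeSeries(frames, frame_interval_s=1.0)
    return series, gt_labels, trace


# ---------------------------------------------------------------------------
# Stitched detection benchmark
# ---------------------------------------------------------------------------


def stitch_test_image(
    patch_pools: Dict[str, List[Tuple[GrayImage, BoxAnnotationSet]]],
    grid_rows: int,
    grid_cols: int,
    patch_px: int,
    seed: int = 0,
) -> Tuple[GrayImage, BoxAnnotationSet, List[List[str]]]:
    """Randomly stitch per-condition patches into one benchmark image.

    Tile classes are drawn uniformly with replacement; per-patch boxes are
    translated by the tile offset.  Mirrors a detection test set built from
    200x200 px^2 patches stitched into 800x800 px^2 images.
    """
    if not patch_pools:
        raise SynthError("patch_pools must be non-empty")
    for cls, pool in patch_pools.items():
        if not pool:
            raise SynthError(f"empty patch pool for class {cls!r}")
        for img, ann in pool:
            if img.pixels.shape != (patch_px, patch_px):
                raise SynthError(
                    f"class {cls!r}: patch shape {img.pixels.shape} != "
                    f"({patch_px}, {patch_px})")
    rng = np.random.default_rng(seed)
    classes = sorted(patch_pools)
    out_h, out_w = grid_rows * patch_px, grid_cols * patch_px
    canvas = np.zeros((out_h, out_w), dtype=np.float64)
    boxes: List[Box] = []
    tile_map: List[List[str]] = []
    for r in range(grid_rows):
        row_classes: List[str] = []
        for c in range(grid_cols):
            cls = classes[int(rng.integers(len(classes)))]
            pool = patch_pools[cls]
            img, ann = pool[int(rng.integers(len(pool)))]
            dy, dx = r * patch_px, c * patch_px
            canvas[dy:dy + patch_px, dx:dx + patch_px] = img.pixels
            boxes.extend(b.translated(dx, dy) for b in ann.boxes)
            row_classes.append(cls)
        tile_map.append(row_classes)
    return GrayImage(canvas), BoxAnnotationSet(out_h, out_w, boxes), tile_map
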