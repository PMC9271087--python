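# Methods

This note documents the models, estimators and numerical conventions behind
`bacteval`, the choices made where several defensible options existed, and
what the synthetic generator does and does not emulate.

## Coordinate and data conventions

Arrays are row-major, 0-based, `(row, col) = (y, x)`. Bounding boxes are
0-based and half-open internally (`xmin <= x < xmax`); PASCAL VOC XML files
use the standard 1-based inclusive dialect, converted only at the I/O
boundary (`xmin_int = xmin_voc − 1`, `xmax_int = xmax_voc`), so a box's
pixel width is `xmax_voc − xmin_voc + 1` in both conventions. A consequence
of rejecting `xmax_voc <= xmin_voc` as degenerate is that 1-px-wide boxes
cannot be expressed in files; they remain legal in memory. A prediction
score, when present, is stored in a non-standard `<score>` child element so
that detection predictions round-trip through VOC files.

Instance label maps are written as 16-bit TIFF, switching to 32-bit only
when a label exceeds 65535 — the common ImageJ-compatible "ROI map" usage.
`relabel_sequential` renumbers objects to `1..N` in order of first raster
occurrence and returns the old→new bijection.

## Synthetic scenes

Cells are parametrised as spherocylinders (rods: rectangle of end-to-end
length L and width w, capped by half-discs; rasterised by
distance-to-axis-segment ≤ w/2), ellipses (cocci, axial ratio sampled in
[1.0, 1.15]), or chains of 2–6 collinear rods joined at flat 1-px contact
planes. Placement is rejection sampling: position and orientation uniform,
cells fully inside the frame, with a budget of 100 × n attempts; when
`allow_touching=False`, a candidate is rejected if it intersects the 1-px
dilation of anything already placed, which guarantees pairwise disjointness
even after dilating either object by one pixel. Density-specified scenes
convert the requested covered-area fraction into a cell count via the
analytic mean cell area.

Two contracts are enforced on the *rasterised* objects, not just the
sampled parameters: coccus candidates whose second-moment axial ratio
exceeds 1.2 are rejected (pixelation can elongate small ellipses), and
rasterised areas match the analytic spherocylinder/ellipse area within 5 %
for widths ≥ 6 px (verified by test).

Default geometry (length 24 ± 4 px, width 7 ± 0.5 px on a 256² frame)
corresponds to exponentially growing *E. coli*-like rods at roughly 100 nm
pixel size; cocci default to ~7 px diameter, *S. aureus*-like at that
sampling.

## Rendering

Three stylised intensity models turn a label map into a clean image:

- **membrane** — each object's 1-px inner rim (pixels with an 8-neighbour
  outside the object) at the boundary level, interior at the cell level;
  emulates a fluorescent membrane stain.
- **cytosolic_bimodal** — interior at the cytosol level plus a 2-px
  mid-cell band, orthogonal to the object's principal axis (from second
  moments), at the septum level; emulates division-site-enriched FtsZ-like
  labelling over a dim cytosolic background. Which cells carry a septum when
  `septum_fraction < 1` is chosen deterministically (lowest labels first) so
  rendering stays a pure function of `(labels, RenderSpec)` with no extra
  seed.
- **brightfield** — interiors darker than the background with a 1-px outer
  halo at 1.3 × background; a minimal stand-in for defocus contrast, *not*
  an optical simulation.

Level orderings are validated per modality. An optional Gaussian blur
(`psf_sigma_px`) is applied last.

## Noise model

`corrupt` implements the mixed Poisson–Gaussian camera model:

    out = Poisson(photons_per_unit · clean) + N(0, read_noise_sd) + offset,

clipped at zero, Poisson stage strictly before the Gaussian stage. This is
the shot-noise-dominated regime of low-SNR fluorescence imaging;
`photons_per_unit` is the exposure/illumination dial that separates low-
from high-SNR acquisitions. `photons_per_unit=None` disables the shot-noise
stage (pure additive read noise on the clean signal) — used for closed-form
Gaussian checks and read-noise-only pairs. `make_snr_pair` renders one
clean frame, corrupts it twice with independent draws, and returns both
images normalised back to the clean intensity scale so PSNR against the
clean frame is directly comparable; the low/high ordering is required
(photon budgets, or read-noise sds for Gaussian-only pairs) rather than
checked post hoc.

Clipping at zero truncates the Gaussian tail; with a background level or
offset of at least ~3 sd the effect on means/variances is negligible, which
is how the calibration tests are set up.

## Time-lapse growth and division

Each cell's geometric state (centre, orientation, length, width, cap
flags) evolves per frame: length grows by `elongation_rate` (exponential
elongation); in `stationary_release` mode the width additionally grows at
half that rate, emulating cells resuming growth from stationary phase by
expanding in all directions — area rises while circularity falls only
slightly. A rod reaching `division_length_px` splits at its mid-plane into
two touching daughters.

Division geometry: daughters are *flat-ended* at the former division plane
(the parent's pixel set is partitioned, not re-capped), and subsequent
growth extends a flat-ended cell away from the junction. This makes the
per-cell pixel sets monotone under growth and keeps the total foreground
area exactly non-decreasing — a naive "two capped half-length rods" split
would lose the junction corners. Overlaps between independently growing
neighbours are resolved by painting order (later labels win); the
foreground union is unaffected.

Bleaching scales clean frame *t* by `2^(−t / t_half_frames)` — base-2 so
the parameter is the literal half time — and the applied factors are
returned as the ground-truth intensity trace. Per-frame noise seeds are
derived deterministically from the noise seed and the frame index.

## Tri-mask and semantic-to-instance post-processing

The three-class training target sets each object's 1-px inner boundary
(equivalently, object minus its 8-connected 1-px erosion) to 2 and the rest
of the object to 1. Because the rim is computed per object, pixels where
two objects touch are boundary on *both* sides, so no cytosol component
ever spans two objects — this is the property that keeps touching cells
separable, reproducing hand-annotated 1-px boundaries in a deterministic
way.

The inverse operation subtracts the boundary channel from the cytosol
channel (hard labels: cytosol pixels; probabilities: `p_cyto − p_bound ≥
τ_seed`), keeps connected seed components of at least `min_size_px` as
markers, and floods a marker-based watershed over the foreground support
(`cytosol ∪ boundary`, or `p_cyto + p_bound ≥ τ_fg`) on the inverted
cytosol support (probabilities: `−p_cyto`). Components use 8-connectivity,
flooding uses 4-connectivity — the behaviour of the standard morphological
toolboxes this mirrors. Boundary pixels are assigned to instances rather
than left as background so that downstream morphometry sees whole cells.
Defaults `τ_seed = τ_fg = 0.5`, `min_size_px = 10` are conventions (no
canonical values exist) and are exposed both in the API and the CLI.

Single-channel `probmap_to_instances` (threshold + connected components +
small-object removal) is provided deliberately including its known failure
mode: touching cells merge at high density. Its output support is monotone
in the threshold.

## Segmentation metrics

Semantic IoU binarises label maps (any positive label = foreground) and is
defined as 1.0 when both masks are empty. Instance matching computes IoU
for all overlapping (gt, pred) pairs from a joint label histogram, then
matches greedily in descending IoU with ties broken by (gt_id, pred_id).
At thresholds ≥ 0.5 two distinct objects cannot both overlap a third above
threshold, so the greedy matching is the unique maximum matching; for
thresholds below 0.5 greedy is an approximation and the exhaustive oracle
tests are restricted to ≥ 0.5. The default threshold 0.5 is the community
convention for "correctly detected".

Precision = TP/(TP+FP) over predictions, recall = TP/(TP+FN) over ground
truth (recall is the counting accuracy). Degenerate cases are explicit:
both sets empty → (1, 1); predictions absent with GT present → recall 0 and
precision NaN with `precision_defined=False`; GT absent with predictions
present → precision as computed, recall vacuously 1. Dataset reports give
unweighted per-image means and the sample standard deviation (ddof 1), with
an `n=1` marker for single images.

Morphometry uses pixel-count area and the Crofton 4-direction perimeter
estimator (comparable to common Fiji-adjacent measurements); circularity
4πA/P² is clamped to ≤ 1 with the raw value retained, since the Crofton
estimator can yield nominally super-circular values on small discretised
discs. Physical units follow the pixel size in nm when supplied.

## Detection metrics

The VOC protocol: predictions sorted by descending confidence; each matched
greedily to the *unmatched* ground-truth box of highest IoU ≥ threshold in
the same image; duplicates of an already-matched GT count as false
positives; precision/recall accumulated after every prediction. AP
defaults to the all-point interpolation (area under the precision
envelope); the classic 11-point variant is available because the two can
differ by several points and either convention may be needed for
comparisons. "Different detection thresholds" is read as a sweep over
confidence scores at fixed IoU 0.5, not an IoU sweep. mAP is the
unweighted mean over classes that have at least one GT box; classes without
GT are excluded with a warning. Matching is per image, so pooled evaluation
equals per-image evaluation; difficult/ignore flags are not supported.

## Restoration metrics

PSNR is `10·log10(data_range² / MSE)`; identical images return the explicit
`+inf` sentinel, never a cap. SSIM uses a Gaussian window (σ = 1.5, 11×11
support, normalised to unit sum), stabilisers K1 = 0.01, K2 = 0.03, and
reflect boundary handling; local statistics are window-weighted moments
(population covariances). `data_range=None` resolves to
`max(gt) − min(gt)` per pair (falling back to 1.0 for constant references),
which keeps 8-bit and 16-bit data comparable.

The multiscale variant combines the finest-scale per-pixel SSIM map with
contrast–structure terms computed after repeated 2× average-pooling, each
upsampled back to full resolution (nearest-neighbour) and raised to the
standard weights (0.0448, 0.2856, 0.3001, 0.2363, 0.1333, renormalised over
the scales actually used). Scales are auto-reduced when the image is
smaller than `window · 2^(n_scales−1)` — bacterial crops are small —
and `n_scales=1` is exactly single-scale SSIM (verified against an
independent direct-formula implementation to 1e-6 and against scikit-image
away from borders). Negative contrast–structure terms are clipped at zero
before exponentiation so the weighted product stays real; single-scale maps
are returned unclipped on [−1, 1].

Masked SSIM averages the full-resolution map over a binary cell mask. The
rationale: most restoration networks reproduce the (large, dark) background
almost perfectly, so the plain image mean is over-optimistic; restricting
to cell outlines measures what matters. Masks come from Otsu thresholding
(default; the thresholding method is a convention) of a high-SNR reference
image or of the temporal mean of a series, with an explicit error on
constant images or empty foregrounds.

Subsequent-frame SSIM compares each frame to the next (T−1 values for T
frames): with no ground truth available, frame-to-frame structural
variation is a noise proxy — noisier series score lower, a static noiseless
series scores exactly 1. The statistic is symmetric under time reversal.

## Photobleaching fits

Intensity traces are fit to `I(t) = A·2^(−t/t_half) + c` by nonlinear least
squares (bounded: A, k = 1/t_half, c ≥ 0), initialised from a log₂-linear
fit on offset-subtracted data with the initial offset at the trace minimum.
Base-2 makes `t_half` the literal half time; it is reported in trace-time
units × `frame_interval`. Non-decaying or constant traces return
`converged=False` with the explicit `t_half = +inf` sentinel rather than an
error. Parameter recovery: within 0.5 % on noiseless decays across
t_half ∈ {5, 20, 50, 200} frames and within 10 % under Poisson noise at
100 expected photons/pixel; a 20-fold half-time ratio between two noisy
series is recovered within 15 % (all exercised by the test suite and the
acceptance script).

## Stitched detection benchmarks

`stitch_test_image` assembles a grid of fixed-size per-condition patches
(default geometry: 4×4 tiles of 200×200 px → 800×800 px images, the common
construction for multi-condition antibiotic-phenotyping test sets), drawing
each tile's class uniformly with replacement under the seed, and translates
each patch's box annotations by its tile offset. Patches are whole tiles,
so no box clipping can occur, and the union of translated per-tile
annotations equals the output annotation set exactly.

## Determinism

Every generator is a pure function of its specs: the seed fully determines
the output (bit-identical across runs on one platform). Time-lapse
per-frame noise seeds are derived from `(noise seed, frame index)`; the CLI
threads one global `--seed` through all specs and logs the fully resolved
configuration as a JSON sidecar, which suffices to reproduce any run.

## What the generator does and does not emulate

It emulates: rod/coccus/chain geometry at realistic pixel scales, membrane
and septal-enrichment staining patterns, stylised bright-field contrast,
shot-noise-limited low-SNR acquisition with read noise and camera offset,
exponential growth with mid-cell division, photobleaching, and
multi-condition stitched test images.

It does not emulate: real optics (the PSF is at most a Gaussian blur; no
defocus, aberrations or structured illumination), cell–cell mechanics or
biofilm geometry, curved or filamentous morphologies, intracellular texture
beyond the septal band, uneven illumination, or stage drift. Passing tests
therefore demonstrate the correctness of the *metrics and post-processing*
and internal consistency of the simulation — not that any particular
network performs well on real data.

## Problem sizes

The test suite and acceptance script run at desk scale by design: scenes of
3–40 cells on 64–320 px frames, 100 random scenes for the metric-oracle
comparisons, 50 scenes for the round-trip checks, 200–400-frame bleaching
traces on 64² frames, and four 800×800 stitched benchmark images. These
sizes make the brute-force oracles (exhaustive assignment, per-threshold
confusion counting, per-pixel SSIM) exact and fast while exercising every
code path at realistic cell geometry.

## Known limitations

- Greedy instance matching is only provably optimal at IoU ≥ 0.5.
- The multiscale SSIM map construction (finest-scale map × upsampled
  coarse cs terms) is one of several "multiscale" readings; `n_scales=1`
  is the unambiguous single-scale definition, and both are exposed.
- The bright-field rendering is a stylised two-level model with a halo,
  suitable for testing pipelines but not for training transferable models.
- Watershed post-processing assumes the boundary class is thin (~1 px);
  thick predicted boundaries shrink seeds and can drop small cells below
  `min_size_px`.
- The placement sampler is rejection-based; densities near the 0.6 packing
  ceiling may fail the attempt budget (explicitly reported, with a
  `best_effort` escape hatch).
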