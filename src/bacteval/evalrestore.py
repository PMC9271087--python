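"""Image-restoration evaluation for denoising and restoration pipelines.

Provides PSNR, a (multi-scale) SSIM that returns a full-resolution
similarity map, cell-outline-masked SSIM (restricting the average to cell
pixels, because the easily-reproduced background otherwise inflates the
per-image value), the ground-truth-free subsequent-frame SSIM statistic for
live-cell time series, per-frame intensity traces, and photobleaching
half-time fitting under a base-2 exponential decay model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

from .imagedata import GrayImage, ImageDataError, TimeSeries

# standard 5-scale weights of the multiscale SSIM formulation
_MS_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass
class SSIMParams:
    """SSIM internals: Gaussian window (sigma 1.5, 11x11 support),
    stabilisers K1=0.01 / K2=0.03, and multiscale configuration.

    ``data_range=None`` means "use max(gt) - min(gt) of each image pair"
    (needed when 8-bit and 16-bit data are mixed).  ``n_scales=1`` is exact
    single-scale SSIM; larger values combine coarser-scale contrast/structure
    terms with the finest-scale map, auto-reduced when the image is smaller
    than ``window * 2**(n_scales - 1)``.
    """

    window: int = 11
    sigma: float = 1.5
    K1: float = 0.01
    K2: float = 0.03
    data_range: Optional[float] = None
    n_scales: int = 5
    scale_weights: Tuple[float, ...] = _MS_WEIGHTS

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ImageDataError("window must be odd and >= 3")
        if self.n_scales < 1:
            raise ImageDataError("n_scales must be >= 1")
        if self.data_range is not None and self.data_range <= 0:
            raise ImageDataError("data_range must be positive")
        if len(self.scale_weights) < self.n_scales:
            raise ImageDataError("need a weight per scale")


def psnr(pred: GrayImage, gt: GrayImage, data_range: float) -> float:
    """Peak signal-to-noise ratio, 10*log10(range^2 / MSE), in dB.

    Identical images return +inf (reported as such, never capped).
    """
    if pred.pixels.shape != gt.pixels.shape:
        raise ImageDataError("shape mismatch")
    if data_range <= 0:
        raise ImageDataError("data_range must be positive")
    mse = float(np.mean((pred.pixels.astype(np.float64)
                         - gt.pixels.astype(np.float64)) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / mse))


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------


def _gaussian_window(window: int, sigma: float) -> np.ndarray:
    r = window // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x ** 2) / (2 * sigma ** 2))
    return k / k.sum()


def _filter(arr: np.ndarray, kernel1d: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(arr, kernel1d, axis=0, mode="reflect")
    return ndimage.correlate1d(out, kernel1d, axis=1, mode="reflect")


def _lum_cs(x: np.ndarray, y: np.ndarray, params: SSIMParams,
            data_range: float) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel luminance and contrast-structure terms at one scale."""
    k = _gaussian_window(params.window, params.sigma)
    c1 = (params.K1 * data_range) ** 2
    c2 = (params.K2 * data_range) ** 2
    mu_x = _filter(x, k)
    mu_y = _filter(y, k)
    var_x = _filter(x * x, k) - mu_x ** 2
    var_y = _filter(y * y, k) - mu_y ** 2
    cov = _filter(x * y, k) - mu_x * mu_y
    lum = (2 * mu_x * mu_y + c1) / (mu_x ** 2 + mu_y ** 2 + c1)
    cs = (2 * cov + c2) / (var_x + var_y + c2)
    return lum, cs


def _downsample(arr: np.ndarray) -> np.ndarray:
    """2x average pooling (pad odd edges by reflection)."""
    h, w = arr.shape
    if h % 2:
        arr = np.vstack([arr, arr[-1:]])
    if w % 2:
        arr = np.hstack([arr, arr[:, -1:]])
    return 0.25 * (arr[::2, ::2] + arr[1::2, ::2]
                   + arr[::2, 1::2] + arr[1::2, 1::2])


def _upsample_to(arr: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    out = np.repeat(np.repeat(arr, 2, axis=0), 2, axis=1)
    return out[:shape[0], :shape[1]]


def _resolve_range(pred: np.ndarray, gt: np.ndarray,
                   params: SSIMParams) -> float:
    if params.data_range is not None:
        return params.data_range
    rng = float(gt.max() - gt.min())
    return rng if rng > 0 else 1.0


def ssim_map(pred: GrayImage, gt: GrayImage,
             params: Optional[SSIMParams] = None
             ) -> Tuple[GrayImage, float]:
    """Full-resolution (multi-scale) SSIM map and its mean over all pixels.

    With ``n_scales=1`` this is exactly single-scale SSIM.  At more scales,
    the finest-scale SSIM map is combined with upsampled contrast-structure
    maps of coarser scales, each raised to its (normalised) weight; negative
    terms are clipped at zero before exponentiation so the weighted product
    stays real.
    """
    params = params or SSIMParams()
    x = pred.pixels.astype(np.float64)
    y = gt.pixels.astype(np.float64)
    if x.shape != y.shape:
        raise ImageDataError("shape mismatch")
    if min(x.shape) < params.window:
        raise ImageDataError(
            f"image smaller than one {params.window}-px window")
    data_range = _resolve_range(x, y, params)

    # auto-reduce scale count for small images
    n = params.n_scales
    while n > 1 and min(x.shape) < params.window * 2 ** (n - 1):
        n -= 1
    weights = np.asarray(params.scale_weights[:n], dtype=np.float64)
    weights = weights / weights.sum()

    lum, cs = _lum_cs(x, y, params, data_range)
    if n == 1:
        smap = lum * cs
        return GrayImage(smap), float(smap.mean())

    full_shape = x.shape
    smap = np.clip(lum * cs, 0.0, None) ** weights[0]
    cx, cy = x, y
    for j in range(1, n):
        cx, cy = _downsample(cx), _downsample(cy)
        _, cs_j = _lum_cs(cx, cy, params, data_range)
        up = cs_j
        for _ in range(j):
            up = _upsample_to(up, (up.shape[0] * 2, up.shape[1] * 2))
        up = up[:full_shape[0], :full_shape[1]]
        if up.shape != full_shape:  # odd sizes: pad by edge replication
            up = np.pad(up, ((0, full_shape[0] - up.shape[0]),
                             (0, full_shape[1] - up.shape[1])), mode="edge")
        smap = smap * np.clip(up, 0.0, None) ** weights[j]
    return GrayImage(smap), float(smap.mean())


@dataclass
class MaskResult:
    mask: np.ndarray
    foreground_fraction: float
    threshold: float


def cell_mask_from_reference(ref: Union[GrayImage, TimeSeries],
                             method: str = "otsu",
                             fixed_threshold: Optional[float] = None
                             ) -> MaskResult:
    """Binary cell mask from a high-SNR reference image or series average.

    TimeSeries input is reduced to its per-pixel temporal mean first.  The
    mask is ``pixels >= threshold`` with the threshold from Otsu's method
    (default) or given explicitly.  A constant image (Otsu) or an empty
    foreground raises instead of silently returning all-background.
    """
    if isinstance(ref, TimeSeries):
        img = ref.as_array().astype(np.float64).mean(axis=0)
    else:
        img = ref.pixels.astype(np.float64)
    if method == "otsu":
        if img.max() == img.min():
            raise ImageDataError("constant image: Otsu threshold undefined")
        thr = float(threshold_otsu(img))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ImageDataError("method 'fixed' requires fixed_threshold")
        thr = float(fixed_threshold)
    else:
        raise ImageDataError(f"unknown method {method!r}")
    mask = img >= thr
    frac = float(mask.mean())
    if not mask.any():
        raise ImageDataError("thresholding produced an empty cell mask")
    return MaskResult(mask, frac, thr)


def masked_ssim(pred: GrayImage, gt: GrayImage, mask: np.ndarray,
                params: Optional[SSIMParams] = None) -> float:
    """Mean of the full-resolution SSIM map restricted to mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gt.pixels.shape:
        raise ImageDataError("mask shape mismatch")
    if not mask.any():
        raise ImageDataError("empty mask")
    smap, _ = ssim_map(pred, gt, params)
    return float(smap.pixels[mask].mean())


def subsequent_frame_ssim(series: TimeSeries,
                          params: Optional[SSIMParams] = None,
                          mask: Optional[np.ndarray] = None) -> List[float]:
    """SSIM between each frame and the next: a ground-truth-free noise proxy.

    Low-SNR series show higher frame-to-frame signal variation, hence lower
    values; returns exactly T-1 numbers for a T-frame series.
    """
    values = []
    for k in range(series.n_frames - 1):
        a, b = series.frames[k], series.frames[k + 1]
        if mask is not None:
            values.append(masked_ssim(a, b, mask, params))
        else:
            values.append(ssim_map(a, b, params)[1])
    return values


def intensity_trace(series: TimeSeries,
                    mask: Optional[np.ndarray] = None) -> List[float]:
    """Per-frame mean intensity, optionally restricted to a mask."""
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != series.shape:
            raise ImageDataError("mask shape mismatch")
        if not mask.any():
            raise ImageDataError("empty mask")
        return [float(f.pixels[mask].mean()) for f in series.frames]
    return [float(f.pixels.mean()) for f in series.frames]


# ---------------------------------------------------------------------------
# Photobleaching half-time
# ---------------------------------------------------------------------------


@dataclass
class DecayFit:
    """Fit of I(t) = amplitude * 2**(-t / t_half) + offset.

    ``t_half`` is in trace-time units times the frame interval;
    non-decaying traces carry ``converged=False`` and ``t_half=inf``.
    """

    t_half: float
    amplitude: float
    offset: float
    rss: float
    converged: bool


def fit_bleaching_halftime(trace: Sequence[float],
                           frame_interval: float = 1.0) -> DecayFit:
    """Least-squares fit of a base-2 exponential decay with offset.

    Initialised from a log-linear fit on offset-subtracted data (initial
    offset = min(trace)).  A non-decaying or constant trace returns the
    explicit +inf sentinel rather than an error.
    """
    y = np.asarray(trace, dtype=np.float64)
    if y.size < 5:
        raise ImageDataError("need at least 5 trace points")
    if np.any(y <= 0):
        raise ImageDataError("trace values must be positive")
    t = np.arange(y.size, dtype=np.float64)

    c0 = float(y.min())
    resid = y - c0
    pos = resid > 0
    mean_level = float(y.mean())
    if pos.sum() >= 2:
        slope, logA = np.polyfit(t[pos], np.log2(resid[pos]), 1)
    else:
        slope, logA = 0.0, 0.0
    if slope >= -1e-12:
        rss = float(np.sum((y - mean_level) ** 2))
        return DecayFit(float("inf"), 0.0, mean_level, rss, converged=False)

    k0 = -slope  # per-frame decay rate in half-lives
    a0 = float(2.0 ** logA)

    def model(tt, a, k, c):
        return a * 2.0 ** (-k * tt) + c

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[a0, k0, c0],
            bounds=([0.0, 1e-12, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20_000)
    except RuntimeError:
        return DecayFit(float("inf"), a0, c0, float("nan"), converged=False)
    a, k, c = popt
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    if k <= 1e-9:
        return DecayFit(float("inf"), float(a), float(c), rss, converged=False)
    return DecayFit(float(frame_interval / k), float(a), float(c), rss,
                    converged=True)
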