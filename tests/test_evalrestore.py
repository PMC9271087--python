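import math

import numpy as np
import pytest

from bacteval import (
    GrayImage,
    ImageDataError,
    NoiseSpec,
    RenderSpec,
    SceneSpec,
    SSIMParams,
    TimeSeries,
    cell_mask_from_reference,
    corrupt,
    fit_bleaching_halftime,
    generate_scene,
    intensity_trace,
    masked_ssim,
    normalize_track_features,
    psnr,
    render_modality,
    semantic_iou,
    simulate_timelapse,
    ssim_map,
    subsequent_frame_ssim,
)
from bacteval import GrowthSpec

from _oracles import ssim_direct


class TestPsnr:
    def test_identical_images_inf(self, rng):
        img = GrayImage(rng.random((32, 32)))
        assert psnr(img, img, 1.0) == float("inf")

    def test_constant_offset_closed_form(self, rng):
        gt = GrayImage(rng.random((64, 64)) * 100)
        pred = GrayImage(gt.pixels + 10.0)
        expected = 10 * math.log10(255**2 / 100)
        assert psnr(pred, gt, 255.0) == pytest.approx(expected, abs=1e-9)

    def test_full_range_error_is_zero_db(self):
        pred = GrayImage(np.zeros((16, 16)))
        gt = GrayImage(np.full((16, 16), 255.0))
        assert psnr(pred, gt, 255.0) == pytest.approx(0.0)

    def test_bad_inputs(self, rng):
        img = GrayImage(rng.random((16, 16)))
        with pytest.raises(ImageDataError):
            psnr(img, GrayImage(rng.random((16, 17))), 1.0)
        with pytest.raises(ImageDataError):
            psnr(img, img, 0.0)


class TestSsimMap:
    def test_identical_images_map_of_ones(self, rng):
        img = GrayImage(rng.random((64, 64)))
        smap, mean = ssim_map(img, img, SSIMParams(n_scales=1))
        assert mean == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(smap.pixels, 1.0, atol=1e-12)

    def test_inverted_contrast_degrades(self, rng):
        gt = GrayImage(rng.random((64, 64)))
        pred = GrayImage(1.0 - gt.pixels)
        _, mean = ssim_map(pred, gt, SSIMParams(n_scales=1, data_range=1.0))
        assert mean < 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula_reference(self, seed):
        rng = np.random.default_rng(seed)
        gt = rng.random((128, 128))
        pred = gt + 0.1 * rng.standard_normal((128, 128))
        dr = float(gt.max() - gt.min())
        _, mean = ssim_map(GrayImage(pred), GrayImage(gt),
                           SSIMParams(n_scales=1, data_range=dr))
        assert mean == pytest.approx(ssim_direct(pred, gt, dr), abs=1e-9)

    def test_matches_skimage_interior(self, rng):
        """Cross-check the single-scale map against scikit-image away from
        the borders, where padding conventions cannot differ."""
        from skimage.metrics import structural_similarity

        gt = rng.random((96, 96))
        pred = gt + 0.2 * rng.standard_normal((96, 96))
        _, ref_map = structural_similarity(
            pred, gt, win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0, full=True)
        smap, _ = ssim_map(GrayImage(pred), GrayImage(gt),
                           SSIMParams(n_scales=1, data_range=1.0))
        np.testing.assert_allclose(smap.pixels[8:-8, 8:-8],
                                   ref_map[8:-8, 8:-8], atol=1e-7)

    def test_multiscale_reduces_to_single_scale_at_one(self, rng):
        gt = rng.random((64, 64))
        pred = gt + 0.05 * rng.standard_normal((64, 64))
        m1 = ssim_map(GrayImage(pred), GrayImage(gt),
                      SSIMParams(n_scales=1, data_range=1.0))[1]
        assert m1 == pytest.approx(
            ssim_direct(pred, gt, 1.0), abs=1e-9)

    def test_scale_auto_reduction_on_small_images(self, rng):
        img = GrayImage(rng.random((24, 24)))
        noisy = GrayImage(img.pixels + 0.1 * rng.standard_normal((24, 24)))
        _, mean = ssim_map(noisy, img, SSIMParams(n_scales=5, data_range=1.0))
        assert 0 < mean <= 1.0  # would raise without auto-reduction

    def test_intensity_scale_invariance_with_adjusted_range(self, rng):
        """Rescaling both images (e.g. 8-bit vs 16-bit data) leaves SSIM
        unchanged when data_range is rescaled with them."""
        gt = rng.random((48, 48))
        pred = gt + 0.1 * rng.standard_normal((48, 48))
        base = ssim_map(GrayImage(pred), GrayImage(gt),
                        SSIMParams(n_scales=1, data_range=1.0))[1]
        a = 257.0
        scaled = ssim_map(GrayImage(a * pred), GrayImage(a * gt),
                          SSIMParams(n_scales=1, data_range=a * 1.0))[1]
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_too_small_image_rejected(self, rng):
        img = GrayImage(rng.random((8, 8)))
        with pytest.raises(ImageDataError, match="window"):
            ssim_map(img, img, SSIMParams(n_scales=1))


class TestCellMask:
    def test_bimodal_image_split_exactly(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 200.0
        res = cell_mask_from_reference(GrayImage(img))
        np.testing.assert_array_equal(res.mask, img >= 100)
        assert res.foreground_fraction == pytest.approx(0.5)

    def test_constant_image_rejected(self):
        with pytest.raises(ImageDataError, match="Otsu"):
            cell_mask_from_reference(GrayImage(np.full((16, 16), 3.0)))

    def test_fixed_threshold(self):
        img = GrayImage(np.arange(100, dtype=float).reshape(10, 10))
        res = cell_mask_from_reference(img, method="fixed", fixed_threshold=50)
        assert res.mask.sum() == 50

    def test_series_average_recovers_scene_foreground(self):
        _, labels = generate_scene(SceneSpec(n_cells=8, seed=4))
        clean = render_modality(labels, RenderSpec(
            background_level=10, cell_level=100, boundary_or_septum_level=150))
        frames = [corrupt(clean, NoiseSpec(photons_per_unit=None,
                                           read_noise_sd=15, seed=s))
                  for s in range(10)]
        series = TimeSeries(frames)
        res = cell_mask_from_reference(series)
        gt_fg = labels.labels > 0
        assert semantic_iou(res.mask, gt_fg) >= 0.9


class TestMaskedSsim:
    def test_full_mask_equals_unmasked_mean(self, rng):
        gt = GrayImage(rng.random((64, 64)))
        pred = GrayImage(gt.pixels + 0.1 * rng.standard_normal((64, 64)))
        params = SSIMParams(n_scales=1, data_range=1.0)
        full = np.ones((64, 64), dtype=bool)
        assert masked_ssim(pred, gt, full, params) == pytest.approx(
            ssim_map(pred, gt, params)[1], abs=1e-12)

    def test_noisy_background_drags_global_mean(self, rng):
        """Perfect cells + noisy background: the cell-masked value exceeds
        the global mean and equals the oracle average of the map."""
        _, labels = generate_scene(SceneSpec(n_cells=8, seed=6))
        gt = render_modality(labels, RenderSpec(background_level=0.2,
                                                cell_level=0.6))
        cells = labels.labels > 0
        pred = gt.pixels.copy()
        pred[~cells] += 0.3 * rng.standard_normal((~cells).sum())
        params = SSIMParams(n_scales=1, data_range=1.0)
        pred_img = GrayImage(np.clip(pred, 0, None))
        masked = masked_ssim(pred_img, gt, cells, params)
        smap, unmasked = ssim_map(pred_img, gt, params)
        assert masked > unmasked
        assert masked == pytest.approx(float(smap.pixels[cells].mean()),
                                       abs=1e-12)

    def test_reproduced_background_inflates_global_mean(self, rng):
        """Corrupt only the cells: the global mean is over-optimistic,
        the masked value lower - the reason for masking in the first place."""
        _, labels = generate_scene(SceneSpec(n_cells=8, seed=7))
        gt = render_modality(labels, RenderSpec(background_level=0.2,
                                                cell_level=0.6))
        cells = labels.labels > 0
        pred = gt.pixels.copy()
        pred[cells] += 0.3 * rng.standard_normal(cells.sum())
        params = SSIMParams(n_scales=1, data_range=1.0)
        pred_img = GrayImage(np.clip(pred, 0, None))
        masked = masked_ssim(pred_img, gt, cells, params)
        _, unmasked = ssim_map(pred_img, gt, params)
        assert masked < unmasked

    def test_empty_mask_rejected(self, rng):
        img = GrayImage(rng.random((32, 32)))
        with pytest.raises(ImageDataError, match="empty"):
            masked_ssim(img, img, np.zeros((32, 32), dtype=bool))


class TestSubsequentFrameSsim:
    def test_static_noiseless_series_is_exactly_one(self):
        _, labels = generate_scene(SceneSpec(n_cells=6, seed=2))
        clean = render_modality(labels, RenderSpec())
        series = TimeSeries([clean] * 5)
        vals = subsequent_frame_ssim(series, SSIMParams(n_scales=1))
        assert vals == [1.0, 1.0, 1.0, 1.0]

    def test_monotone_decreasing_in_noise_level(self):
        _, labels = generate_scene(SceneSpec(n_cells=10, seed=3))
        clean = render_modality(labels, RenderSpec(
            background_level=10, cell_level=100, boundary_or_septum_level=200))
        means = []
        for sigma in (1.0, 5.0, 20.0):
            frames = [corrupt(clean, NoiseSpec(photons_per_unit=None,
                                               read_noise_sd=sigma,
                                               seed=100 + k))
                      for k in range(6)]
            vals = subsequent_frame_ssim(TimeSeries(frames),
                                         SSIMParams(n_scales=1))
            means.append(float(np.mean(vals)))
        assert means[0] > means[1] > means[2]

    def test_values_match_pairwise_ssim(self, rng):
        frames = [GrayImage(rng.random((32, 32))) for _ in range(4)]
        series = TimeSeries(frames)
        params = SSIMParams(n_scales=1, data_range=1.0)
        vals = subsequent_frame_ssim(series, params)
        for k, v in enumerate(vals):
            assert v == ssim_map(frames[k], frames[k + 1], params)[1]

    def test_reversal_symmetry(self, rng):
        frames = [GrayImage(rng.random((32, 32))) for _ in range(5)]
        params = SSIMParams(n_scales=1, data_range=1.0)
        fwd = subsequent_frame_ssim(TimeSeries(frames), params)
        rev = subsequent_frame_ssim(TimeSeries(frames[::-1]), params)
        assert fwd == pytest.approx(rev[::-1], abs=1e-12)


class TestIntensityTrace:
    def test_constant_series(self):
        frames = [GrayImage(np.full((16, 16), 10.0))] * 3
        assert intensity_trace(TimeSeries(frames)) == [10.0, 10.0, 10.0]

    @pytest.mark.filterwarnings("ignore:zero elongation")
    def test_bleached_timelapse_round_trip(self):
        # a deliberately static scene: bleaching is the only dynamics
        spec = SceneSpec(n_cells=5, seed=9, image_height=128, image_width=128)
        gspec = GrowthSpec(n_frames=11, elongation_rate=0.0,
                           division_length_px=1000,
                           bleach_t_half_frames=10)
        rspec = RenderSpec(background_level=0.0, cell_level=1.0,
                           boundary_or_septum_level=2.0)
        series, gt_labels, _ = simulate_timelapse(
            spec, gspec, rspec, NoiseSpec(photons_per_unit=1000,
                                          read_noise_sd=0.0, seed=1))
        mask = gt_labels[0].labels > 0
        trace = normalize_track_features(intensity_trace(series, mask))
        assert trace[10] == pytest.approx(0.5, rel=0.05)

    def test_background_mask_reads_background_level(self):
        _, labels = generate_scene(SceneSpec(n_cells=5, seed=11))
        img = render_modality(labels, RenderSpec(background_level=0.25,
                                                 cell_level=0.5))
        series = TimeSeries([img, img])
        bg = labels.labels == 0
        trace = intensity_trace(series, bg)
        assert trace == [0.25, 0.25]


class TestBleachFit:
    @pytest.mark.parametrize("t_half", [5.0, 20.0, 50.0, 200.0])
    def test_noiseless_recovery(self, t_half):
        t = np.arange(200)
        trace = 100.0 * 2.0 ** (-t / t_half) + 5.0
        fit = fit_bleaching_halftime(trace)
        assert fit.converged
        assert fit.t_half == pytest.approx(t_half, rel=0.005)
        assert fit.offset == pytest.approx(5.0, abs=0.1)

    def test_constant_trace_sentinel(self):
        fit = fit_bleaching_halftime([7.0] * 20)
        assert not fit.converged and fit.t_half == float("inf")

    def test_rising_trace_sentinel(self):
        fit = fit_bleaching_halftime(np.linspace(1, 10, 30))
        assert not fit.converged and fit.t_half == float("inf")

    def test_frame_interval_scaling(self):
        t = np.arange(100)
        trace = 50.0 * 2.0 ** (-t / 20.0) + 1.0
        fit = fit_bleaching_halftime(trace, frame_interval=2.5)
        assert fit.t_half == pytest.approx(50.0, rel=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ImageDataError):
            fit_bleaching_halftime([5, 4, 3, 2])
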