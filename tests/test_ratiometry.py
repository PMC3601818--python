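"""Measurement chain: background, voxel selection, ratios, smoothing, baseline."""

import numpy as np
import pytest

import vmsync as v
from vmsync.ratiometry import RatioTrace
from vmsync.synthgen import DualChannelMovie, indicator_kernel

from conftest import make_event_log


def toy_movie(gcamp, mcherry, fps=20.0):
    g = np.asarray(gcamp, dtype=np.float32)
    m = np.asarray(mcherry, dtype=np.float32)
    return DualChannelMovie(gcamp=g, mcherry=m, frame_rate_hz=fps)


class TestEstimateBackground:
    def test_noiseless_movie_recovers_background_level(self):
        cfg = v.wildtype(duration_s=3.0, noise_sd=0.0, background_sd=0.0)
        mov = v.render_movie(make_event_log([], 3.0), cfg)
        bg = v.estimate_background(mov, cfg.geometry.masks(cfg.image_shape)["background"])
        assert (bg.mean, bg.sd) == (200.0, 0.0)

    def test_toy_roi_statistics(self):
        # 2x2 frame {100, 100, 300, 300}; background ROI over the two 100s
        mov = toy_movie([[[300, 100], [300, 100]]], [[[300, 100], [300, 100]]])
        roi = np.array([[False, True], [False, True]])
        bg = v.estimate_background(mov, roi)
        assert (bg.mean, bg.sd, bg.source) == (100.0, 0.0, "user_roi")

    def test_gaussian_background_recovered_with_roi(self):
        cfg = v.wildtype(duration_s=5.0, seed=4)  # 100 frames, sd 20 background
        mov = v.render_movie(v.sample_events(cfg), cfg)
        bg = v.estimate_background(mov, cfg.geometry.masks(cfg.image_shape)["background"])
        assert bg.mean == pytest.approx(200.0, abs=2.0)
        assert bg.sd == pytest.approx(20.0, abs=2.0)

    def test_auto_fallback_is_conservative(self):
        cfg = v.wildtype(duration_s=3.0, seed=4)
        mov = v.render_movie(v.sample_events(cfg), cfg)
        bg = v.estimate_background(mov)
        assert bg.source == "auto"
        # lower-tail sample: biased at or below the true background level
        assert bg.mean <= 200.0

    def test_empty_roi_rejected(self):
        mov = toy_movie(np.ones((2, 4, 4)), np.ones((2, 4, 4)))
        with pytest.raises(ValueError):
            v.estimate_background(mov, np.zeros((4, 4), dtype=bool))


class TestSelectVoxels:
    def test_strict_two_sigma_threshold(self):
        # bg 200 +/- 20 -> threshold 240, strict inequality
        mov = toy_movie([[[200, 239, 241, 5000]]], [[[200, 239, 241, 5000]]])
        sel = v.select_voxels(mov, v.BackgroundStats(200.0, 20.0, "user_roi"))
        np.testing.assert_array_equal(sel.masks[0, 0], [False, False, True, True])

    def test_noiseless_selection_equals_roi_geometry(self):
        cfg = v.wildtype(duration_s=3.0, seed=1, noise_sd=0.0, background_sd=0.0)
        mov = v.render_movie(v.sample_events(cfg), cfg)
        masks = cfg.geometry.masks(cfg.image_shape)
        bg = v.estimate_background(mov, masks["background"])
        sel = v.select_voxels(mov, bg)
        roi = masks["A"] | masks["P"]
        for f in range(mov.n_frames):
            np.testing.assert_array_equal(sel.masks[f], roi)

    def test_all_background_frame_selects_nothing(self):
        mov = toy_movie(np.full((3, 4, 4), 200.0), np.full((3, 4, 4), 200.0))
        sel = v.select_voxels(mov, v.BackgroundStats(200.0, 20.0, "user_roi"))
        assert sel.counts.sum() == 0


class TestExtractRatioTrace:
    def test_single_voxel_ratio(self):
        mov = toy_movie([[[400.0]]], [[[200.0]]])
        sel = v.VoxelSelection(np.ones((1, 1, 1), dtype=bool))
        assert v.extract_ratio_trace(mov, sel).ratio[0] == pytest.approx(2.0)

    def test_mean_of_ratios_not_ratio_of_sums(self):
        # (2/4, 4/4) -> (0.5 + 1.0)/2 = 0.75, not 6/8
        mov = toy_movie([[[2.0, 4.0]]], [[[4.0, 4.0]]])
        sel = v.VoxelSelection(np.ones((1, 1, 2), dtype=bool))
        assert v.extract_ratio_trace(mov, sel).ratio[0] == pytest.approx(0.75)

    def test_empty_frames_marked_missing(self):
        mov = toy_movie(np.full((2, 2, 2), 400.0), np.full((2, 2, 2), 200.0))
        masks = np.zeros((2, 2, 2), dtype=bool)
        masks[0] = True
        tr = v.extract_ratio_trace(mov, v.VoxelSelection(masks))
        assert tr.ratio[0] == pytest.approx(2.0) and np.isnan(tr.ratio[1])

    def test_gain_invariance(self):
        cfg = v.wildtype(duration_s=3.0, seed=8)
        mov = v.render_movie(v.sample_events(cfg), cfg)
        sel = v.select_voxels(mov, v.estimate_background(mov))
        base = v.extract_ratio_trace(mov, sel).ratio
        scaled_movie = DualChannelMovie(
            gcamp=mov.gcamp * 1.7, mcherry=mov.mcherry * 1.7, frame_rate_hz=20.0,
            bit_depth=18,  # headroom so scaled counts stay in range
        )
        scaled = v.extract_ratio_trace(scaled_movie, sel).ratio
        np.testing.assert_allclose(scaled, base, rtol=1e-6)

    def test_bad_compartment_mask_rejected(self):
        mov = toy_movie(np.ones((1, 4, 4)), np.ones((1, 4, 4)))
        sel = v.VoxelSelection(np.ones((1, 4, 4), dtype=bool))
        with pytest.raises(ValueError):
            v.extract_ratio_trace(mov, sel, compartment_mask=np.ones((8, 8), dtype=bool))


def _trace(values, fps=20.0, n_voxels=None):
    values = np.asarray(values, dtype=float)
    return RatioTrace(
        time_s=np.arange(len(values)) / fps, ratio=values, n_voxels=n_voxels
    )


class TestRollingAverage:
    def test_hand_example_with_shrinking_edges(self):
        out = v.rolling_average(_trace([0, 0, 3, 0, 0]), 3)
        np.testing.assert_allclose(out.ratio, [0, 1, 1, 1, 0])

    def test_constant_is_fixed_point(self):
        out = v.rolling_average(_trace([2.0] * 10), 3)
        np.testing.assert_allclose(out.ratio, 2.0)

    def test_window_one_is_identity(self):
        x = np.arange(1.0, 6.0)
        np.testing.assert_array_equal(v.rolling_average(_trace(x), 1).ratio, x)

    def test_missing_values_propagate_and_are_excluded(self):
        x = np.array([1.0, np.nan, 3.0, 3.0])
        out = v.rolling_average(_trace(x), 3).ratio
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(1.0)  # nan neighbour excluded
        assert out[2] == pytest.approx(3.0)

    def test_bounded_by_input_range(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 2.0, size=50)
        out = v.rolling_average(_trace(x), 3).ratio
        assert out.min() >= x.min() - 1e-12 and out.max() <= x.max() + 1e-12

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            v.rolling_average(_trace([1.0] * 10), window)

    def test_window_larger_than_trace_rejected(self):
        with pytest.raises(ValueError):
            v.rolling_average(_trace([1.0] * 3), 5)


class TestComputeDelta:
    def test_lowest_decile_baseline_hand_example(self):
        # 10 samples, lowest decile = {1} -> R0 = 1, max dR/R = 200%
        delta = v.compute_delta(_trace([1, 1, 1, 1, 1, 1, 1, 1, 2, 3]))
        assert delta.baseline_R0 == pytest.approx(1.0)
        assert delta.dRR.max() == pytest.approx(2.0)

    def test_constant_trace_gives_zero_delta(self):
        delta = v.compute_delta(_trace([3.0] * 20))
        np.testing.assert_allclose(delta.dRR, 0.0, atol=1e-12)

    def test_argmin_sample_is_nonpositive(self):
        rng = np.random.default_rng(3)
        delta = v.compute_delta(_trace(rng.uniform(0.5, 3.0, 40)))
        assert delta.dRR.min() <= 0

    def test_lowest_decile_maps_to_zero_mean(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.5, 3.0, 100)
        delta = v.compute_delta(_trace(x))
        k = 10  # ceil(0.10 * 100)
        low = np.sort(delta.dRR)[:k]
        assert abs(low.mean()) < 1e-9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            v.compute_delta(_trace([1.0] * 5))

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            v.compute_delta(_trace([-1.0] * 20))


class TestEndToEnd:
    def test_noiseless_movie_reproduces_ideal_trace(self, noiseless_wt):
        """Movie rendering then full extraction agrees with the ideal dR/R
        to 1e-6 relative error when both see the same smoothing/baseline."""
        cfg = noiseless_wt
        events = v.sample_events(cfg)
        ideal = v.render_traces(events, cfg)
        mov = v.render_movie(events, cfg)
        masks = cfg.geometry.masks(cfg.image_shape)
        got = v.movie_to_delta_traces(
            mov, {"A": masks["A"], "P": masks["P"]}, bg_roi=masks["background"]
        )
        rest = cfg.gcamp_rest_mean / cfg.mcherry_mean
        for comp, ideal_drr in (("A", ideal.dRR_A), ("P", ideal.dRR_P)):
            ref = v.compute_delta(
                v.rolling_average(RatioTrace(ideal.time_s, rest * (1 + ideal_drr), comp))
            )
            scale = max(1.0, np.abs(ref.dRR).max())
            assert np.abs(got[comp].dRR - ref.dRR).max() / scale < 1e-6

    def test_smoothing_bias_bounded_by_kernel_analysis(self, noiseless_wt):
        """Smoothed+baselined output deviates from the raw ideal trace by at
        most the 3-point smoothing bias of the kernel times the largest
        amplitude (plus baseline slack)."""
        cfg = noiseless_wt
        events = v.sample_events(cfg)
        ideal = v.render_traces(events, cfg)
        mov = v.render_movie(events, cfg)
        masks = cfg.geometry.masks(cfg.image_shape)
        got = v.movie_to_delta_traces(
            mov, {"A": masks["A"], "P": masks["P"]}, bg_roi=masks["background"]
        )
        dt = 1.0 / cfg.frame_rate_hz
        t = np.arange(-1.0, 5.0, dt / 10)
        k = indicator_kernel(t, cfg.tau_rise_s, cfg.tau_decay_s)
        k_sm = (
            indicator_kernel(t - dt, cfg.tau_rise_s, cfg.tau_decay_s)
            + k
            + indicator_kernel(t + dt, cfg.tau_rise_s, cfg.tau_decay_s)
        ) / 3.0
        amp_max = events.events.amplitude_dRR.max()
        bound = amp_max * np.abs(k - k_sm).max() + 1e-3  # baseline slack
        for comp, ideal_drr in (("A", ideal.dRR_A), ("P", ideal.dRR_P)):
            assert np.abs(got[comp].dRR - ideal_drr).max() <= bound

    def test_selected_voxel_count_band_at_acquisition_scale(self):
        # default geometry at 256x256: the per-frame measurement selection
        # (threshold mask within the muscle ROIs) lands near ~500 voxels
        cfg = v.wildtype(duration_s=1.0, seed=2, image_shape=(256, 256))
        mov = v.render_movie(v.sample_events(cfg), cfg)
        masks = cfg.geometry.masks(cfg.image_shape)
        sel = v.select_voxels(
            mov, v.estimate_background(mov, masks["background"])
        )
        muscle = masks["A"] | masks["P"]
        counts = (sel.masks & muscle).sum(axis=(1, 2))
        assert 100 <= np.median(counts) <= 1000


class TestIntensityModulatedRendering:
    def test_color_bins_and_no_measurement_side_effects(self):
        cfg = v.wildtype(duration_s=2.0, seed=6, noise_sd=0.0, background_sd=0.0)
        log = make_event_log([(0.5, "both", 0.0, 2.0, "egg_laying")], 2.0)
        mov = v.render_movie(log, cfg)
        masks = cfg.geometry.masks(cfg.image_shape)
        bg = v.estimate_background(mov, masks["background"])
        sel = v.select_voxels(mov, bg)
        before = v.extract_ratio_trace(mov, sel).ratio.copy()
        rest = cfg.gcamp_rest_mean / cfg.mcherry_mean
        rgb = v.render_intensity_modulated(mov, sel, baseline_R0=rest)
        assert rgb.shape == mov.gcamp.shape + (3,)
        # frame 0 (pre-event, dRR=0) and the peak frame map to opposite ends
        from matplotlib import colormaps

        cmap = colormaps["rainbow"]
        roi = masks["A"]
        peak_frame = int(np.argmax(mov.gcamp[:, roi].mean(axis=1)))
        bright = mov.mcherry.max()
        lo = np.asarray(cmap(0.0)[:3]) * (cfg.mcherry_mean / bright)
        hi = np.asarray(cmap(1.0)[:3]) * (cfg.mcherry_mean / bright)
        np.testing.assert_allclose(rgb[0][roi], np.tile(lo, (roi.sum(), 1)), atol=1e-6)
        np.testing.assert_allclose(
            rgb[peak_frame][roi], np.tile(hi, (roi.sum(), 1)), atol=1e-6
        )
        after = v.extract_ratio_trace(mov, sel).ratio
        np.testing.assert_array_equal(before, after)
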