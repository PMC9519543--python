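import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

from spiris import (FrameStack,
                    SimulationConfig, binarize, correlate, detect_stack,
                    differential_image, extract_and_filter_keypoints,
                    normalize_stack, pseudomedian_smooth, render_timelapse,
                    render_zstack, sample_events, temporal_average,
                    temporal_baseline)
from spiris.detect import _pseudomedian_dense, detect_frame
from spiris.simulate import GroundTruthEvent, default_spot, defocus_amplitude

from conftest import plant_particles


def _stack(frames, kind="time", pitch=0.5):
    frames = np.asarray(frames, dtype=float)
    return FrameStack(frames, kind, np.arange(len(frames), dtype=float), pitch)


class TestTemporalAverage:
    def test_n1_is_identity(self):
        s = _stack(np.random.default_rng(0).normal(100, 1, (5, 8, 8)))
        out = temporal_average(s, 1)
        assert np.array_equal(out.frames, s.frames)

    def test_noise_sd_scales_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(1)
        s = _stack(rng.normal(100.0, 2.0, (40, 64, 64)))
        out = temporal_average(s, 4)
        sd = out.frames.std()
        assert sd == pytest.approx(1.0, rel=0.10)

    def test_incomplete_tail_block_dropped(self):
        s = _stack(np.arange(8, dtype=float)[:, None, None] * np.ones((8, 4, 4)))
        out = temporal_average(s, 3)
        assert len(out) == 2
        assert out.frames[0, 0, 0] == pytest.approx(1.0)  # mean of 0,1,2
        assert out.axis_values.tolist() == [1.0, 4.0]

    def test_n_larger_than_stack_errors(self):
        s = _stack(np.zeros((3, 4, 4)) + 1)
        with pytest.raises(ValueError, match="exceeds frame count"):
            temporal_average(s, 5)


class TestPseudomedian:
    def test_constant_image_unchanged(self):
        img = np.full((30, 30), 7.0)
        assert np.allclose(pseudomedian_smooth(img, 5), 7.0)

    def test_small_bright_bump_suppressed(self):
        # 3x3 bump of 200 on constant 100, kernel 9: background estimate
        # at the bump center stays < 110
        img = np.full((40, 40), 100.0)
        img[18:21, 18:21] = 200.0
        out = pseudomedian_smooth(img, 9)
        assert out[19, 19] < 110.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sparse_close_to_dense_on_smooth_fields(self, seed):
        rng = np.random.default_rng(seed)
        field = ndimage.gaussian_filter(rng.normal(0, 1, (80, 80)), 16)
        dense = _pseudomedian_dense(field, 9)
        sparse = pseudomedian_smooth(field, 9)
        assert np.abs(dense - sparse).max() < 0.02 * np.ptp(field)

    def test_kernel_larger_than_image_errors(self):
        with pytest.raises(ValueError, match="kernel"):
            pseudomedian_smooth(np.zeros((5, 5)), 7)


class TestNormalization:
    def test_constant_stack_becomes_ones(self):
        out = normalize_stack(_stack(np.full((5, 6, 6), 123.0), "z"))
        assert np.allclose(out.frames, 1.0)

    def test_pixel_series_divided_by_median(self):
        frames = np.ones((3, 2, 2))
        frames[:, 0, 0] = [90.0, 100.0, 110.0]
        out = normalize_stack(_stack(frames, "z"))
        assert out.frames[:, 0, 0].tolist() == pytest.approx([0.9, 1.0, 1.1])

    def test_output_median_is_exactly_one_for_odd_counts(self):
        rng = np.random.default_rng(2)
        out = normalize_stack(_stack(rng.uniform(50, 150, (7, 10, 10)), "z"))
        assert np.all(np.median(out.frames, axis=0) == 1.0)

    def test_nonpositive_median_errors(self):
        frames = np.full((3, 4, 4), 1.0)
        frames[:, 2, 2] = [-1.0, 0.0, 0.5]
        with pytest.raises(ValueError, match="median"):
            normalize_stack(_stack(frames, "z"))

    def test_needs_three_frames(self):
        with pytest.raises(ValueError, match="3 frames"):
            normalize_stack(_stack(np.ones((2, 4, 4))))

    def test_min_block_baseline_robust_to_long_occupancy(self):
        # a particle bound from frame 4 onward occupies > half the series;
        # the median baseline absorbs it, the robust minimum does not
        frames = np.full((30, 8, 8), 100.0)
        frames[4:, 3, 3] = 130.0
        s = _stack(frames)
        assert temporal_baseline(s, "median")[3, 3] == pytest.approx(130.0)
        assert temporal_baseline(s, "min_block", block=4)[3, 3] == pytest.approx(100.0)


class TestDifferentialImage:
    def test_constant_stack_gives_zeros(self):
        assert np.all(differential_image(_stack(np.ones((4, 5, 5)))) == 0.0)

    def test_max_minus_min(self):
        frames = np.ones((3, 2, 2))
        frames[:, 1, 1] = [0.9, 1.0, 1.1]
        d = differential_image(_stack(frames))
        assert d[1, 1] == pytest.approx(0.2)
        assert np.all(d >= 0)

    def test_matches_defocus_excursion_of_planted_particle(self, noiseless_config):
        stack = render_zstack(noiseless_config, [(40.0, 30.0)])
        a = defocus_amplitude(noiseless_config, stack.axis_values)
        d = differential_image(stack)
        assert d[30, 40] == pytest.approx(np.ptp(a) * noiseless_config.background_level)


class TestCorrelate:
    def test_perfect_self_match_scores_one(self, kernel):
        img = np.zeros((40, 40))
        img[10:21, 14:25] = kernel.template
        score = correlate(img, kernel)
        iy, ix = np.unravel_index(score.argmax(), score.shape)
        assert (iy, ix) == (15, 19)
        assert score.max() == pytest.approx(1.0)
        assert score.min() >= -1.0

    def test_pure_noise_scores_below_half(self, kernel):
        # null distribution: max ZNCC over a 64x64 noise image < 0.5
        # in at least 49 of 50 seeds
        hits = sum(
            correlate(np.random.default_rng(s).normal(0, 1, (64, 64)), kernel).max()
            < 0.5
            for s in range(50)
        )
        assert hits >= 49

    def test_two_planted_particles_peak_within_one_pixel(self, kernel):
        img, pts = plant_particles((64, 64), 2, 150.0, min_sep=20, seed=3)
        score = correlate(img - 1000.0, kernel)
        for x, y in pts:
            win = score[int(y) - 3:int(y) + 4, int(x) - 3:int(x) + 4]
            iy, ix = np.unravel_index(win.argmax(), win.shape)
            assert abs(ix + int(x) - 3 - x) <= 1.0
            assert abs(iy + int(y) - 3 - y) <= 1.0

    def test_flat_windows_score_zero(self, kernel):
        assert np.all(correlate(np.full((32, 32), 5.0), kernel) == 0.0)


class TestBinarize:
    def test_threshold_near_one_keeps_only_the_perfect_match(self, kernel):
        img = np.zeros((40, 40))
        img[10:21, 14:25] = kernel.template
        mask = binarize(correlate(img, kernel), 1.0 - 1e-9)
        assert mask[15, 19]
        assert mask.sum() == 1

    @given(st.floats(0.1, 0.5), st.floats(0.5, 0.99), st.integers(0, 100))
    def test_masks_nest_monotonically(self, t1, t2, seed):
        score = np.random.default_rng(seed).uniform(-1, 1, (20, 20))
        low, high = sorted((t1, t2))
        assert not np.any(binarize(score, high) & ~binarize(score, low))

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((4, 4)), 0.0)


class TestKeypoints:
    def test_empty_mask_gives_no_detections(self, det_params):
        dets = extract_and_filter_keypoints(
            np.zeros((20, 20), bool), np.zeros((20, 20)), det_params)
        assert dets == []

    def test_round_disc_kept_elongated_line_rejected(self, det_params):
        mask = np.zeros((40, 60), bool)
        yy, xx = np.mgrid[:40, :60]
        mask[(yy - 15) ** 2 + (xx - 15) ** 2 <= 9] = True  # disc, radius 3
        mask[30, 20:40] = True  # 1x20 line
        score = np.ones((40, 60)) * 0.8
        dets = extract_and_filter_keypoints(mask, score, det_params)
        assert len(dets) == 1
        assert dets[0].x == pytest.approx(15.0)
        assert dets[0].y == pytest.approx(15.0)
        # the line fails the compactness (area/perimeter) criterion
        disc_area = int(((yy - 15) ** 2 + (xx - 15) ** 2 <= 9).sum())
        assert dets[0].area == disc_area

    def test_fifty_planted_particles_all_recovered_subpixel(self, kernel, det_params):
        img, pts = plant_particles((128, 128), 50, 150.0, seed=1)
        dets = detect_frame(img, kernel, det_params)
        assert len(dets) == 50
        errors = [min(np.hypot(d.x - x, d.y - y) for d in dets) for x, y in pts]
        assert max(errors) <= 0.5


class TestDetectStack:
    def test_blank_movie_yields_empty_table(self, kernel, det_params):
        cfg = SimulationConfig(rng_seed=21, image_shape=(64, 64), duration=600.0)
        stack = render_timelapse(cfg, [])
        table = detect_stack(stack, kernel, det_params, "kinetic")
        assert table.empty

    def test_endpoint_zstack_counts_planted_particles(self, kernel, det_params):
        cfg = SimulationConfig(rng_seed=22)
        img, pts = plant_particles((128, 128), 20, 1.0, seed=5)
        stack = render_zstack(cfg, pts, cfg.rng())
        table = detect_stack(stack, kernel, det_params, "endpoint")
        assert len(table) == 20
        assert (table["frame_index"] == -1).all()

    def test_kinetic_detection_starts_at_binding_frame(self, kernel, det_params):
        cfg = SimulationConfig(rng_seed=23, image_shape=(64, 64), duration=600.0)
        events = [GroundTruthEvent(0, "s", 30.0, 25.0, t_bind=203.0,
                                   t_unbind=np.inf)]
        stack = render_timelapse(cfg, events, cfg.rng())
        table = detect_stack(stack, kernel, det_params, "kinetic")
        assert not table.empty
        first = table["frame_index"].min()
        bind_frame = int(np.searchsorted(stack.axis_values, 203.0))
        assert abs(first - bind_frame) <= 1

    def test_recall_and_precision_one_on_noiseless_scene(self, kernel, det_params):
        img, pts = plant_particles((128, 128), 50, 150.0, seed=2)
        dets = detect_frame(img, kernel, det_params)
        matched = sum(
            1 for x, y in pts if any(np.hypot(d.x - x, d.y - y) <= 2 for d in dets))
        assert matched == 50 and len(dets) == 50  # recall = precision = 1.0

    def test_recall_at_contrast_to_noise_ten(self, kernel, det_params):
        # contrast 0.1, noise 0.01 of background: recall >= 0.95
        total = hit = 0
        for seed in range(5):
            img, pts = plant_particles((128, 128), 50, 100.0, seed=seed,
                                       noise_sd=10.0)
            dets = detect_frame(img, kernel, det_params)
            hit += sum(1 for x, y in pts
                       if any(np.hypot(d.x - x, d.y - y) <= 2 for d in dets))
            total += 50
        assert hit / total >= 0.95

    def test_localization_error_at_default_noise(self, kernel, det_params):
        img, pts = plant_particles((128, 128), 50, 150.0, seed=4, noise_sd=10.0)
        dets = detect_frame(img, kernel, det_params)
        errors = [min(np.hypot(d.x - x, d.y - y) for d in dets) for x, y in pts]
        assert np.mean(errors) <= 1.0

    def test_operators_are_deterministic(self, kernel, det_params):
        cfg = SimulationConfig(rng_seed=24, image_shape=(64, 64), duration=400.0)
        spot = default_spot(cfg)
        events = sample_events(cfg, spot, 1e-15, cfg.rng())
        stack = render_timelapse(cfg, events, cfg.rng())
        a = detect_stack(stack, kernel, det_params, "kinetic")
        b = detect_stack(stack, kernel, det_params, "kinetic")
        assert a.equals(b)
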