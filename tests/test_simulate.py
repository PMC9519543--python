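import numpy as np
import pytest

from spiris import (SimulationConfig, binding_rate, cumulative_events,
                    differential_image, make_calibration_dataset,
                    nonspecific_rate_for_lod, planted_lod, render_timelapse,
                    render_zstack, sample_events)
from spiris.simulate import default_spot, defocus_amplitude


def _cfg(**kw):
    kw.setdefault("nonspecific_rate", 0.0)
    return SimulationConfig(**kw)


class TestEventSampling:
    def test_zero_concentration_gives_no_events(self):
        cfg = _cfg(rng_seed=1)
        assert sample_events(cfg, default_spot(cfg), 0.0) == []

    def test_negative_concentration_rejected(self):
        cfg = _cfg()
        with pytest.raises(ValueError, match="concentration"):
            sample_events(cfg, default_spot(cfg), -1e-15)

    def test_poisson_mean_event_count(self):
        # k = 10/h at c_ref over 1 h: mean count 10 within 3 SE over 1000 seeds
        cfg = _cfg(rate_constant=10.0, duration=3600.0, rng_seed=0)
        spot = default_spot(cfg)
        rng = cfg.rng()
        counts = [len(sample_events(cfg, spot, cfg.c_ref, rng)) for _ in range(1000)]
        se = np.sqrt(10.0 / 1000)
        assert abs(np.mean(counts) - 10.0) < 3 * se

    def test_two_thirds_rate_scaling_eightfold(self):
        # (8)^(2/3) = 4: mean count at 8*c_ref is 4x the c_ref mean
        cfg = _cfg(rate_constant=10.0, duration=3600.0, rng_seed=2)
        spot = default_spot(cfg)
        rng = cfg.rng()
        n = 800
        lo = np.array([len(sample_events(cfg, spot, cfg.c_ref, rng)) for _ in range(n)])
        hi = np.array([len(sample_events(cfg, spot, 8 * cfg.c_ref, rng))
                       for _ in range(n)])
        assert binding_rate(cfg, 8 * cfg.c_ref) == pytest.approx(
            4 * binding_rate(cfg, cfg.c_ref))
        diff_se = np.sqrt(hi.var() / n + 16 * lo.var() / n)
        assert abs(hi.mean() - 4 * lo.mean()) < 3 * diff_se

    def test_arrivals_are_poisson_dispersed(self):
        # variance/mean within [0.8, 1.2] over 500 seeds
        cfg = _cfg(rate_constant=30.0, duration=3600.0, rng_seed=3)
        spot = default_spot(cfg)
        rng = cfg.rng()
        counts = np.array([len(sample_events(cfg, spot, cfg.c_ref, rng))
                           for _ in range(500)])
        assert 0.8 <= counts.var() / counts.mean() <= 1.2

    def test_event_geometry_and_dwell(self):
        cfg = _cfg(rate_constant=400.0, duration=3600.0,
                   permanent_fraction=0.3, rng_seed=4)
        spot = default_spot(cfg)
        events = sample_events(cfg, spot, cfg.c_ref)
        assert len(events) > 200
        for ev in events:
            assert spot.contains(ev.x, ev.y)
            assert 0.0 <= ev.t_bind <= cfg.duration
            assert ev.t_unbind > ev.t_bind
        frac_perm = np.mean([ev.permanent for ev in events])
        se = np.sqrt(0.3 * 0.7 / len(events))
        assert abs(frac_perm - 0.3) < 4 * se

    def test_same_seed_bit_identical(self):
        cfg = _cfg(rng_seed=7)
        spot = default_spot(cfg)
        a = sample_events(cfg, spot, 1e-15)
        b = sample_events(cfg, spot, 1e-15)
        assert a == b
        sa = render_timelapse(SimulationConfig(rng_seed=7), a)
        sb = render_timelapse(SimulationConfig(rng_seed=7), b)
        assert np.array_equal(sa.frames, sb.frames)


class TestTimelapseRendering:
    def test_blank_noiseless_movie_is_constant(self, noiseless_config):
        stack = render_timelapse(noiseless_config, [])
        assert np.all(stack.frames == noiseless_config.background_level)

    def test_permanent_event_appears_at_its_frame(self, noiseless_config):
        from spiris.simulate import GroundTruthEvent

        ev = GroundTruthEvent(0, "s", 40.0, 60.0, t_bind=50.0, t_unbind=np.inf)
        stack = render_timelapse(noiseless_config, [ev])
        bg = noiseless_config.background_level
        px = stack.frames[:, 60, 40]
        assert np.all(px[:5] == bg)
        assert np.all(px[5:] > bg * 1.1)

    def test_two_events_give_two_local_maxima(self, noiseless_config):
        from spiris.simulate import GroundTruthEvent

        evs = [GroundTruthEvent(0, "s", 50.0, 50.0, 0.0, np.inf),
               GroundTruthEvent(1, "s", 60.0, 50.0, 0.0, np.inf)]
        stack = render_timelapse(noiseless_config, evs)
        frame = stack.frames[-1]
        for ev in evs:
            win = frame[45:56, int(ev.x) - 3:int(ev.x) + 4]
            iy, ix = np.unravel_index(win.argmax(), win.shape)
            assert abs(ix + int(ev.x) - 3 - ev.x) <= 0.5
            assert abs(iy + 45 - ev.y) <= 0.5

    def test_event_outside_bounds_rejected(self, noiseless_config):
        from spiris.simulate import GroundTruthEvent

        ev = GroundTruthEvent(0, "s", 500.0, 10.0, 0.0, np.inf)
        with pytest.raises(ValueError, match="outside image bounds"):
            render_timelapse(noiseless_config, [ev])

    def test_visible_events_exceed_noise_floor(self):
        # planted events leave a > 5 sigma excursion at their centroid
        cfg = SimulationConfig(rng_seed=9)
        spot = default_spot(cfg)
        rng = cfg.rng()
        events = [ev for ev in sample_events(cfg, spot, 3e-16, rng)
                  if ev.t_bind < cfg.duration - 2 * cfg.frame_interval]
        stack = render_timelapse(cfg, events, rng)
        noise_sd = cfg.shot_noise_scale * cfg.background_level
        times = stack.axis_values
        for ev in events:
            fi = int(np.searchsorted(times, ev.t_bind))
            visible = times[(times >= ev.t_bind) & (times < ev.t_unbind)]
            if len(visible) == 0:
                continue
            val = stack.frames[fi, int(round(ev.y)), int(round(ev.x))]
            assert val - cfg.background_level > 5 * noise_sd


class TestZStackRendering:
    def test_no_particles_stays_at_noise_floor(self):
        cfg = SimulationConfig(rng_seed=11)
        stack = render_zstack(cfg, [])
        diff = differential_image(stack)
        noise_sd = cfg.shot_noise_scale * cfg.background_level
        # max-min of iid normals across ~17 planes is a few sigma, never huge
        assert diff.max() < 8 * noise_sd
        assert diff.mean() > noise_sd  # but clearly nonzero (it is noise range)

    def test_single_particle_excursion_matches_defocus_curve(self, noiseless_config):
        stack = render_zstack(noiseless_config, [(64.0, 64.0)])
        a = defocus_amplitude(noiseless_config, stack.axis_values)
        expected = np.ptp(a) * noiseless_config.background_level
        assert differential_image(stack)[64, 64] == pytest.approx(expected)

    def test_contrast_flips_sign_across_focus(self, noiseless_config):
        for delta in (0.1, 0.3, 0.5):
            a = defocus_amplitude(noiseless_config, np.array([-delta, delta]))
            assert a[0] * a[1] < 0


class TestCalibrationDataset:
    def test_default_grid_spans_decades_100am_to_1pm(self):
        cfg = SimulationConfig()
        assert cfg.concentrations[0] == pytest.approx(1e-16)
        assert cfg.concentrations[-1] == pytest.approx(1e-12)
        ratios = np.diff(np.log10(cfg.concentrations))
        assert np.allclose(ratios, 1.0)

    def test_blank_rates_zero_without_nonspecific_binding(self):
        cfg = _cfg(rng_seed=13)
        ds = make_calibration_dataset(cfg, replicates=2, blank_replicates=5)
        assert np.all(ds.blank_rates == 0.0)

    def test_replicate_rates_match_rate_law(self):
        # 200 replicates: mean measured rate within 3 SE of lambda(c) at every c
        cfg = _cfg(rng_seed=14)
        ds = make_calibration_dataset(cfg, replicates=200, blank_replicates=2)
        for c, grp in ds.rates.groupby("concentration"):
            lam = binding_rate(cfg, c)
            se = np.sqrt(lam / ds.duration_h / len(grp))
            assert abs(grp["rate_per_h"].mean() - lam) < 3 * se

    def test_requires_two_concentrations(self):
        with pytest.raises(ValueError, match="at least 2"):
            make_calibration_dataset(_cfg(), concentrations=(1e-15,))


class TestGroundTruthHelpers:
    def test_cumulative_events_counts_bind_times(self):
        from spiris.simulate import GroundTruthEvent

        evs = [GroundTruthEvent(i, "s", 0, 0, t, t + 1) for i, t in
               enumerate([5.0, 5.0, 30.0])]
        counts = cumulative_events(evs, np.array([0.0, 10.0, 60.0]))
        assert counts.tolist() == [0, 2, 3]

    def test_planted_lod_round_trips_with_nonspecific_rate(self):
        cfg = SimulationConfig()
        lod = planted_lod(cfg)
        assert nonspecific_rate_for_lod(cfg, lod) == pytest.approx(
            cfg.nonspecific_rate)
        # more nonspecific binding can only raise the detection limit
        worse = SimulationConfig(nonspecific_rate=4 * cfg.nonspecific_rate)
        assert planted_lod(worse) > lod

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(psf_sigma=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(permanent_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(z_range=(2.0, -2.0))
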