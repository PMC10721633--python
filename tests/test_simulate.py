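"""Simulator: placement geometry, event statistics, rendering physics."""

import dataclasses

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist

from spotdrop import (
    CONDITION_PRESETS,
    SimulationConfig,
    condition_preset,
    render_movie,
    sample_event_schedule,
    sample_spot_positions,
    simulate_movie,
)
from spotdrop.errors import CrowdedFieldError
from spotdrop.simulate import GroundTruthEvent


class TestSpotPositions:
    def test_zero_spots_gives_empty_list(self):
        assert sample_spot_positions(0, (64, 64), 10.0, seed=0) == []

    def test_pairwise_spacing_holds_exhaustively(self):
        pts = sample_spot_positions(100, (512, 512), 10.0, seed=1)
        assert len(pts) == 100
        assert pdist(np.asarray(pts, dtype=float)).min() >= 10.0

    def test_positions_respect_border_margin(self):
        pts = np.asarray(sample_spot_positions(50, (128, 128), 5.0, seed=2, margin=8))
        assert pts.min() >= 8 and pts.max() <= 119

    def test_infeasible_spacing_raises_instead_of_looping(self):
        # spacing exceeds the usable-region diagonal: geometrically impossible
        with pytest.raises(CrowdedFieldError):
            sample_spot_positions(2, (64, 64), 100.0, seed=0)

    def test_overcrowded_field_raises_after_bounded_attempts(self):
        with pytest.raises(CrowdedFieldError):
            sample_spot_positions(500, (64, 64), 10.0, seed=0, max_attempts=50, max_restarts=2)

    def test_deterministic_for_fixed_seed(self):
        a = sample_spot_positions(30, (256, 256), 8.0, seed=7)
        b = sample_spot_positions(30, (256, 256), 8.0, seed=7)
        assert a == b


class TestEventSchedule:
    def test_no_event_limit(self, small_config):
        cfg = dataclasses.replace(small_config, drop_probability=0.0, photobleach_rate=0.0)
        events = sample_event_schedule(cfg, 200, seed=0)
        assert all(e.event_type == "none" and e.event_frame is None for e in events)

    def test_certain_drop_times_follow_truncated_exponential(self):
        cfg = SimulationConfig(
            drop_probability=1.0, drop_time_scale=60.0, photobleach_rate=0.0, event_onset=0.0
        )
        n = 10_000
        events = sample_event_schedule(cfg, n, seed=3)
        assert all(e.event_type == "drop" for e in events)
        frames = np.array([e.event_frame for e in events])
        span, dt, scale = cfg.acquisition_span, cfg.frame_interval, cfg.drop_time_scale

        def cdf(t):
            return -np.expm1(-t / scale) / -np.expm1(-span / scale)

        # empirical CDF at every frame boundary vs the closed form:
        # frame f collects events with t in [f*dt, (f+1)*dt)
        edges = np.arange(1, cfg.n_frames + 1) * dt
        ecdf = np.searchsorted(np.sort(frames * dt), edges, side="left") / n
        assert np.max(np.abs(ecdf - cdf(edges))) < 0.025  # ~2x the 5% KS bound at n=1e4

    def test_events_never_precede_protein_onset(self):
        cfg = SimulationConfig(drop_probability=1.0, event_onset=30.0, frame_interval=5.0)
        events = sample_event_schedule(cfg, 500, seed=4)
        assert min(e.event_frame for e in events) >= int(30.0 / 5.0)

    def test_photobleach_competes_and_earlier_process_wins(self):
        cfg = SimulationConfig(
            drop_probability=1.0, drop_time_scale=1e9, photobleach_rate=0.05, event_onset=0.0
        )
        # photobleaching (mean wait 20 s) should almost always pre-empt the
        # drop, whose huge scale truncates to ~uniform over the 605-s window
        events = sample_event_schedule(cfg, 300, seed=5)
        n_bleach = sum(e.event_type == "photobleach" for e in events)
        assert n_bleach > 270

    def test_empirical_drop_fraction_matches_probability(self):
        p = 0.3
        n = 10_000
        cfg = SimulationConfig(drop_probability=p, photobleach_rate=0.0)
        events = sample_event_schedule(cfg, n, seed=6)
        frac = sum(e.event_type == "drop" for e in events) / n
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_preset_mean_drop_count_matches_binomial(self):
        preset = condition_preset("ATP")
        cfg = SimulationConfig(
            drop_probability=preset.drop_probability, photobleach_rate=0.0
        )
        counts = [
            sum(e.event_type == "drop"
                for e in sample_event_schedule(cfg, preset.n_spots, seed=s))
            for s in range(200)
        ]
        se_mean = np.sqrt(preset.n_spots * preset.drop_probability
                          * (1 - preset.drop_probability) / 200)
        assert abs(np.mean(counts) - preset.n_drops) < 3 * se_mean


class TestConditionPresets:
    @pytest.mark.parametrize(
        "name,drops,total",
        [
            ("ATP", 255, 330),
            ("ADP", 48, 413),
            ("no_protein", 44, 340),
            ("boxes_scr", 61, 609),
            ("trios_scr", 82, 706),
            ("R264A", 24, 353),
            ("I190A", 23, 309),
            ("domainIII_IV", 209, 387),
            ("dual_atto647", 194, 235),
            ("dual_atto565", 170, 413),
        ],
    )
    def test_registered_counts(self, name, drops, total):
        p = condition_preset(name)
        assert p.n_drops == drops and p.n_spots == total
        assert p.drop_probability == pytest.approx(drops / total)
        assert 0.0 <= p.drop_probability <= 1.0

    def test_unknown_preset_lists_available(self):
        with pytest.raises(KeyError, match="ATP"):
            condition_preset("does_not_exist")


class TestRendering:
    def test_background_poisson_moments(self):
        cfg = SimulationConfig(
            field_shape=(256, 256), n_spots=0, read_noise_sd=0.0, camera_gain=1.0,
            background_level=100.0,
        )
        movie = render_movie(cfg, [], [], seed=0)
        data = movie.data.astype(float)
        assert abs(data.mean() - 100.0) / 100.0 < 0.02
        assert abs(data.var() - 100.0) / 100.0 < 0.02

    def test_static_noiseless_spot(self):
        cfg = SimulationConfig(
            field_shape=(64, 64), n_frames=10, n_spots=1, shot_noise=False,
            read_noise_sd=0.0, spot_amplitude_cv=0.0, background_level=5.0,
        )
        ev = [GroundTruthEvent(0, 32, 32, "none", None)]
        movie = render_movie(cfg, [(32, 32)], ev, seed=0)
        assert np.array_equal(movie.data[0], movie.data[5])
        integrated = movie.data[0].sum() - 5.0 * 64 * 64
        assert integrated == pytest.approx(cfg.spot_amplitude_mean, rel=1e-4)

    def test_drop_renders_as_perfect_step(self):
        cfg = SimulationConfig(
            field_shape=(64, 64), n_frames=30, n_spots=1, shot_noise=False,
            read_noise_sd=0.0, spot_amplitude_cv=0.0, residual_fraction=0.0,
            background_level=5.0,
        )
        ev = [GroundTruthEvent(0, 32, 32, "drop", 12)]
        movie = render_movie(cfg, [(32, 32)], ev, seed=0)
        roi = movie.data[:, 27:38, 27:38].sum(axis=(1, 2)) - 5.0 * 11 * 11
        assert np.allclose(roi[:12], roi[0]) and roi[0] > 1000
        assert np.allclose(roi[12:], 0.0, atol=1e-3)

    def test_residual_fraction_scales_post_event_intensity(self):
        cfg = SimulationConfig(
            field_shape=(64, 64), n_frames=20, n_spots=1, shot_noise=False,
            read_noise_sd=0.0, spot_amplitude_cv=0.0, residual_fraction=0.4,
            background_level=0.0,
        )
        ev = [GroundTruthEvent(0, 32, 32, "drop", 10)]
        movie = render_movie(cfg, [(32, 32)], ev, seed=0)
        before, after = movie.data[0].sum(), movie.data[-1].sum()
        assert after == pytest.approx(0.4 * before, rel=1e-6)

    def test_mismatched_positions_and_events_raise(self, small_config):
        with pytest.raises(ValueError):
            render_movie(small_config, [(10, 10)], [], seed=0)


class TestReproducibility:
    def test_same_seed_bitwise_identical(self, small_config):
        m1, e1 = simulate_movie(small_config)
        m2, e2 = simulate_movie(small_config)
        assert np.array_equal(m1.data, m2.data)
        assert e1 == e2

    def test_different_seed_differs(self, small_config):
        m1, _ = simulate_movie(small_config)
        m2, _ = simulate_movie(dataclasses.replace(small_config, seed=43))
        assert not np.array_equal(m1.data, m2.data)

    def test_noiseless_rendering_matches_analytic_forward_model(self):
        cfg = SimulationConfig(
            field_shape=(48, 48), n_frames=4, shot_noise=False, read_noise_sd=0.0,
            spot_amplitude_cv=0.0, background_level=10.0,
        )
        pos = [(20, 24)]
        ev = [GroundTruthEvent(0, 20, 24, "none", None)]
        movie = render_movie(cfg, pos, ev, seed=0)
        yy, xx = np.mgrid[0:48, 0:48]
        sig = cfg.psf_sigma
        expected = 10.0 + cfg.spot_amplitude_mean / (2 * np.pi * sig**2) * np.exp(
            -((yy - 24.0) ** 2 + (xx - 20.0) ** 2) / (2 * sig**2)
        )
        # analytic model exact up to the float32 render buffer
        assert np.allclose(movie.data[0], expected, rtol=1e-5, atol=1e-3)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"drop_probability": 1.5},
            {"residual_fraction": 0.8},
            {"n_frames": 0},
            {"photobleach_rate": -1.0},
            {"field_shape": (0, 64)},
            {"event_onset": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
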