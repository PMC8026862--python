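"""Kalman filter, fixed-lag smoother and tracker behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piprtrack import (
    KalmanConfig,
    PupilState,
    RenderConfig,
    SeedPoint,
    TrajectoryParams,
    Tracker,
    render_video,
    synthesize_trajectory,
    track,
)
from piprtrack.core import InitializationError, InvalidParameterError
from piprtrack.kalman import FilterStep, fixed_lag_smooth, predict, update

from oracles import riccati_steady_state, textbook_filter, textbook_rts

CFG = KalmanConfig()
I3 = np.eye(3)


def run_filter(zs, cfg=CFG, x0=None, p0=None):
    """Run predict/update over a measurement sequence, keeping history."""
    zs = np.asarray(zs, dtype=float)
    state = PupilState(zs[0] if x0 is None else x0,
                       (cfg.init_var if p0 is None else p0) * I3)
    steps = [FilterStep(state, state)]
    for z in zs[1:]:
        prior = predict(state, cfg)
        state = update(prior, z, cfg)
        steps.append(FilterStep(state, prior))
    return steps


class TestPredictUpdate:
    def test_predict_adds_isotropic_process_noise(self):
        p = np.diag([0.5, 1.0, 2.0])
        state = PupilState([100.0, 100.0, 40.0], p)
        out = predict(state, CFG)
        assert np.array_equal(out.mean, state.mean)
        assert np.allclose(out.cov, p + 2e-4 * I3)

    def test_zero_q_leaves_covariance_unchanged(self):
        state = PupilState([0.0, 0.0, 10.0], I3)
        out = predict(state, KalmanConfig(process_noise_q=0.0))
        assert np.array_equal(out.cov, I3)

    def test_two_predicts_equal_one_with_double_q(self):
        state = PupilState([0.0, 0.0, 10.0], I3)
        twice = predict(predict(state, CFG), CFG)
        once = predict(state, KalmanConfig(process_noise_q=4e-4))
        assert np.allclose(twice.cov, once.cov)

    def test_uninformative_prior_posterior_tracks_measurement(self):
        state = PupilState([0.0, 0.0, 10.0], 1e12 * I3)
        z = [5.0, -3.0, 42.0]
        out = update(state, z, CFG)
        assert np.allclose(out.mean, z, atol=1e-6)

    def test_huge_r_posterior_tracks_prior(self):
        state = PupilState([5.0, 5.0, 40.0], I3)
        out = update(state, [100.0, 100.0, 80.0], KalmanConfig(observation_noise_r=1e12))
        assert np.allclose(out.mean, state.mean, atol=1e-6)

    def test_nonfinite_measurement_rejected(self):
        state = PupilState([0.0, 0.0, 10.0], I3)
        with pytest.raises(InvalidParameterError):
            update(state, [np.nan, 0.0, 1.0], CFG)

    def test_steady_state_matches_riccati_closed_form(self):
        """Iterated predict/update with Q=0.0002, R=1 converges to the
        closed-form posterior variance and gain (~0.0140)."""
        p_star, k_star = riccati_steady_state(2e-4, 1.0)
        assert p_star == pytest.approx(0.014042489, abs=1e-9)
        state = PupilState([0.0, 0.0, 40.0], 1.0 * I3)
        for _ in range(2000):
            prior = predict(state, CFG)
            state = update(prior, [0.0, 0.0, 40.0], CFG)
        assert np.allclose(np.diag(state.cov), p_star, atol=1e-9)
        # empirical gain: response of the mean to a unit innovation
        prior = predict(state, CFG)
        bumped = update(prior, [1.0, 0.0, 40.0], CFG)
        assert bumped.mean[0] == pytest.approx(k_star, abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_covariance_stays_symmetric_psd_and_contracts(self, seed):
        rng = np.random.default_rng(seed)
        zs = rng.normal([100, 100, 40], 5.0, size=(20, 3))
        state = PupilState(zs[0], CFG.init_var * I3)
        for z in zs[1:]:
            prior = predict(state, CFG)
            state = update(prior, z, CFG)
            assert np.allclose(state.cov, state.cov.T, atol=1e-12)
            assert np.min(np.linalg.eigvalsh(state.cov)) >= -1e-12
            assert np.trace(state.cov) <= np.trace(prior.cov) + 1e-12


class TestFixedLagSmoother:
    def test_lag_zero_returns_filtered(self):
        steps = run_filter(np.random.default_rng(0).normal(size=(10, 3)))
        out, ok = fixed_lag_smooth(steps, KalmanConfig(lag_n=0))
        assert ok
        assert np.array_equal(out.mean, steps[-1].filtered.mean)

    def test_insufficient_history_flagged(self):
        steps = run_filter(np.zeros((3, 3)))
        out, ok = fixed_lag_smooth(steps, KalmanConfig(lag_n=4))
        assert not ok
        assert np.array_equal(out.mean, steps[0].filtered.mean)

    def test_constant_measurements_steady_state(self):
        z = np.tile([50.0, 60.0, 30.0], (300, 1))
        steps = run_filter(z)
        out, ok = fixed_lag_smooth(steps, CFG)
        assert ok
        assert np.allclose(out.mean, z[0], atol=1e-9)

    def test_matches_fixed_interval_smoother_on_all_prefixes(self):
        """Lag-4 smoothed estimate equals the full fixed-interval smoother
        at t-4 on every prefix of a 50-frame sequence (textbook oracle)."""
        rng = np.random.default_rng(3)
        zs = np.cumsum(rng.normal(0, 0.3, size=(50, 3)), axis=0) + [100, 100, 40]
        steps = run_filter(zs)
        n = CFG.lag_n
        for T in range(n + 1, 51):
            ours, ok = fixed_lag_smooth(steps[:T], CFG)
            assert ok
            xf, pf, xp, pp = textbook_filter(zs[:T], 2e-4, 1.0, zs[0], CFG.init_var)
            xs, ps = textbook_rts(xf, pf, xp, pp)
            assert np.allclose(ours.mean, xs[T - 1 - n], atol=1e-10)
            assert np.allclose(ours.cov, ps[T - 1 - n], atol=1e-10)

    def test_smoothed_variance_not_above_filtered(self):
        rng = np.random.default_rng(8)
        zs = rng.normal([100, 100, 40], 2.0, size=(30, 3))
        steps = run_filter(zs)
        for T in range(CFG.lag_n + 1, 31):
            smoothed, _ = fixed_lag_smooth(steps[:T], CFG)
            filtered = steps[T - 1 - CFG.lag_n].filtered
            assert np.trace(smoothed.cov) <= np.trace(filtered.cov) + 1e-12


class TestTracker:
    def test_constant_radius_video(self, constant_trial, frame_center):
        truth, render, frames = constant_trial
        trace = track(frames, frame_center, px_per_mm=render.px_per_mm)
        # true diameter 5.6 mm * 15 px/mm = 84 px
        assert np.all(np.abs(trace.diameter_px[5:] - 84.0) < 0.5)
        assert trace.measurement_used.all()
        assert not trace.blink_flag.any()

    def test_filter_matches_textbook_reference_on_the_same_measurements(
        self, constant_trial, frame_center
    ):
        """With gating disabled and the identical measurement stream, the
        tracker's filtered states equal the textbook implementation to
        1e-10."""
        from piprtrack.segment import DetectConfig, detect_pupil

        truth, render, frames = constant_trial
        tracker = Tracker(frames, frame_center, px_per_mm=render.px_per_mm)
        tracker.run()
        filtered = np.array([s.filtered.mean for s in tracker._steps])
        # reconstruct the measurement stream the tracker saw
        zs = [filtered[0]]
        for k in range(1, len(frames)):
            seed = tracker._clipped_seed(*tracker._steps[k].predicted.mean[:2])
            fit, _ = detect_pupil(frames[k], seed, DetectConfig())
            zs.append([fit.center_x_px, fit.center_y_px, fit.mean_radius_px])
        xf, _, _, _ = textbook_filter(np.array(zs), CFG.process_noise_q,
                                      CFG.observation_noise_r, zs[0], CFG.init_var)
        assert np.allclose(filtered, xf, atol=1e-10)

    def test_blink_bridged_without_excursion(self, frame_center):
        params = TrajectoryParams(
            phasic_amplitude_mm=0.0, sustained_amplitude_mm=0.0,
            noise_sd_mm=0.0, drift_sd_mm=0.0,
            blink_times_s=(1.0,), blink_duration_s=0.2, trial_duration_s=3.0,
            seed=13,
        )
        truth = synthesize_trajectory(params, 30.0)
        frames = render_video(truth, RenderConfig(pixel_noise_sd=0.0, center_jitter_px_sd=0.0))
        trace = track(frames, frame_center, px_per_mm=15.0)
        blink_idx = np.where(truth.blink_mask)[0]
        assert not trace.measurement_used[blink_idx].any()
        assert trace.blink_flag[blink_idx].all()
        # continuity: no step anywhere exceeds 3x the largest non-blink step
        steps = np.abs(np.diff(trace.diameter_px))
        open_steps = steps[~truth.blink_mask[1:]]
        assert steps.max() <= max(3.0 * open_steps.max(), 1e-6)

    def test_intensity_scale_invariance(self, constant_trial, frame_center):
        """Gradient-based detection makes the trace invariant to uniform
        intensity scaling (within 0.1 px)."""
        from piprtrack.core import FrameSequence

        truth, render, frames = constant_trial
        scaled = FrameSequence(
            frames.frames * 0.7, frames.frame_rate_hz, frames.timestamps_s
        )
        a = track(frames, frame_center)
        b = track(scaled, frame_center)
        assert np.max(np.abs(a.diameter_px - b.diameter_px)) < 0.1

    def test_initialization_failure_raises(self):
        from piprtrack.core import FrameSequence

        uniform = FrameSequence.from_frames(np.full((5, 64, 64), 0.3), 30.0)
        with pytest.raises(InitializationError):
            track(uniform, SeedPoint(32, 32))

    def test_pipr_shaped_recovery(self, frame_center):
        """Rendered PIPR trial tracked at default settings: the published
        filter constants smooth heavily (gain ~0.014), so the tracked
        diameter lags fast constriction; RMSE stays within the
        lag-dominated envelope measured for this geometry."""
        params = TrajectoryParams(sustained_amplitude_mm=0.9, seed=17)
        truth = synthesize_trajectory(params, 30.0)
        cfg = RenderConfig()
        frames = render_video(truth, cfg)
        trace = track(frames, frame_center, px_per_mm=cfg.px_per_mm)
        rmse = np.sqrt(np.mean((trace.diameter_mm - truth.diameter_mm) ** 2))
        assert rmse < 0.4


class TestCorrections:
    def test_correction_equal_to_estimate_is_transparent(self, constant_trial, frame_center):
        truth, render, frames = constant_trial
        tracker = Tracker(frames, frame_center, px_per_mm=render.px_per_mm)
        base = tracker.run()
        k = 20
        existing = tuple(tracker._steps[k].filtered.mean)
        corrected = tracker.apply_correction(k, existing)
        assert np.allclose(
            corrected.diameter_px[-1], base.diameter_px[-1], atol=1e-6
        )
        # earlier samples untouched
        assert np.array_equal(corrected.diameter_px[:k], base.diameter_px[:k])

    def test_correction_repairs_a_corrupted_state(self, constant_trial, frame_center):
        truth, render, frames = constant_trial
        tracker = Tracker(frames, frame_center, px_per_mm=render.px_per_mm)
        base = tracker.run()
        true_d = truth.diameter_mm * render.px_per_mm
        rmse_clean = np.sqrt(np.mean((base.diameter_px[10:] - true_d[10:]) ** 2))
        k = 15
        tracker.apply_correction(k, (63.5, 63.5, 10.0))  # corrupt
        repaired = tracker.apply_correction(k, (63.5, 63.5, base.diameter_px[k] / 2.0))
        rmse_rep = np.sqrt(np.mean((repaired.diameter_px[10:] - true_d[10:]) ** 2))
        assert rmse_rep <= 1.1 * rmse_clean + 1e-9

    def test_correction_at_frame_zero_reinitializes(self, constant_trial, frame_center):
        truth, render, frames = constant_trial
        t1 = Tracker(frames, frame_center, px_per_mm=render.px_per_mm)
        base = t1.run()
        init = tuple(t1._steps[0].filtered.mean)
        redone = t1.apply_correction(0, init)
        assert np.allclose(redone.diameter_px, base.diameter_px, atol=1e-12)

    def test_out_of_range_correction_rejected(self, constant_trial, frame_center):
        truth, render, frames = constant_trial
        tracker = Tracker(frames, frame_center, px_per_mm=render.px_per_mm)
        tracker.run()
        with pytest.raises(InvalidParameterError):
            tracker.apply_correction(10_000, (0.0, 0.0, 10.0))
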