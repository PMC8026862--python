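"""Frame-to-frame pupil tracking: Kalman filter with fixed-lag smoothing.

The state is the pupil centre and radius, ``(x_c, y_c, r)`` in pixels.
Because the pupil evolves slowly relative to the frame rate, the transition
model is a random walk (identity dynamics) with isotropic process noise
``Q * I3``; each frame's segmentation supplies a direct observation of all
three states with noise ``R * I3``.  Estimates are reported after fixed-lag
smoothing with lag ``N`` (the smoothed state at ``t - N`` uses observations
up to ``t``), implemented as a backward Rauch-Tung-Striebel recursion over
the lag window, which for identity dynamics equals the fixed-interval
smoother restricted to that window.

Measurements are gated: frames whose detection quality falls below
``gate_quality`` (blinks, occlusions) are flagged and bridged by the
prediction; an optional innovation gate rejects gross outliers.  A manual
correction API resets the state at any processed frame and re-runs the
filter forward, mirroring an operator fixing a bad fit and re-automating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    FrameSequence,
    InitializationError,
    InvalidParameterError,
    PupilTrace,
    SeedPoint,
)
from .segment import DetectConfig, detect_pupil

__all__ = [
    "KalmanConfig",
    "PupilState",
    "FilterStep",
    "predict",
    "update",
    "fixed_lag_smooth",
    "Tracker",
    "track",
]

_I3 = np.eye(3)


@dataclass(frozen=True)
class KalmanConfig:
    """Filter constants.

    ``process_noise_q`` and ``observation_noise_r`` are scalar spectral
    levels applied isotropically (units: px^2 per frame and px^2); the
    defaults are the constants of the clinical system this package
    re-implements.  ``gate_innovation_sd`` is the maximum per-component
    innovation in units of its predicted standard deviation; ``None``
    disables the gate (with the default Q/R the innovation statistic is
    dominated by model lag during fast constriction, so a tight gate would
    starve the filter — see the methods note).
    """

    process_noise_q: float = 2e-4
    observation_noise_r: float = 1.0
    lag_n: int = 4
    gate_quality: float = 0.5
    gate_innovation_sd: float | None = None
    init_var: float = 1.0

    def validate(self) -> None:
        if self.process_noise_q < 0 or self.observation_noise_r <= 0:
            raise InvalidParameterError("Q must be >= 0 and R > 0")
        if self.lag_n < 0:
            raise InvalidParameterError("lag_n must be non-negative")
        if not 0.0 <= self.gate_quality <= 1.0:
            raise InvalidParameterError("gate_quality must lie in [0, 1]")
        if self.init_var <= 0:
            raise InvalidParameterError("init_var must be positive")


@dataclass
class PupilState:
    """Gaussian belief over (x_c, y_c, r): mean and 3x3 covariance."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        self.cov = np.asarray(self.cov, dtype=float).reshape(3, 3)
        if not np.allclose(self.cov, self.cov.T, atol=1e-9):
            raise InvalidParameterError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.cov)) < -1e-9:
            raise InvalidParameterError("covariance must be PSD")

    @property
    def radius_px(self) -> float:
        return float(self.mean[2])


@dataclass
class FilterStep:
    """Filtered posterior and one-step prior stored for one frame."""

    filtered: PupilState
    predicted: PupilState  # prior at this index (before the update)


def predict(state: PupilState, config: KalmanConfig = KalmanConfig()) -> PupilState:
    """Random-walk time update: mean unchanged, covariance grows by Q*I."""
    return PupilState(
        mean=state.mean.copy(),
        cov=state.cov + config.process_noise_q * _I3,
    )


def update(
    state: PupilState,
    measurement: np.ndarray,
    config: KalmanConfig = KalmanConfig(),
) -> PupilState:
    """Measurement update with direct observation of all three states."""
    z = np.asarray(measurement, dtype=float).reshape(3)
    if not np.all(np.isfinite(z)):
        raise InvalidParameterError("measurement must be finite")
    r_cov = config.observation_noise_r * _I3
    s = state.cov + r_cov
    gain = state.cov @ np.linalg.inv(s)
    mean = state.mean + gain @ (z - state.mean)
    a = _I3 - gain
    cov = a @ state.cov @ a.T + gain @ r_cov @ gain.T  # Joseph form
    cov = 0.5 * (cov + cov.T)
    return PupilState(mean=mean, cov=cov)


def fixed_lag_smooth(
    history: list[FilterStep],
    config: KalmanConfig = KalmanConfig(),
) -> tuple[PupilState, bool]:
    """Smoothed state ``lag_n`` frames in the past given the stored window.

    Runs the backward recursion over the last ``lag_n + 1`` entries of
    ``history`` and returns the smoothed state at index ``len - 1 - lag_n``
    together with a flag; with fewer than ``lag_n + 1`` entries the oldest
    filtered estimate is returned unchanged and flagged as unsmoothed.
    """
    if len(history) == 0:
        raise InvalidParameterError("history must be non-empty")
    n = config.lag_n
    if n == 0:
        return history[-1].filtered, True
    if len(history) < n + 1:
        return history[0].filtered, False
    window = history[-(n + 1):]
    return _smooth_window(window), True


def _smooth_window(window: list[FilterStep]) -> PupilState:
    """Backward RTS pass (identity dynamics) returning the state at the
    start of the window given all observations inside it."""
    xs = window[-1].filtered.mean.copy()
    ps = window[-1].filtered.cov.copy()
    for j in range(len(window) - 2, -1, -1):
        pred_next = window[j + 1].predicted
        filt = window[j].filtered
        c = filt.cov @ np.linalg.inv(pred_next.cov)
        xs = filt.mean + c @ (xs - pred_next.mean)
        ps = filt.cov + c @ (ps - pred_next.cov) @ c.T
        ps = 0.5 * (ps + ps.T)
    return PupilState(mean=xs, cov=ps)


class Tracker:
    """Stateful tracking session over a frame sequence.

    Keeps the per-frame filter history so that an operator correction at any
    processed frame can reset the state there and re-run the automated
    filtering/smoothing forward (earlier samples are left untouched).
    """

    def __init__(
        self,
        frames: FrameSequence,
        seed: SeedPoint,
        detect_config: DetectConfig = DetectConfig(),
        kalman_config: KalmanConfig = KalmanConfig(),
        px_per_mm: float | None = None,
    ) -> None:
        kalman_config.validate()
        self.frames = frames
        self.seed = seed
        self.detect_config = detect_config
        self.config = kalman_config
        self.px_per_mm = px_per_mm
        n = len(frames)
        self._steps: list[FilterStep | None] = [None] * n
        self._used = np.zeros(n, dtype=bool)
        self._blink = np.zeros(n, dtype=bool)
        self._smoothed = np.zeros((n, 3))
        self._ran = False

    # -- filtering ---------------------------------------------------------

    def _clipped_seed(self, x: float, y: float) -> SeedPoint:
        h, w = self.frames.shape
        return SeedPoint(
            x_px=float(np.clip(x, 1.0, w - 2.0)),
            y_px=float(np.clip(y, 1.0, h - 2.0)),
        )

    def _init_state(self) -> None:
        fit, q = detect_pupil(self.frames[0], self.seed, self.detect_config)
        if fit is None or q <= 0.0:
            raise InitializationError(
                "no pupil edge found at the seeded frame; choose another seed"
            )
        state = PupilState(
            mean=np.array([fit.center_x_px, fit.center_y_px, fit.mean_radius_px]),
            cov=self.config.init_var * _I3,
        )
        self._steps[0] = FilterStep(filtered=state, predicted=state)
        self._used[0] = True
        self._blink[0] = q < self.config.gate_quality

    def _filter_frame(self, k: int) -> None:
        prev = self._steps[k - 1]
        assert prev is not None
        prior = predict(prev.filtered, self.config)
        seed_k = self._clipped_seed(prior.mean[0], prior.mean[1])
        fit, q = detect_pupil(self.frames[k], seed_k, self.detect_config)
        blink = fit is None or q < self.config.gate_quality
        accept = not blink
        if accept and self.config.gate_innovation_sd is not None:
            z = np.array([fit.center_x_px, fit.center_y_px, fit.mean_radius_px])
            s_diag = np.diag(prior.cov) + self.config.observation_noise_r
            norm_innov = np.abs(z - prior.mean) / np.sqrt(s_diag)
            if np.max(norm_innov) > self.config.gate_innovation_sd:
                accept = False
        if accept:
            z = np.array([fit.center_x_px, fit.center_y_px, fit.mean_radius_px])
            filtered = update(prior, z, self.config)
        else:
            filtered = prior
        self._steps[k] = FilterStep(filtered=filtered, predicted=prior)
        self._used[k] = accept
        self._blink[k] = blink

    def _smooth_index(self, k: int) -> np.ndarray:
        """Fixed-lag smoothed mean at frame k (observations up to k + N,
        truncated at the end of the sequence)."""
        n = len(self.frames)
        end = min(k + self.config.lag_n, n - 1)
        window = [self._steps[j] for j in range(k, end + 1)]
        return _smooth_window(window).mean

    def _run_from(self, start: int) -> None:
        n = len(self.frames)
        if start == 0:
            self._init_state()
            start = 1
        for k in range(start, n):
            self._filter_frame(k)

    def run(self) -> PupilTrace:
        """Track every frame and return the smoothed trace."""
        self._run_from(0)
        for k in range(len(self.frames)):
            self._smoothed[k] = self._smooth_index(k)
        self._ran = True
        return self._make_trace()

    def apply_correction(
        self, frame_index: int, corrected: tuple[float, float, float]
    ) -> PupilTrace:
        """Replace the estimate at ``frame_index`` and re-automate forward.

        The state mean is set to the correction, its covariance reset to the
        initialisation covariance, and filtering plus smoothing re-run from
        that frame on; samples before ``frame_index`` are unchanged.
        """
        if not self._ran:
            raise InvalidParameterError("run() must be called before corrections")
        n = len(self.frames)
        if not 0 <= frame_index < n:
            raise InvalidParameterError(f"frame_index {frame_index} out of range")
        state = PupilState(
            mean=np.asarray(corrected, dtype=float),
            cov=self.config.init_var * _I3,
        )
        self._steps[frame_index] = FilterStep(filtered=state, predicted=state)
        self._used[frame_index] = True
        self._blink[frame_index] = False
        for k in range(frame_index + 1, n):
            self._filter_frame(k)
        for k in range(frame_index, n):
            self._smoothed[k] = self._smooth_index(k)
        return self._make_trace()

    def _make_trace(self) -> PupilTrace:
        return PupilTrace(
            times_s=self.frames.timestamps_s.copy(),
            diameter_px=2.0 * self._smoothed[:, 2],
            center_x_px=self._smoothed[:, 0],
            center_y_px=self._smoothed[:, 1],
            measurement_used=self._used.copy(),
            blink_flag=self._blink.copy(),
            calibration_px_per_mm=self.px_per_mm,
        )


def track(
    frames: FrameSequence,
    seed: SeedPoint,
    detect_config: DetectConfig = DetectConfig(),
    kalman_config: KalmanConfig = KalmanConfig(),
    px_per_mm: float | None = None,
) -> PupilTrace:
    """Track a frame sequence end-to-end and return the smoothed trace."""
    return Tracker(frames, seed, detect_config, kalman_config, px_per_mm).run()
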