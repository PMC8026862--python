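"""Shared data containers and exceptions.

Coordinate convention (used everywhere in the package): ``x`` is the column
index, ``y`` the row index, origin at the centre of the top-left pixel,
0-based; angles are measured from the +x axis, counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PiprTrackError",
    "InvalidParameterError",
    "NoEdgeError",
    "InsufficientPointsError",
    "EllipseFitError",
    "NoDataError",
    "UndefinedCorrelationError",
    "TraceFormatError",
    "InitializationError",
    "SeedPoint",
    "FrameSequence",
    "EllipseFit",
    "PupilTrace",
]


class PiprTrackError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(PiprTrackError, ValueError):
    """A parameter or input violates its documented constraints."""


class NoEdgeError(PiprTrackError):
    """No accepted edge point is available where at least one is required."""


class InsufficientPointsError(PiprTrackError):
    """Fewer points than the fitted model requires (a conic needs five)."""


class EllipseFitError(PiprTrackError):
    """The conic fit is degenerate or does not describe an ellipse."""


class NoDataError(PiprTrackError):
    """An analysis window or trial set contains no usable samples."""


class UndefinedCorrelationError(PiprTrackError):
    """Correlation requested for a zero-variance input."""


class TraceFormatError(PiprTrackError, ValueError):
    """A trace file does not match the expected schema."""


class InitializationError(PiprTrackError):
    """Tracking could not start (no pupil edge at the seeded frame)."""


@dataclass(frozen=True)
class SeedPoint:
    """A user-supplied point strictly inside the pupil."""

    x_px: float
    y_px: float

    def require_inside(self, height: int, width: int) -> None:
        if not (0 <= self.x_px <= width - 1 and 0 <= self.y_px <= height - 1):
            raise InvalidParameterError(
                f"seed ({self.x_px}, {self.y_px}) outside a "
                f"{height}x{width} frame"
            )


@dataclass
class FrameSequence:
    """Ordered grayscale frames with a uniform sampling clock.

    ``frames`` is an ``(n, h, w)`` float array with intensities in [0, 1].
    """

    frames: np.ndarray
    frame_rate_hz: float
    timestamps_s: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a (n, h, w) array")
        if self.frame_rate_hz <= 0:
            raise InvalidParameterError("frame_rate_hz must be positive")
        if len(self.timestamps_s) != len(self.frames):
            raise InvalidParameterError("one timestamp per frame required")
        if len(self.timestamps_s) > 1:
            expected = self.timestamps_s[0] + np.arange(len(self.frames)) / self.frame_rate_hz
            if np.max(np.abs(self.timestamps_s - expected)) > 1e-6:
                raise InvalidParameterError(
                    "timestamps inconsistent with frame rate (>1e-6 s)"
                )

    @classmethod
    def from_frames(
        cls, frames: Sequence[np.ndarray] | np.ndarray, frame_rate_hz: float
    ) -> "FrameSequence":
        arr = np.asarray(frames, dtype=float)
        ts = np.arange(len(arr)) / frame_rate_hz
        return cls(frames=arr, frame_rate_hz=frame_rate_hz, timestamps_s=ts)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class EllipseFit:
    """Geometric ellipse parameters of the pupil boundary in one frame."""

    center_x_px: float
    center_y_px: float
    semi_major_px: float
    semi_minor_px: float
    orientation_rad: float

    def __post_init__(self) -> None:
        if self.semi_minor_px <= 0:
            raise EllipseFitError("semi-minor axis must be positive")
        if self.semi_major_px < self.semi_minor_px:
            raise EllipseFitError("semi-major axis smaller than semi-minor")

    @property
    def mean_radius_px(self) -> float:
        return 0.5 * (self.semi_major_px + self.semi_minor_px)


@dataclass
class PupilTrace:
    """Time series of tracked pupil diameter with per-sample flags.

    ``diameter_px`` holds the tracked diameter in pixels;
    ``calibration_px_per_mm`` converts to millimetres (a calibration of 1.0
    means the series is already in mm, as for purely synthetic traces).
    ``measurement_used`` is False where the tracker propagated its prediction
    instead of accepting a measurement; ``blink_flag`` marks frames whose
    detection quality fell below the blink threshold.
    """

    times_s: np.ndarray
    diameter_px: np.ndarray
    center_x_px: np.ndarray
    center_y_px: np.ndarray
    measurement_used: np.ndarray
    blink_flag: np.ndarray
    calibration_px_per_mm: float | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.diameter_px = np.asarray(self.diameter_px, dtype=float)
        self.center_x_px = np.asarray(self.center_x_px, dtype=float)
        self.center_y_px = np.asarray(self.center_y_px, dtype=float)
        self.measurement_used = np.asarray(self.measurement_used, dtype=bool)
        self.blink_flag = np.asarray(self.blink_flag, dtype=bool)
        n = len(self.times_s)
        for name in ("diameter_px", "center_x_px", "center_y_px",
                     "measurement_used", "blink_flag"):
            if len(getattr(self, name)) != n:
                raise InvalidParameterError(f"{name} length differs from times_s")
        if n > 1 and np.any(np.diff(self.times_s) <= 0):
            raise InvalidParameterError("times_s must be strictly increasing")
        if self.calibration_px_per_mm is not None and self.calibration_px_per_mm <= 0:
            raise InvalidParameterError("calibration_px_per_mm must be positive")

    @property
    def diameter_mm(self) -> np.ndarray:
        if self.calibration_px_per_mm is None:
            raise InvalidParameterError(
                "trace has no pixel-to-mm calibration; set calibration_px_per_mm"
            )
        return self.diameter_px / self.calibration_px_per_mm

    @classmethod
    def from_mm(
        cls,
        times_s: np.ndarray,
        diameter_mm: np.ndarray,
        blink_flag: np.ndarray | None = None,
    ) -> "PupilTrace":
        """Build a trace directly from a diameter series in millimetres."""
        times_s = np.asarray(times_s, dtype=float)
        d = np.asarray(diameter_mm, dtype=float)
        n = len(times_s)
        if blink_flag is None:
            blink_flag = np.zeros(n, dtype=bool)
        return cls(
            times_s=times_s,
            diameter_px=d,
            center_x_px=np.zeros(n),
            center_y_px=np.zeros(n),
            measurement_used=~np.asarray(blink_flag, dtype=bool),
            blink_flag=blink_flag,
            calibration_px_per_mm=1.0,
        )

    def __len__(self) -> int:
        return len(self.times_s)
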