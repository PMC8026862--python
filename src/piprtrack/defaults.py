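"""Protocol and pipeline constants, collected in one place.

The values mirror the clinical acquisition and analysis protocol this
package re-implements; each constant notes what it means physically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .core import InvalidParameterError
from .kalman import KalmanConfig
from .segment import DetectConfig

__all__ = [
    "FRAME_RATE_HZ",
    "PRE_WINDOW_S",
    "STIM_DURATION_S",
    "POST_WINDOW_S",
    "TRIAL_DURATION_S",
    "BASELINE_LO_MM",
    "BASELINE_HI_MM",
    "BLINK_FRACTION_MAX",
    "RunConfig",
]

FRAME_RATE_HZ = 30.0        # video sampling rate of the acquisition camera
PRE_WINDOW_S = 5.0          # pre-stimulus baseline averaging window
STIM_DURATION_S = 5.0       # light-pulse duration
POST_WINDOW_S = 30.0        # post-stimulus averaging window
TRIAL_DURATION_S = 40.0     # 5 s baseline + 5 s stimulus + 30 s recovery
BASELINE_LO_MM = 5.5        # inclusion band for the pre-stimulus diameter
BASELINE_HI_MM = 5.7        # (closed interval; baseline confounds PIPR)
BLINK_FRACTION_MAX = 0.1    # trials with more flagged frames are discarded


@dataclass
class RunConfig:
    """Aggregate configuration for the simulate -> track -> analyze chain."""

    detect: DetectConfig = field(default_factory=DetectConfig)
    kalman: KalmanConfig = field(default_factory=KalmanConfig)
    frame_rate_hz: float = FRAME_RATE_HZ
    pre_window_s: float = PRE_WINDOW_S
    post_window_s: float = POST_WINDOW_S
    post_anchor: str = "offset"
    baseline_lo_mm: float = BASELINE_LO_MM
    baseline_hi_mm: float = BASELINE_HI_MM
    blink_fraction_max: float = BLINK_FRACTION_MAX
    equal_var: bool = True              # pooled-variance t-test (Welch if False)
    calibration_px_per_mm: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detect"] = asdict(self.detect)
        d["kalman"] = asdict(self.kalman)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "detect" in d:
            d["detect"] = DetectConfig(**d["detect"])
        if "kalman" in d:
            d["kalman"] = KalmanConfig(**d["kalman"])
        return cls(**d)
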