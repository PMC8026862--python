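"""Synthetic pupil trials: ground-truth trajectories and rendered eye videos.

The trajectory model is a baseline diameter minus two stimulus-locked
constriction components:

* a *phasic* component shared by all wavelengths — rises exponentially during
  the stimulus (time constant ``constriction_tau_s``) and redilates with
  ``recovery_tau_s`` after stimulus offset;
* a *sustained* component carrying the melanopsin-driven post-illumination
  response — rises during the stimulus and decays slowly
  (``sustained_tau_s``) after offset.  Setting its amplitude to zero emulates
  long-wavelength ("red") trials; a positive amplitude emulates
  short-wavelength ("blue") trials, whose constriction outlasts the stimulus.

On top of the deterministic profile the generator adds white measurement
noise, a smooth integrated-random-walk drift (hippus-like wander), and
eyelid blinks.  Rendering turns a trajectory into grayscale frames: a dark
anti-aliased pupil disk on a brighter iris background with centre jitter and
pixel noise; during blinks an eyelid band occludes the upper part of the
disk.  All randomness derives from the single integer seed in the trajectory
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .core import FrameSequence, InvalidParameterError

__all__ = [
    "TrajectoryParams",
    "GroundTruthTrace",
    "RenderConfig",
    "closed_form_diameter",
    "synthesize_trajectory",
    "render_video",
    "CohortSpec",
    "synthesize_cohort",
]

# Fraction of the pupil radius below the centre row that the eyelid band
# reaches during a blink: eyelids typically close past the pupil midline,
# which also breaks the horizontal detection rays.
_BLINK_OVERHANG = 0.2


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of one synthetic trial (distances in mm, times in s)."""

    baseline_diameter_mm: float = 5.63
    phasic_amplitude_mm: float = 1.4
    sustained_amplitude_mm: float = 0.0
    constriction_tau_s: float = 0.4
    recovery_tau_s: float = 15.0
    sustained_tau_s: float = 20.0
    stim_onset_s: float = 5.0
    stim_offset_s: float = 10.0
    trial_duration_s: float = 40.0
    noise_sd_mm: float = 0.02
    drift_sd_mm: float = 0.05
    blink_times_s: tuple[float, ...] = ()
    blink_duration_s: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_diameter_mm <= 0:
            raise InvalidParameterError("baseline diameter must be positive")
        if self.phasic_amplitude_mm < 0 or self.sustained_amplitude_mm < 0:
            raise InvalidParameterError("amplitudes must be non-negative")
        if self.baseline_diameter_mm <= (
            self.phasic_amplitude_mm + self.sustained_amplitude_mm
        ):
            raise InvalidParameterError(
                "baseline must exceed the sum of constriction amplitudes"
            )
        for name in ("constriction_tau_s", "recovery_tau_s", "sustained_tau_s"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not self.stim_onset_s < self.stim_offset_s:
            raise InvalidParameterError("stimulus onset must precede offset")
        if self.trial_duration_s <= 0:
            raise InvalidParameterError("trial duration must be positive")
        if self.noise_sd_mm < 0 or self.drift_sd_mm < 0:
            raise InvalidParameterError("noise/drift sd must be non-negative")
        if self.blink_duration_s <= 0:
            raise InvalidParameterError("blink duration must be positive")
        for bt in self.blink_times_s:
            if bt < 0 or bt + self.blink_duration_s > self.trial_duration_s:
                raise InvalidParameterError(
                    f"blink at {bt} s extends outside the trial"
                )


@dataclass
class GroundTruthTrace:
    """Sampled ground-truth diameter series for one trial."""

    times_s: np.ndarray
    diameter_mm: np.ndarray
    blink_mask: np.ndarray
    params: TrajectoryParams

    def __post_init__(self) -> None:
        n = len(self.times_s)
        if len(self.diameter_mm) != n or len(self.blink_mask) != n:
            raise InvalidParameterError("trace sequences must share one length")
        if np.any(self.diameter_mm[~self.blink_mask] <= 0):
            raise InvalidParameterError("diameter must stay positive")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass(frozen=True)
class RenderConfig:
    """Rendering geometry and noise for synthetic eye frames."""

    image_width_px: int = 128
    image_height_px: int = 128
    px_per_mm: float = 15.0
    pupil_intensity: float = 0.08
    iris_intensity: float = 0.55
    edge_blur_px: float = 1.0
    pixel_noise_sd: float = 0.02
    center_jitter_px_sd: float = 0.3

    def validate(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise InvalidParameterError("image dimensions must be positive")
        if self.px_per_mm <= 0:
            raise InvalidParameterError("px_per_mm must be positive")
        if not 0 <= self.pupil_intensity < self.iris_intensity <= 1:
            raise InvalidParameterError(
                "need 0 <= pupil_intensity < iris_intensity <= 1"
            )
        if self.edge_blur_px < 0 or self.pixel_noise_sd < 0 or self.center_jitter_px_sd < 0:
            raise InvalidParameterError("blur/noise/jitter must be non-negative")


def _component(
    t: np.ndarray,
    amplitude: float,
    rise_tau: float,
    decay_tau: float,
    onset: float,
    offset: float,
) -> np.ndarray:
    """Exponential saturation during the stimulus, exponential decay after."""
    out = np.zeros_like(t)
    stim = (t >= onset) & (t < offset)
    post = t >= offset
    out[stim] = amplitude * (1.0 - np.exp(-(t[stim] - onset) / rise_tau))
    at_offset = amplitude * (1.0 - math.exp(-(offset - onset) / rise_tau))
    out[post] = at_offset * np.exp(-(t[post] - offset) / decay_tau)
    return out


def closed_form_diameter(params: TrajectoryParams, t: np.ndarray) -> np.ndarray:
    """Noise-free diameter profile D(t) in mm (no drift, no blinks)."""
    t = np.asarray(t, dtype=float)
    phasic = _component(
        t,
        params.phasic_amplitude_mm,
        params.constriction_tau_s,
        params.recovery_tau_s,
        params.stim_onset_s,
        params.stim_offset_s,
    )
    sustained = _component(
        t,
        params.sustained_amplitude_mm,
        params.constriction_tau_s,
        params.sustained_tau_s,
        params.stim_onset_s,
        params.stim_offset_s,
    )
    return params.baseline_diameter_mm - phasic - sustained


def synthesize_trajectory(
    params: TrajectoryParams, frame_rate_hz: float = 30.0
) -> GroundTruthTrace:
    """Sample the trajectory model on a uniform frame grid.

    Deterministic given ``params.seed``: the drift stream is drawn first,
    then the white-noise stream, from a single generator.
    """
    params.validate()
    if frame_rate_hz <= 0:
        raise InvalidParameterError("frame_rate_hz must be positive")
    n = int(round(params.trial_duration_s * frame_rate_hz))
    if n < 1:
        raise InvalidParameterError("trial too short for the given frame rate")
    t = np.arange(n) / frame_rate_hz
    d = closed_form_diameter(params, t)

    rng = np.random.default_rng(params.seed)
    if params.drift_sd_mm > 0 and n > 1:
        walk = np.cumsum(np.cumsum(rng.standard_normal(n)))
        walk -= walk[0]
        scale = walk.std()
        drift = walk * (params.drift_sd_mm / scale) if scale > 0 else np.zeros(n)
    else:
        drift = np.zeros(n)
    noise = rng.normal(0.0, params.noise_sd_mm, n) if params.noise_sd_mm > 0 else np.zeros(n)
    d = d + drift + noise

    blink = np.zeros(n, dtype=bool)
    for bt in params.blink_times_s:
        blink |= (t >= bt) & (t < bt + params.blink_duration_s)
    return GroundTruthTrace(times_s=t, diameter_mm=d, blink_mask=blink, params=params)


def _render_frame(
    radius_px: float,
    center: tuple[float, float],
    xx: np.ndarray,
    yy: np.ndarray,
    cfg: RenderConfig,
    blink: bool,
) -> np.ndarray:
    cx, cy = center
    dist = np.hypot(xx - cx, yy - cy)
    # Normal-CDF edge profile: smooth, with its steepest gradient exactly at
    # the ground-truth radius; width floor 0.5 px keeps the edge resolvable.
    sigma = max(cfg.edge_blur_px, 0.5)
    frame = cfg.pupil_intensity + (cfg.iris_intensity - cfg.pupil_intensity) * ndtr(
        (dist - radius_px) / sigma
    )
    if blink:
        frame[yy <= cy + _BLINK_OVERHANG * radius_px] = cfg.iris_intensity
    return frame


def render_video(trace: GroundTruthTrace, render: RenderConfig) -> FrameSequence:
    """Render a trajectory as grayscale frames (deterministic per seed)."""
    render.validate()
    h, w = render.image_height_px, render.image_width_px
    r_max = float(np.max(trace.diameter_mm)) * render.px_per_mm / 2.0
    margin = 3.0 * render.center_jitter_px_sd + 2.0 * max(render.edge_blur_px, 0.5) + 1.0
    if r_max + margin > min(w - 1, h - 1) / 2.0:
        raise InvalidParameterError(
            f"pupil (radius {r_max:.1f} px + margin {margin:.1f} px) does not "
            f"fit a {h}x{w} frame"
        )
    fps = 1.0 / float(np.diff(trace.times_s).mean()) if len(trace) > 1 else 30.0

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    c0 = ((w - 1) / 2.0, (h - 1) / 2.0)
    rng = np.random.default_rng(np.random.SeedSequence([trace.params.seed, 0x52454E44]))
    jitter = (
        rng.normal(0.0, render.center_jitter_px_sd, size=(len(trace), 2))
        if render.center_jitter_px_sd > 0
        else np.zeros((len(trace), 2))
    )
    frames = np.empty((len(trace), h, w))
    for i in range(len(trace)):
        r_px = trace.diameter_mm[i] * render.px_per_mm / 2.0
        center = (c0[0] + jitter[i, 0], c0[1] + jitter[i, 1])
        frame = _render_frame(r_px, center, xx, yy, render, bool(trace.blink_mask[i]))
        if render.pixel_noise_sd > 0:
            frame = frame + rng.normal(0.0, render.pixel_noise_sd, size=frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)
    return FrameSequence(
        frames=frames,
        frame_rate_hz=fps,
        timestamps_s=np.asarray(trace.times_s, dtype=float),
    )


# ---------------------------------------------------------------------------
# Two-group cohort synthesis
# ---------------------------------------------------------------------------

def _window_deficit_factor(decay_tau: float, window_s: float) -> float:
    """Mean of exp(-t/tau) over [0, window]: converts an offset-time
    constriction amplitude into its average contribution to the
    post-stimulus window."""
    return decay_tau * (1.0 - math.exp(-window_s / decay_tau)) / window_s


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic two-group chromatic-pupillometry
    cohort.

    Group mean PIPRs and between-subject scatter follow the published group
    summaries of the clinical study this package models (19 PD, 10 control;
    blue 470 nm and red 610 nm stimuli at 30 uW; sd = printed SEM * sqrt(n)).
    A subject's red-trial PIPR and net PIPR (blue minus red) are drawn
    independently; blue amplitudes are derived from their sum.
    """

    n_pd: int = 19
    n_control: int = 10
    pipr_red_mm: dict = field(
        default_factory=lambda: {"PD": 0.79, "control": 0.61}
    )
    net_pipr_mm: dict = field(
        default_factory=lambda: {"PD": 0.13, "control": 0.61}
    )
    subject_sd_red_mm: dict = field(
        default_factory=lambda: {"PD": 0.35, "control": 0.22}
    )
    subject_sd_net_mm: dict = field(
        default_factory=lambda: {"PD": 0.35, "control": 0.16}
    )
    baseline_mean_mm: float = 5.63
    baseline_sd_mm: float = 0.04
    n_trials: int = 3
    wavelengths_nm: tuple[float, float] = (470.0, 610.0)
    power_uw: float = 30.0
    pre_stim_s: float = 5.0
    stim_s: float = 5.0
    post_stim_s: float = 30.0
    constriction_tau_s: float = 0.4
    recovery_tau_s: float = 15.0
    sustained_tau_s: float = 20.0
    noise_sd_mm: float = 0.02
    drift_sd_mm: float = 0.05
    blink_rate_per_trial: float = 0.8
    blink_duration_s: float = 0.2


def _subject_params(
    spec: CohortSpec,
    baseline: float,
    pipr_red: float,
    net: float,
    rng: np.random.Generator,
) -> dict[float, TrajectoryParams]:
    """Trajectory parameters per wavelength whose closed-form window PIPRs
    equal the subject's drawn red PIPR and net PIPR."""
    onset = spec.pre_stim_s
    offset = spec.pre_stim_s + spec.stim_s
    duration = offset + spec.post_stim_s
    rise = 1.0 - math.exp(-spec.stim_s / spec.constriction_tau_s)
    f_rec = _window_deficit_factor(spec.recovery_tau_s, spec.post_stim_s)
    f_sus = _window_deficit_factor(spec.sustained_tau_s, spec.post_stim_s)

    pipr_red = max(pipr_red, 0.05)
    ph_off_red = pipr_red / f_rec
    if net >= 0:
        su_off_blue, ph_off_blue = net / f_sus, ph_off_red
    else:
        # paradoxical subject (blue PIPR below red): shrink the blue phasic
        su_off_blue = 0.0
        ph_off_blue = max(ph_off_red + net / f_rec, 0.0)

    out = {}
    for wl in spec.wavelengths_nm:
        blue = wl < 500.0
        ph = (ph_off_blue if blue else ph_off_red) / rise
        su = (su_off_blue if blue else 0.0) / rise
        # the pupil cannot close: cap an extreme draw so at least ~1.5 mm
        # of diameter remains at peak constriction
        total = ph + su
        max_total = baseline - 1.5
        if total > max_total:
            ph *= max_total / total
            su *= max_total / total
        n_blinks = rng.poisson(spec.blink_rate_per_trial)
        blink_times = tuple(
            float(bt)
            for bt in rng.uniform(0.5, duration - spec.blink_duration_s - 0.5, n_blinks)
        )
        out[wl] = TrajectoryParams(
            baseline_diameter_mm=baseline,
            phasic_amplitude_mm=ph,
            sustained_amplitude_mm=su,
            constriction_tau_s=spec.constriction_tau_s,
            recovery_tau_s=spec.recovery_tau_s,
            sustained_tau_s=spec.sustained_tau_s,
            stim_onset_s=onset,
            stim_offset_s=offset,
            trial_duration_s=duration,
            noise_sd_mm=spec.noise_sd_mm,
            drift_sd_mm=spec.drift_sd_mm,
            blink_times_s=blink_times,
            blink_duration_s=spec.blink_duration_s,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return out


def synthesize_cohort(
    spec: CohortSpec = CohortSpec(),
    seed: int = 0,
    frame_rate_hz: float = 30.0,
):
    """Generate a full two-group cohort of ground-truth trials.

    Returns a list of ``piprtrack.stats.SubjectRecord`` with one
    :class:`~piprtrack.core.PupilTrace` per trial (diameters in mm,
    calibration 1.0), ready for the PIPR analysis pipeline.
    """
    from .core import PupilTrace
    from .stats import StimulusMeta, SubjectRecord, Trial

    rng = np.random.default_rng(seed)
    subjects = []
    for group, n in (("PD", spec.n_pd), ("control", spec.n_control)):
        for i in range(n):
            baseline = rng.normal(spec.baseline_mean_mm, spec.baseline_sd_mm)
            pipr_red = rng.normal(
                spec.pipr_red_mm[group], spec.subject_sd_red_mm[group]
            )
            net = rng.normal(spec.net_pipr_mm[group], spec.subject_sd_net_mm[group])
            trials = []
            for _ in range(spec.n_trials):
                by_wl = _subject_params(spec, baseline, pipr_red, net, rng)
                for wl, params in by_wl.items():
                    gt = synthesize_trajectory(params, frame_rate_hz)
                    trace = PupilTrace.from_mm(gt.times_s, gt.diameter_mm, gt.blink_mask)
                    stim = StimulusMeta(
                        wavelength_nm=wl,
                        power_uw=spec.power_uw,
                        stim_onset_s=params.stim_onset_s,
                        stim_offset_s=params.stim_offset_s,
                    )
                    trials.append(Trial(trace=trace, stim=stim, ground_truth=gt))
            subjects.append(
                SubjectRecord(subject_id=f"{group}-{i:03d}", group=group, trials=trials)
            )
    return subjects
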