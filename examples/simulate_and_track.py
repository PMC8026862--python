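"""Simulate one blue-stimulus trial, render it as video, track it back.

Generates a 40-s ground-truth pupil trajectory with a sustained
(melanopsin-like) constriction component, renders it as a grayscale eye
video, runs the radial-gradient detector + Kalman tracker over the frames,
and compares the tracked diameter against the ground truth.
"""

import numpy as np

from piprtrack import (
    RenderConfig,
    SeedPoint,
    StimulusMeta,
    TrajectoryParams,
    compute_pipr,
    render_video,
    synthesize_trajectory,
    track,
)

params = TrajectoryParams(
    baseline_diameter_mm=5.63,
    phasic_amplitude_mm=1.4,
    sustained_amplitude_mm=1.1,   # > 0: a short-wavelength ("blue") trial
    blink_times_s=(12.0, 27.0),
    seed=7,
)
truth = synthesize_trajectory(params, frame_rate_hz=30.0)
render = RenderConfig()  # 128x128 px at 15 px/mm, mild noise and jitter
frames = render_video(truth, render)
print(f"rendered {len(frames)} frames of {frames.shape[0]}x{frames.shape[1]} px")

# the operator's single click inside the pupil seeds the tracker
trace = track(frames, SeedPoint(63.5, 63.5), px_per_mm=render.px_per_mm)

rmse = np.sqrt(np.mean((trace.diameter_mm - truth.diameter_mm) ** 2))
flagged = int(trace.blink_flag.sum())
print(f"tracked diameter RMSE vs ground truth: {rmse:.3f} mm")
print(f"blink frames flagged: {flagged} (truth: {int(truth.blink_mask.sum())})")

stim = StimulusMeta(wavelength_nm=470, power_uw=30, stim_onset_s=5.0, stim_offset_s=10.0)
res = compute_pipr(trace, stim)
print(
    f"PIPR from the tracked trace: pre {res.pre_stim_diameter_mm:.2f} mm, "
    f"post {res.post_stim_diameter_mm:.2f} mm -> PIPR {res.pipr_mm:.2f} mm "
    f"({res.pipr_pct:.1f}% of baseline)"
)
# The RMSE is dominated by the heavy smoothing of the published filter
# constants (gain ~0.014), not by detection error; the 30-s window average
# behind the PIPR is far less sensitive to that lag.
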