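# Methods

This note documents the models, parameters and numerical choices behind
`piprtrack`, and what the synthetic benchmark does and does not show.

## Pupil boundary estimation

Detection starts from a seed point strictly inside the pupil (in the
clinical workflow, one operator click; during tracking, the predicted
centre). Twelve rays leave the seed at angles 2πk/12 (30° spacing,
configurable). Intensity is sampled by bilinear interpolation at 1 px steps
out to 60 px, truncated at the image border, and differentiated by forward
differences; gradient sample *i* is located midway between intensity
samples *i* and *i+1*. The edge candidate on a ray is the sample with the
largest *signed* (dark→bright) gradient — the pupil is the darkest
structure, so signed maxima reject iris→sclera edges that an absolute
gradient would latch onto. A candidate is accepted when its gradient
reaches `min_strength` (default 0.1 intensity/px, calibrated on rendered
fixtures: genuine edges measure ≈ 0.19/px at default contrast and blur,
while gradient noise at pixel-noise 0.02 is ≈ 0.028/px; with ~60 samples
per ray, a threshold much below 3.5 noise sd admits spurious maxima on
occluded rays and erodes blink sensitivity). Accepted maxima are refined by
a three-point parabolic interpolation of the gradient, clipped to ±0.5
sample.

Detection *quality* is the accepted fraction of rays. The averaged-length
radius is the mean seed-to-point distance; the boundary points (≥ 5) are
also fitted with a direct least-squares conic constrained to ellipses
(scikit-image's `EllipseModel`), normalised to semi-major ≥ semi-minor and
orientation in [0, π). The tracker consumes the ellipse mean radius
(a+b)/2; when the conic fit degenerates but ≥ 3 points exist, a circle
fallback (centroid centre, averaged-length radius) preserves a usable
measurement. Coordinates are x = column, y = row, origin at the top-left
pixel centre, angles counter-clockwise from +x.

## Tracking

The state is (x_c, y_c, R) in pixels with identity (random-walk) dynamics:
the pupil moves and re-sizes slowly relative to 30 fps, so no velocity
states are carried. Process noise Q = 0.0002 and observation noise R = 1
are scalar spectral levels applied as Q·I₃ and R·I₃; their units are px²
(per frame for Q) — the source system printed bare scalars, and only the
ratio Q/R shapes the gain. The steady-state scalar Riccati solution for
these values is P\* = (−Q + √(Q² + 4Q))/2 ≈ 0.01404 with gain
K\* = (P\* + Q)/(P\* + Q + R) ≈ 0.01404.

Each frame is measured by re-seeding the detector at the *predicted*
centre, which makes tracking robust to slow drift. Measurements are gated:

- **quality gate** (default 0.5): frames with fewer than half the rays
  accepted — blinks, occlusions — are flagged, skipped, and bridged by the
  prediction;
- **innovation gate** (default *off*): with the published Q/R the filter
  gain is 0.014, so during physiological constriction (~1 mm within a
  second) the innovation is dominated by model lag and reaches tens of its
  predicted standard deviation; any tight gate would reject valid
  measurements wholesale and freeze the filter. The gate is therefore
  disabled by default and exposed for high-noise material.

Reported estimates are fixed-lag smoothed with N = 4: the estimate at t−4
uses observations up to t, implemented as a backward Rauch–Tung–Striebel
recursion over the stored lag window, which for identity dynamics equals
the fixed-interval smoother restricted to that window (this equality, per
prefix, is what the tests assert). The last N frames of a sequence are
smoothed with whatever future exists. Covariance updates use the Joseph
form and re-symmetrisation; symmetry/PSD is asserted in tests at every
step.

**Known limitation — smoothing lag.** K\* ≈ 0.014 corresponds to a ~71
frame (~2.4 s at 30 fps) time constant. Fast constriction is therefore
low-pass filtered: on rendered synthetic trials the tracked-vs-truth
diameter RMSE is ≈ 0.3 mm, almost all of it transient lag during the
stimulus and early redilation (detection alone recovers radii to ≈ 0.06 px
≈ 0.004 mm). The PIPR statistics are means over a 5 s baseline and a 30 s
post-stimulus window and are far less sensitive: the lag shifts a few
seconds of the post-window average, biasing a single-trial PIPR by roughly
+0.1 mm, and the blue−red *net* PIPR by less, since the shared phasic
transient largely cancels. Applications that need faithful constriction
*velocities* should raise Q; the defaults reproduce the source system's
behaviour instead.

Operator corrections replace the state mean at the corrected frame, reset
its covariance to the initialisation covariance (1·I₃), and re-run
filtering and smoothing forward; earlier samples are untouched.

## PIPR analysis

For a trace with stimulus onset *t₀* and offset *t₁* (5 s pulse):

- baseline = mean diameter over [t₀−5 s, t₀), blink-flagged samples
  excluded;
- post-stimulus mean = mean over [t₁, t₁+30 s). The post window is
  anchored at stimulus *offset*: a 5 s pre + 5 s stimulus + 30 s post
  protocol exhausts a 40 s recording only under this reading. Anchoring at
  onset is available via `post_anchor="onset"`.
- PIPR = baseline − post-stimulus mean; PIPR% = 100·PIPR/baseline;
  net PIPR = blue PIPR − red PIPR (same subject and power). These are
  exact identities, asserted to machine precision.

Per subject and condition, up to three trials are averaged pointwise after
removing trials whose blink-flag fraction exceeds 0.1 (the offline analogue
of discarding blink-contaminated recordings). Subjects enter the group
analysis only if their mean baseline lies in the closed interval
[5.5, 5.7] mm (with a 1e−9 guard for mean-accumulation rounding), since
baseline diameter confounds PIPR magnitude. Group contrasts use the
two-sided pooled-variance Student t-test (Welch available via
`equal_var=False`); SEM = sd/√n with the n−1 sd throughout — the
convention that reproduces the bundled cohort-description header.
Correlations of net PIPR with age, levodopa-equivalent dose and
Hoehn–Yahr grade use the sample Pearson r with the t(n−2) p-value. No
multiple-testing correction is applied, matching the source analysis.

## Synthetic data

The trajectory model is
D(t) = baseline − phasic(t) − sustained(t) + drift(t) + noise(t), each
constriction component rising as A(1−e^(−(t−t₀)/τ_c)) during the stimulus
and decaying exponentially after offset — the simplest form producing the
blue/red asymmetry: the phasic component (both wavelengths) decays with
τ_recovery, the sustained component (blue only) with the slower
τ_sustained. Defaults: baseline 5.63 mm, τ_c = 0.4 s (constriction
completes within the 5 s pulse), τ_recovery = 15 s and τ_sustained = 20 s.
The recovery constants are not printed anywhere in the source material;
they were chosen once so that a phasic amplitude of plausible size yields
the published 30-s-window red PIPR (≈ 0.6–0.8 mm implies slow, incomplete
redilation in these dark-adapted elderly subjects) and are flagged as
package defaults, not measured values. Noise is white (sd 0.02 mm);
drift is a doubly integrated random walk rescaled to sd 0.05 mm per trial
(hippus-like wander); blinks mask 0.2 s intervals. All randomness flows
from one integer seed per trial; rendering derives its own stream from the
same seed.

Rendering draws a dark disk (radius = diameter·px_per_mm/2) on a brighter
iris background with a normal-CDF edge profile whose steepest gradient sits
exactly at the ground-truth radius (σ = max(edge_blur, 0.5) px — the floor
keeps the edge resolvable and anti-aliased), plus centre jitter and pixel
noise. Blinks are rendered as an iris-intensity eyelid band covering the
frame down to 0.2·radius *below* the pupil centre: eyelids close past the
midline, and the overhang also breaks the two horizontal detection rays,
dropping quality to 5/12 ≈ 0.42 < 0.5 on occluded frames.

The cohort generator draws, per subject, a red-trial PIPR and a net PIPR
from normal distributions whose means are the published group summaries
(red 0.61/0.79 mm, net 0.61/0.13 mm for control/PD) and whose sds are the
published SEMs scaled by √n; closed-form window algebra converts these
targets into phasic and sustained amplitudes (for the occasional subject
with net < 0, the blue trial's phasic amplitude is shrunk instead, since
the sustained amplitude cannot be negative). Baselines are drawn around
5.63 mm (sd 0.04 mm). The generator's blue-PIPR scatter is therefore the
quadrature sum of the red and net scatter — slightly wider than the
published blue SEM for PD — and it emulates none of gaze movement, corneal
reflections, pupil eccentricity, illumination gradients or camera
compression. Passing tests show the pipeline recovers what this model
generates; they do not certify performance on clinical video.

## Test and benchmark sizes

Unit tests use 2–3 s clips and 50-frame filter sequences. The recovery
benchmark (tests and acceptance script) uses 20 rendered 40 s trials at
30 fps and 128×128 px (15 px/mm); the type-I calibration uses 5000
simulated 19-vs-10 null cohorts; the synthetic-cohort analysis uses the
full 19 PD / 10 control design with 3 trials per condition at trace level.
The CLI demo defaults to a smaller rendered cohort (3+3 subjects, 2
trials, 10 fps, 80×80 px at 10 px/mm) so it finishes in well under a
minute.
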