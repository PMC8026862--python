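"""Group analysis of a synthetic two-group chromatic-pupillometry cohort.

Generates ground-truth diameter traces for 19 PD and 10 control subjects
(three trials per wavelength, group means calibrated to the published
summaries), then runs the full analysis pipeline: baseline inclusion
filter, blink-trial exclusion, trial averaging, per-subject PIPR and the
group t-tests.
"""

from piprtrack import CohortSpec, analyze_cohort, synthesize_cohort

subjects = synthesize_cohort(CohortSpec(), seed=42, frame_rate_hz=30.0)
print(f"generated {len(subjects)} subjects, {len(subjects[0].trials)} trials each")

results = analyze_cohort(subjects)

report = results["baseline_report"]
kept = int(report.included.sum())
print(f"baseline filter (5.5-5.7 mm): kept {kept} of {len(report)} subjects")

gs = results["group_stats"]
print("\ngroup statistics (mean +/- SEM):")
for _, row in gs.iterrows():
    print(
        f"  {row.parameter:26s} PD {row.pd_mean:6.2f} (+/-{row.pd_sem:.2f})   "
        f"control {row.control_mean:6.2f} (+/-{row.control_sem:.2f})   "
        f"p = {row.p_value:.2g}"
    )
# Expect net PIPR ~0.13 mm (PD) vs ~0.61 mm (control) with a highly
# significant difference, while the single-wavelength PIPRs separate the
# groups weakly -- the within-subject blue-minus-red contrast is what
# carries the discrimination.

corr = results["correlations"]
if len(corr):
    print("\nnet PIPR vs clinical covariates (PD group):")
    for _, row in corr.iterrows():
        print(f"  {row.covariate:12s} r = {row.r:+.2f}  p = {row.p_value:.2f}  n = {row.n}")
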