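"""Published reference values bundled for validation.

These are the printed group-level summaries of the clinical chromatic
pupillometry study this package re-implements (19 Parkinson's disease and
10 control subjects; consensual response to 5-s blue 470 nm and red 610 nm
stimuli at 30 uW).  They serve as *inputs* for arithmetic identity checks
(net PIPR, post-stimulus contrasts, cohort descriptives) and as calibration
targets for the synthetic cohort generator — the raw videos behind them are
not distributed.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "pd_cohort",
    "REPORTED_PIPR_MM",
    "REPORTED_PIPR_SEM_MM",
    "REPORTED_NET_PIPR_MM",
    "REPORTED_NET_PIPR_PCT",
    "REPORTED_POST_STIM_MM",
    "REPORTED_PRE_STIM_MM",
    "REPORTED_COHORT_SUMMARY",
]

# Per-subject clinical description of the 19 PD participants:
# age (years), levodopa-equivalent daily dose (mg), Hoehn & Yahr grade.
_PD_COHORT_ROWS = [
    ("101", 65, 750, 2),
    ("102", 69, 300, 3),
    ("103", 65, 240, 1),
    ("104", 68, 600, 3),
    ("105", 85, 1197, 3),
    ("106", 67, 450, 1),
    ("107", 72, 1390, 3),
    ("108", 66, 580, 1),
    ("109", 74, 300, 1),
    ("110", 66, 2760, 4),
    ("111", 66, 1995, 3),
    ("112", 80, 1995, 2),
    ("113", 81, 640, 3),
    ("114", 64, 600, 3),
    ("115", 73, 0, 1),
    ("116", 72, 450, 1),
    ("117", 73, 214, 4),
    ("118", 70, 2827, 4),
    ("119", 70, 300, 1),
]


def pd_cohort() -> pd.DataFrame:
    """The 19-subject PD cohort description as a DataFrame."""
    return pd.DataFrame(
        _PD_COHORT_ROWS,
        columns=["subject_id", "age_years", "ledd_mg", "hy_grade"],
    )


# Printed descriptive header of the cohort table: mean (+/- sample sd).
REPORTED_COHORT_SUMMARY = {
    "age_years": (70.84, 5.9),
    "ledd_mg": (925.68, 864.8),
    "hy_grade": (2.31, 1.2),
}

# Group-mean PIPR per wavelength at 30 uW (mm) and their SEMs.
REPORTED_PIPR_MM = {
    "PD": {"blue": 0.92, "red": 0.79},
    "control": {"blue": 1.22, "red": 0.61},
}
REPORTED_PIPR_SEM_MM = {
    "PD": {"blue": 0.08, "red": 0.08},
    "control": {"blue": 0.08, "red": 0.07},
}

# Group-mean net PIPR (mm) and net PIPR percentage.
REPORTED_NET_PIPR_MM = {"PD": 0.13, "control": 0.61}
REPORTED_NET_PIPR_PCT = {"PD": 2.35, "control": 10.82}

# Group-mean post-stimulus diameters (mm) at 30 uW and the shared
# pre-stimulus baseline.
REPORTED_POST_STIM_MM = {
    "PD": {"blue": 4.72, "red": 4.84},
    "control": {"blue": 4.42, "red": 5.02},
}
REPORTED_PRE_STIM_MM = 5.63
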