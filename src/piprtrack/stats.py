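"""PIPR metrics and group statistics.

The post-illumination pupillary response (PIPR) of a trial is the mean
pre-stimulus diameter (5 s window before stimulus onset) minus the mean
post-stimulus diameter (30 s window anchored at stimulus offset by default).
The net PIPR of a subject is the blue-trial PIPR minus the red-trial PIPR at
matched power; it isolates the melanopsin-driven sustained constriction from
the classical photoreceptor response.  Group contrasts use the two-sample
Student t-test (pooled variance; Welch optional) and associations use the
Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    InvalidParameterError,
    NoDataError,
    PupilTrace,
    UndefinedCorrelationError,
)

__all__ = [
    "StimulusMeta",
    "PIPRResult",
    "NetPIPR",
    "Trial",
    "SubjectRecord",
    "GroupStats",
    "window_mean",
    "compute_pipr",
    "net_pipr",
    "average_trials",
    "filter_by_baseline",
    "group_compare",
    "pearson_corr",
    "describe_cohort",
    "subject_pipr",
    "analyze_cohort",
]


@dataclass(frozen=True)
class StimulusMeta:
    """Stimulus descriptor: wavelength, power and timing."""

    wavelength_nm: float
    power_uw: float
    stim_onset_s: float
    stim_offset_s: float

    def __post_init__(self) -> None:
        if not self.stim_onset_s < self.stim_offset_s:
            raise InvalidParameterError("stimulus onset must precede offset")

    @property
    def is_blue(self) -> bool:
        return self.wavelength_nm < 500.0


@dataclass(frozen=True)
class PIPRResult:
    """Per-trial (or per-subject-average) PIPR metrics in mm and percent."""

    pre_stim_diameter_mm: float
    post_stim_diameter_mm: float

    @property
    def pipr_mm(self) -> float:
        return self.pre_stim_diameter_mm - self.post_stim_diameter_mm

    @property
    def pipr_pct(self) -> float:
        return 100.0 * self.pipr_mm / self.pre_stim_diameter_mm


class NetPIPR(NamedTuple):
    net_mm: float
    net_pct: float


@dataclass
class Trial:
    trace: PupilTrace
    stim: StimulusMeta
    # populated by the synthetic generator; None for real recordings
    ground_truth: object | None = None


@dataclass
class SubjectRecord:
    """All trials of one subject plus clinical covariates."""

    subject_id: str
    group: Literal["PD", "control"]
    trials: list[Trial]
    age_years: float | None = None
    ledd_mg: float | None = None
    hy_grade: float | None = None

    def conditions(self) -> dict[tuple[float, float], list[Trial]]:
        out: dict[tuple[float, float], list[Trial]] = {}
        for t in self.trials:
            out.setdefault((t.stim.wavelength_nm, t.stim.power_uw), []).append(t)
        return out

    def baseline_mm(self, pre_window_s: float = 5.0) -> float:
        """Mean pre-stimulus diameter across all trials."""
        vals = [
            window_mean(
                t.trace, t.stim.stim_onset_s - pre_window_s, t.stim.stim_onset_s
            )
            for t in self.trials
        ]
        if not vals:
            raise NoDataError(f"subject {self.subject_id} has no trials")
        return float(np.mean(vals))


@dataclass(frozen=True)
class GroupStats:
    """Two-group comparison summary (means, SEMs, pooled-variance t-test)."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_stat: float
    p_value: float
    n_a: int
    n_b: int
    degenerate: bool = False


def window_mean(trace: PupilTrace, t_start_s: float, t_end_s: float) -> float:
    """Mean diameter (mm) over ``t_start <= t < t_end``, excluding blinks."""
    t = trace.times_s
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    if t_start_s < t[0] - 1e-9 or t_end_s > t[-1] + dt + 1e-9:
        raise InvalidParameterError(
            f"window [{t_start_s}, {t_end_s}) outside trace span"
        )
    mask = (t >= t_start_s) & (t < t_end_s) & ~trace.blink_flag
    if not mask.any():
        raise NoDataError("no usable (non-blink) samples in window")
    return float(trace.diameter_mm[mask].mean())


def compute_pipr(
    trace: PupilTrace,
    stim: StimulusMeta,
    pre_window_s: float = 5.0,
    post_window_s: float = 30.0,
    post_anchor: Literal["offset", "onset"] = "offset",
) -> PIPRResult:
    """PIPR of one trace: pre-window mean minus post-window mean.

    ``post_anchor`` selects whether the post-stimulus window starts at
    stimulus offset (default; a 5+5+30 s protocol then exhausts a 40 s
    recording) or at onset.
    """
    anchor = stim.stim_offset_s if post_anchor == "offset" else stim.stim_onset_s
    pre = window_mean(trace, stim.stim_onset_s - pre_window_s, stim.stim_onset_s)
    post = window_mean(trace, anchor, anchor + post_window_s)
    return PIPRResult(pre_stim_diameter_mm=pre, post_stim_diameter_mm=post)


def net_pipr(blue: PIPRResult, red: PIPRResult) -> NetPIPR:
    """Net PIPR: blue minus red, in mm and in baseline-normalised percent."""
    return NetPIPR(
        net_mm=blue.pipr_mm - red.pipr_mm,
        net_pct=blue.pipr_pct - red.pipr_pct,
    )


def average_trials(
    traces: Sequence[PupilTrace], blink_fraction_max: float = 0.1
) -> PupilTrace:
    """Average repeated trials of one condition on a common time grid.

    Trials whose blink-flag fraction exceeds ``blink_fraction_max`` are
    removed first (the offline analogue of discarding blink-contaminated
    recordings); the survivors are averaged pointwise.  A sample of the
    average is blink-flagged only where every surviving trial flags it.
    """
    if len(traces) == 0:
        raise NoDataError("no trials given")
    t0 = traces[0].times_s
    for tr in traces[1:]:
        if len(tr) != len(t0) or np.max(np.abs(tr.times_s - t0)) > 1e-6:
            raise InvalidParameterError("trials must share a common time grid")
    survivors = [tr for tr in traces if tr.blink_flag.mean() <= blink_fraction_max]
    if not survivors:
        raise NoDataError(
            f"all {len(traces)} trials exceed blink fraction {blink_fraction_max}"
        )
    cal = survivors[0].calibration_px_per_mm
    d = np.mean([tr.diameter_px for tr in survivors], axis=0)
    blink = np.logical_and.reduce([tr.blink_flag for tr in survivors])
    used = np.logical_or.reduce([tr.measurement_used for tr in survivors])
    return PupilTrace(
        times_s=t0.copy(),
        diameter_px=d,
        center_x_px=np.mean([tr.center_x_px for tr in survivors], axis=0),
        center_y_px=np.mean([tr.center_y_px for tr in survivors], axis=0),
        measurement_used=used,
        blink_flag=blink,
        calibration_px_per_mm=cal,
    )


def filter_by_baseline(
    subjects: Sequence[SubjectRecord],
    lo_mm: float = 5.5,
    hi_mm: float = 5.7,
    pre_window_s: float = 5.0,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Keep subjects whose mean pre-stimulus diameter lies in [lo, hi].

    The baseline diameter is a known confounder of PIPR magnitude, so the
    analysis restricts to a narrow baseline band (closed interval).  Returns
    the included subjects and a per-subject report of baselines and
    inclusion decisions.
    """
    rows = []
    included = []
    for s in subjects:
        b = s.baseline_mm(pre_window_s)
        # closed interval with a 1e-9 guard against mean-accumulation rounding
        ok = lo_mm - 1e-9 <= b <= hi_mm + 1e-9
        rows.append(
            {"subject_id": s.subject_id, "group": s.group,
             "baseline_mm": b, "included": ok}
        )
        if ok:
            included.append(s)
    return included, pd.DataFrame(rows)


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = True,
) -> GroupStats:
    """Two-sided two-sample t-test with means and SEMs (sd uses n-1)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("each group needs at least two values")
    sem_a = a.std(ddof=1) / np.sqrt(len(a))
    sem_b = b.std(ddof=1) / np.sqrt(len(b))
    pooled_var = (
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    degenerate = False
    if equal_var and pooled_var == 0.0:
        degenerate = True
        t_stat = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        t_stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return GroupStats(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(sem_a),
        sem_b=float(sem_b),
        t_stat=float(t_stat),
        p_value=float(p),
        n_a=len(a),
        n_b=len(b),
        degenerate=degenerate,
    )


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t(n-2) distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidParameterError("need matched samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("inputs must be finite")
    if x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def describe_cohort(subjects) -> pd.DataFrame:
    """Mean and sample sd (n-1) of age, LEDD and H&Y grade.

    Accepts a list of :class:`SubjectRecord` or a DataFrame with columns
    ``age_years``, ``ledd_mg``, ``hy_grade``.  Missing fields are reported
    as NaN (absent), never as zero; the sd of a single value is NaN.
    """
    if isinstance(subjects, pd.DataFrame):
        df = subjects
    else:
        df = pd.DataFrame(
            {
                "age_years": [s.age_years for s in subjects],
                "ledd_mg": [s.ledd_mg for s in subjects],
                "hy_grade": [s.hy_grade for s in subjects],
            }
        )
    rows = {}
    for col in ("age_years", "ledd_mg", "hy_grade"):
        vals = pd.to_numeric(df[col], errors="coerce").dropna() if col in df else pd.Series(dtype=float)
        rows[col] = {
            "mean": vals.mean() if len(vals) else np.nan,
            "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            "n": len(vals),
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Cohort-level pipeline
# ---------------------------------------------------------------------------

def subject_pipr(
    subject: SubjectRecord,
    wavelength_nm: float,
    power_uw: float,
    blink_fraction_max: float = 0.1,
    pre_window_s: float = 5.0,
    post_window_s: float = 30.0,
    post_anchor: Literal["offset", "onset"] = "offset",
) -> PIPRResult:
    """Per-subject PIPR of one condition: average the surviving trials of
    that condition, then compute the PIPR of the averaged trace."""
    trials = subject.conditions().get((wavelength_nm, power_uw))
    if not trials:
        raise NoDataError(
            f"subject {subject.subject_id} has no ({wavelength_nm} nm, "
            f"{power_uw} uW) trials"
        )
    avg = average_trials([t.trace for t in trials], blink_fraction_max)
    return compute_pipr(avg, trials[0].stim, pre_window_s, post_window_s, post_anchor)


def analyze_cohort(
    subjects: Sequence[SubjectRecord],
    power_uw: float = 30.0,
    blue_nm: float | None = None,
    red_nm: float | None = None,
    blink_fraction_max: float = 0.1,
    baseline_lo_mm: float = 5.5,
    baseline_hi_mm: float = 5.7,
    apply_baseline_filter: bool = True,
    equal_var: bool = True,
    post_anchor: Literal["offset", "onset"] = "offset",
) -> dict[str, pd.DataFrame]:
    """Full group analysis: per-subject PIPR table, group statistics and
    correlations of net PIPR with clinical covariates.

    Returns ``{"per_subject": ..., "group_stats": ..., "correlations": ...,
    "baseline_report": ...}``.
    """
    wavelengths = sorted(
        {t.stim.wavelength_nm for s in subjects for t in s.trials
         if t.stim.power_uw == power_uw}
    )
    if blue_nm is None:
        blue_nm = min((w for w in wavelengths if w < 500.0), default=None)
    if red_nm is None:
        red_nm = max((w for w in wavelengths if w >= 500.0), default=None)
    if blue_nm is None or red_nm is None:
        raise NoDataError("need one short- and one long-wavelength condition")

    if apply_baseline_filter:
        kept, report = filter_by_baseline(subjects, baseline_lo_mm, baseline_hi_mm)
    else:
        kept, report = list(subjects), pd.DataFrame()

    rows = []
    for s in kept:
        blue = subject_pipr(s, blue_nm, power_uw, blink_fraction_max,
                            post_anchor=post_anchor)
        red = subject_pipr(s, red_nm, power_uw, blink_fraction_max,
                           post_anchor=post_anchor)
        net = net_pipr(blue, red)
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "pre_stim_mm": blue.pre_stim_diameter_mm,
                "pipr_blue_mm": blue.pipr_mm,
                "pipr_red_mm": red.pipr_mm,
                "pipr_blue_pct": blue.pipr_pct,
                "pipr_red_pct": red.pipr_pct,
                "net_pipr_mm": net.net_mm,
                "net_pipr_pct": net.net_pct,
                "age_years": s.age_years,
                "ledd_mg": s.ledd_mg,
                "hy_grade": s.hy_grade,
            }
        )
    per_subject = pd.DataFrame(rows)

    pd_df = per_subject[per_subject.group == "PD"]
    ct_df = per_subject[per_subject.group == "control"]
    stat_rows = []
    for col, label in (
        ("pipr_blue_mm", "PIPR (blue) (mm)"),
        ("pipr_red_mm", "PIPR (red) (mm)"),
        ("net_pipr_mm", "Net PIPR (mm)"),
        ("net_pipr_pct", "Net PIPR percentage (%)"),
    ):
        if len(pd_df) >= 2 and len(ct_df) >= 2:
            gs = group_compare(pd_df[col], ct_df[col], equal_var=equal_var)
            row = {
                "pd_mean": gs.mean_a, "pd_sem": gs.sem_a, "n_pd": gs.n_a,
                "control_mean": gs.mean_b, "control_sem": gs.sem_b,
                "n_control": gs.n_b,
                "t_stat": gs.t_stat, "p_value": gs.p_value,
            }
        else:  # too few subjects for a test: report means only
            row = {
                "pd_mean": pd_df[col].mean(), "pd_sem": np.nan, "n_pd": len(pd_df),
                "control_mean": ct_df[col].mean(), "control_sem": np.nan,
                "n_control": len(ct_df),
                "t_stat": np.nan, "p_value": np.nan,
            }
        stat_rows.append({"parameter": label, **row})
    group_stats = pd.DataFrame(stat_rows)

    corr_rows = []
    for col, label in (
        ("ledd_mg", "LEDD (mg)"),
        ("age_years", "Age (years)"),
        ("hy_grade", "H&Y grade"),
    ):
        sub = pd_df.dropna(subset=[col])
        if len(sub) >= 3 and sub[col].std() > 0:
            r, p = pearson_corr(sub["net_pipr_mm"], sub[col])
            corr_rows.append({"covariate": label, "r": r, "p_value": p, "n": len(sub)})
    correlations = pd.DataFrame(corr_rows)

    return {
        "per_subject": per_subject,
        "group_stats": group_stats,
        "correlations": correlations,
        "baseline_report": report,
    }
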