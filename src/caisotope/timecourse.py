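"""Mixed-effects time-course analysis of urinary Ca isotope series.

The question is whether and when urinary delta44/42 departs from its
pre-bed-rest level.  Following the standard longitudinal treatment, delta is
modelled with a linear mixed model: sampling day as a categorical fixed
effect (all baseline-collection days lumped into one BDC level) and a random
intercept per subject.  Variance components are estimated by REML; a-priori
treatment contrasts of each day against BDC give the per-day change
estimates (BLUPs), their standard errors, and unadjusted two-sided t-test
P-values with residual degrees of freedom.

``TimecourseModel(data).fit()`` returns ``TimecourseResults`` with a
contrast table, response-delay detection, and a text ``summary()``.
Helper functions supply the change-from-baseline series and simple Pearson
correlation screens.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .cohort import NUC_DESIGN, StudyDesign, normalize_day_label, samples_to_frame

__all__ = [
    "ContrastResult",
    "DelayEstimate",
    "TimecourseModel",
    "TimecourseResults",
    "fit_timecourse",
    "detect_delay",
    "change_from_baseline",
    "correlate",
]

BASELINE_LEVEL = "BDC"


@dataclass(frozen=True)
class ContrastResult:
    """One row of the mixed-model output.

    For the BDC row, ``blup`` is the baseline level itself (tested against
    zero); for every other day it is the change versus the lumped BDC level.
    """

    day_label: str
    blup: float
    se: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must lie in [0, 1], got {self.p_value}")


@dataclass(frozen=True)
class DelayEstimate:
    """Detected onset and recovery sampling days (labels, or None)."""

    onset_day: str | None
    recovery_day: str | None


def _coerce_frame(data) -> pd.DataFrame:
    df = data if isinstance(data, pd.DataFrame) else samples_to_frame(data)
    for col in ("subject_id", "day_label", "delta4442_permil"):
        if col not in df.columns:
            raise ValueError(f"data lacks required column {col!r}")
    return df


class TimecourseModel:
    """Linear mixed model of delta vs sampling day with subject intercepts.

    Parameters
    ----------
    data : DataFrame or iterable of UrineSample
        Canonical sample schema; day labels are normalised against the design.
    design : StudyDesign
        Supplies level order and phase assignments; BDC-phase days are lumped
        into the single BDC factor level.
    alpha_level : float
        Significance threshold used by delay detection and the summary.
    """

    def __init__(
        self,
        data,
        design: StudyDesign = NUC_DESIGN,
        alpha_level: float = 0.05,
    ):
        df = _coerce_frame(data).copy()
        df["day_label"] = df["day_label"].map(normalize_day_label)
        df["level"] = [
            BASELINE_LEVEL if design.phase_of(lab) == "BDC" else lab
            for lab in df["day_label"]
        ]
        level_order = [BASELINE_LEVEL] + [
            d.label for d in design.days if d.phase != "BDC"
        ]
        df = df[df["level"].isin(level_order)]
        if df["subject_id"].nunique() < 2:
            raise ValueError("mixed model needs at least 2 subjects")
        # drop levels observed in fewer than two subjects rather than impute
        counts = df.groupby("level")["subject_id"].nunique()
        thin = [lev for lev in counts.index if counts[lev] < 2]
        if thin:
            warnings.warn(
                f"dropping level(s) with fewer than 2 subjects: {', '.join(sorted(thin))}",
                stacklevel=2,
            )
            df = df[~df["level"].isin(thin)]
        levels = [lev for lev in level_order if lev in set(df["level"])]
        subjects = df["subject_id"].unique()
        if BASELINE_LEVEL not in levels:
            raise ValueError("no BDC-phase samples available for the baseline level")
        if len(subjects) < 2:
            raise ValueError("mixed model needs at least 2 subjects")
        if len(levels) < 2:
            raise ValueError("mixed model needs at least 2 time levels")
        per_subject = df.groupby("subject_id")["level"].nunique()
        if (per_subject < 2).any():
            bad = ", ".join(per_subject.index[per_subject < 2])
            raise ValueError(f"subject(s) observed at fewer than 2 levels: {bad}")
        self.data = df.reset_index(drop=True)
        self.design = design
        self.alpha_level = alpha_level
        self.levels = levels

    def fit(self) -> "TimecourseResults":
        df = self.data
        endog = df["delta4442_permil"].to_numpy(float)
        # explicit treatment-coded design matrix: intercept = BDC level
        exog = np.column_stack(
            [np.ones(len(df))]
            + [(df["level"] == lev).to_numpy(float) for lev in self.levels[1:]]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = sm.MixedLM(endog, exog, groups=df["subject_id"])
            fitted = model.fit(reml=True)
        k = exog.shape[1]
        params = np.asarray(fitted.fe_params, float)
        ses = np.asarray(fitted.bse_fe, float)
        dof = len(df) - k  # residual degrees of freedom for the contrast t-tests
        tvals = params / ses
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        contrasts = [
            ContrastResult(
                day_label=self.levels[i],
                blup=float(params[i]),
                se=float(ses[i]),
                p_value=float(pvals[i]),
            )
            for i in range(k)
        ]
        return TimecourseResults(
            contrasts=contrasts,
            design=self.design,
            alpha_level=self.alpha_level,
            n_obs=len(df),
            n_subjects=df["subject_id"].nunique(),
            dof=dof,
            sigma_subject=float(math.sqrt(max(float(np.asarray(fitted.cov_re)[0, 0]), 0.0))),
            sigma_resid=float(math.sqrt(max(float(fitted.scale), 0.0))),
            converged=bool(fitted.converged),
        )


@dataclass(frozen=True)
class TimecourseResults:
    """Per-day contrasts and variance components from the mixed model."""

    contrasts: list[ContrastResult]
    design: StudyDesign
    alpha_level: float
    n_obs: int
    n_subjects: int
    dof: int
    sigma_subject: float
    sigma_resid: float
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day_label": [c.day_label for c in self.contrasts],
                "blup_permil": [c.blup for c in self.contrasts],
                "se_permil": [c.se for c in self.contrasts],
                "p_value": [c.p_value for c in self.contrasts],
            }
        )

    def detect_delay(self, alpha_level: float | None = None) -> DelayEstimate:
        alpha = self.alpha_level if alpha_level is None else alpha_level
        return detect_delay(self.contrasts, self.design, alpha)

    def summary(self) -> str:
        delay = self.detect_delay()
        lines = [
            "Mixed-effects time course (random subject intercept, REML)",
            "==========================================================",
            f"observations: {self.n_obs}   subjects: {self.n_subjects}   "
            f"residual df: {self.dof}",
            f"sd(subject): {self.sigma_subject:.4f} permil   "
            f"sd(residual): {self.sigma_resid:.4f} permil",
            "",
            f"{'day':>8} {'BLUP':>9} {'SE':>8} {'P':>9}",
        ]
        for c in self.contrasts:
            flag = "*" if c.day_label != BASELINE_LEVEL and c.p_value < self.alpha_level else " "
            lines.append(
                f"{c.day_label:>8} {c.blup:9.4f} {c.se:8.4f} {c.p_value:9.4f}{flag}"
            )
        lines += [
            "",
            "(BDC row: baseline level; other rows: change vs BDC)",
            f"onset day:    {delay.onset_day or 'not detected'}",
            f"recovery day: {delay.recovery_day or 'not detected'}",
        ]
        return "\n".join(lines)


def fit_timecourse(
    samples,
    design: StudyDesign = NUC_DESIGN,
    alpha_level: float = 0.05,
) -> TimecourseResults:
    """Fit the mixed-effects time course; see :class:`TimecourseModel`."""
    return TimecourseModel(samples, design, alpha_level).fit()


def detect_delay(
    contrasts: Sequence[ContrastResult],
    design: StudyDesign = NUC_DESIGN,
    alpha_level: float = 0.05,
) -> DelayEstimate:
    """Locate the response onset and recovery on the sampling grid.

    Onset: the first bed-rest or recovery sampling day whose contrast versus
    BDC is significantly negative.  Recovery: the first outpatient follow-up
    (R2) day after onset at which the contrast is no longer significant.
    Either can be absent; detection is quantised to the sampling schedule.
    """
    onset = None
    recovery = None
    for c in contrasts:
        if c.day_label == BASELINE_LEVEL:
            continue
        try:
            phase = design.phase_of(c.day_label)
        except KeyError:
            continue
        if onset is None:
            if phase in ("HDT", "R1", "R2") and c.p_value < alpha_level and c.blup < 0:
                onset = c.day_label
        elif recovery is None:
            if phase == "R2" and c.p_value >= alpha_level:
                recovery = c.day_label
    return DelayEstimate(onset_day=onset, recovery_day=recovery)


def change_from_baseline(samples, design: StudyDesign = NUC_DESIGN) -> pd.DataFrame:
    """Per-day mean change of delta from each subject's own BDC mean.

    Every subject's BDC-phase mean is subtracted from all of that subject's
    samples; the centred values are then averaged across subjects per day.
    Returns columns day_label, mean_change_permil, se_permil, n_subjects.
    """
    df = _coerce_frame(samples).copy()
    df["day_label"] = df["day_label"].map(normalize_day_label)
    df["phase"] = [design.phase_of(lab) for lab in df["day_label"]]
    bdc = df[df["phase"] == "BDC"].groupby("subject_id")["delta4442_permil"].mean()
    missing = sorted(set(df["subject_id"]) - set(bdc.index))
    if missing:
        raise ValueError(
            f"subject(s) lacking any BDC sample: {', '.join(map(str, missing))}"
        )
    df["change"] = df["delta4442_permil"] - df["subject_id"].map(bdc).to_numpy(float)
    order = [lab for lab in design.labels if lab in set(df["day_label"])]
    grouped = df.groupby("day_label")["change"]
    out = pd.DataFrame(
        {
            "day_label": order,
            "mean_change_permil": [grouped.mean()[lab] for lab in order],
            "se_permil": [
                grouped.std(ddof=1)[lab] / math.sqrt(grouped.count()[lab])
                if grouped.count()[lab] > 1
                else np.nan
                for lab in order
            ],
            "n_subjects": [int(grouped.count()[lab]) for lab in order],
        }
    )
    return out


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation screen: returns (r^2, two-sided t-test P)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"correlation needs at least 3 pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)
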