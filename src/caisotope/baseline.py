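"""Excretion-baseline diagnostic for urinary Ca isotopes.

Because the renal excreted fraction differs strongly between individuals,
urinary delta44/42 alone cannot separate bone loss from renal reabsorption.
On a healthy steady-state population, however, delta and daily Ca excretion
lie on a common Rayleigh trend: delta is affine in log(excretion).  Fitting
that healthy-baseline trend and asking whether a new (delta, excretion)
pair falls below its prediction band cancels the individual reabsorption
effect — bone loss shifts a sample vertically below the trend, while a pure
change in reabsorption moves it along the trend.

Two coordinate modes are supported and never mixed:

``LOGLOG_RATIO``
    y = log10 of the absolute 44/42 ratio (delta placed on the ratio axis of
    a declared reference standard), x = log10 of daily Ca excretion.
    Published baseline trends with slopes near -5e-4 and intercepts near
    1.18 live in this mode.
``SEMILOG_DELTA``
    y = delta44/42 in permil, x = log10 of daily Ca excretion.

The model class follows the usual estimator pattern:
``BaselineTrend(data, mode=...).fit()`` returns a ``BaselineTrendResults``
carrying the coefficients, their uncertainty, the prediction band, and
``classify`` / ``compare_to`` / ``summary`` / ``save`` methods.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import UrineSample, samples_to_frame
from .isotopes import ReferenceStandard, SRM915A

__all__ = [
    "BaselineMode",
    "BaselineTrend",
    "BaselineTrendResults",
    "DiagnosticCall",
    "TrendComparison",
    "fit_baseline",
    "classify_sample",
    "compare_trends",
]


class BaselineMode(str, Enum):
    LOGLOG_RATIO = "loglog-ratio"
    SEMILOG_DELTA = "semilog-delta"


@dataclass(frozen=True)
class DiagnosticCall:
    """Classification of one sample against a fitted baseline.

    ``vertical_offset`` is the observed minus baseline-predicted delta at the
    sample's excretion, in permil; ``band_position`` says where the sample
    sits relative to the pointwise prediction band.
    """

    subject_id: str | None
    day_label: str | None
    delta_urine: float
    ca_excreted: float
    vertical_offset: float
    band_position: str  # "below" | "within" | "above"


@dataclass(frozen=True)
class TrendComparison:
    """Difference between two baseline trends fitted in the same mode.

    All differences are model_b minus model_a; ``mean_offset_permil`` is the
    mean vertical separation over the shared x-range, back-transformed to
    permil (negative: b lies below a).
    """

    d_slope: float
    d_intercept: float
    mean_offset_permil: float
    p_parallel: float
    x_range: tuple[float, float]


def _coerce_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return samples_to_frame(data)


class BaselineTrend:
    """Healthy-baseline trend model of urinary delta vs daily Ca excretion.

    Parameters
    ----------
    data : DataFrame or iterable of UrineSample
        Must provide ``delta4442_permil`` and ``ca_excreted_mmol_d`` columns
        (the canonical sample schema).
    mode : BaselineMode
        Fit coordinate system (see module docstring).
    reference : ReferenceStandard
        Supplies the absolute ratio axis for LOGLOG_RATIO mode.
    confidence_level : float
        Level of the pointwise prediction band used for classification.
    phases : sequence of str, optional
        Restrict the fit to samples from these phases (e.g. ["BDC"]).
    """

    def __init__(
        self,
        data,
        mode: BaselineMode = BaselineMode.SEMILOG_DELTA,
        reference: ReferenceStandard = SRM915A,
        confidence_level: float = 0.95,
        phases: Sequence[str] | None = None,
    ):
        df = _coerce_frame(data)
        if phases is not None:
            df = df[df["phase"].isin(list(phases))]
        for col in ("delta4442_permil", "ca_excreted_mmol_d"):
            if col not in df.columns:
                raise ValueError(f"data lacks required column {col!r}")
        if not 0.0 < confidence_level < 1.0:
            raise ValueError("confidence_level must lie in (0, 1)")
        self.data = df.reset_index(drop=True)
        self.mode = BaselineMode(mode)
        self.reference = reference
        self.confidence_level = confidence_level

    def _xy(self) -> tuple[np.ndarray, np.ndarray]:
        exc = self.data["ca_excreted_mmol_d"].to_numpy(float)
        delta = self.data["delta4442_permil"].to_numpy(float)
        if np.any(exc <= 0):
            raise ValueError("all ca_excreted values must be positive")
        x = np.log10(exc)
        if self.mode is BaselineMode.LOGLOG_RATIO:
            y = np.log10(self.reference.r44_42 * (1.0 + delta / 1000.0))
        else:
            y = delta
        return x, y

    def fit(self) -> "BaselineTrendResults":
        x, y = self._xy()
        n = len(x)
        if n < 3:
            raise ValueError(f"baseline fit needs at least 3 samples, got {n}")
        sxx = float(np.sum((x - x.mean()) ** 2))
        if sxx == 0.0:
            raise ValueError("zero variance in log10(excretion): degenerate design")
        with np.errstate(divide="ignore", invalid="ignore"):
            reg = stats.linregress(x, y)
        resid = y - (reg.intercept + reg.slope * x)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
        residual_sd = math.sqrt(ss_res / (n - 2))
        if residual_sd > 0:
            se_slope = residual_sd / math.sqrt(sxx)
            tstat = reg.slope / se_slope
            p_value = 2.0 * stats.t.sf(abs(tstat), n - 2)
        else:
            se_slope = 0.0
            p_value = 0.0 if reg.slope != 0 else 1.0
        return BaselineTrendResults(
            mode=self.mode,
            slope=float(reg.slope),
            intercept=float(reg.intercept),
            r2=min(r2, 1.0),
            p_value=float(p_value),
            residual_sd=residual_sd,
            se_slope=se_slope,
            n=n,
            confidence_level=self.confidence_level,
            x_mean=float(x.mean()),
            s_xx=sxx,
            x_min=float(x.min()),
            x_max=float(x.max()),
            reference_name=self.reference.name,
            reference_r44_42=self.reference.r44_42,
        )


@dataclass(frozen=True)
class BaselineTrendResults:
    """Fitted baseline trend: coefficients, fit quality, and band geometry."""

    mode: BaselineMode
    slope: float
    intercept: float
    r2: float
    p_value: float
    residual_sd: float
    se_slope: float
    n: int
    confidence_level: float
    x_mean: float
    s_xx: float
    x_min: float
    x_max: float
    reference_name: str = SRM915A.name
    reference_r44_42: float = SRM915A.r44_42

    # -- prediction ---------------------------------------------------------

    def predict_y(self, x: "float | np.ndarray") -> "float | np.ndarray":
        """Trend value in fit coordinates at x = log10(excretion)."""
        return self.intercept + self.slope * np.asarray(x, float)

    def predict_delta(self, ca_excreted: "float | np.ndarray") -> "float | np.ndarray":
        """Baseline-predicted delta (permil) at a daily Ca excretion (mmol/d)."""
        x = np.log10(np.asarray(ca_excreted, float))
        y = self.predict_y(x)
        if self.mode is BaselineMode.LOGLOG_RATIO:
            return 1000.0 * (10.0**y / self.reference_r44_42 - 1.0)
        return y

    def band_halfwidth(self, x: "float | np.ndarray") -> "float | np.ndarray":
        """Half-width of the pointwise prediction band in fit coordinates.

        A prediction band (for a single new observation), not a confidence
        band of the mean: classification concerns an individual sample.
        """
        x = np.asarray(x, float)
        tcrit = stats.t.ppf(0.5 + self.confidence_level / 2.0, self.n - 2)
        return (
            tcrit
            * self.residual_sd
            * np.sqrt(1.0 + 1.0 / self.n + (x - self.x_mean) ** 2 / self.s_xx)
        )

    # -- classification -----------------------------------------------------

    def _y_offset(self, delta_urine: float, ca_excreted: float) -> tuple[float, float]:
        x = math.log10(ca_excreted)
        if self.mode is BaselineMode.LOGLOG_RATIO:
            y = math.log10(self.reference_r44_42 * (1.0 + delta_urine / 1000.0))
        else:
            y = delta_urine
        return x, y - float(self.predict_y(x))

    def vertical_offset(self, delta_urine: float, ca_excreted: float) -> float:
        """Observed minus predicted delta at the sample's excretion, permil."""
        _, dy = self._y_offset(delta_urine, ca_excreted)
        return _offset_to_permil(dy, self.mode)

    def classify(
        self, sample: "UrineSample | tuple[float, float]"
    ) -> DiagnosticCall:
        """Place one sample below/within/above the baseline prediction band."""
        if isinstance(sample, UrineSample):
            subj, day = sample.subject_id, sample.day_label
            delta, exc = sample.delta_urine, sample.ca_excreted
        else:
            subj = day = None
            delta, exc = sample
        if not exc > 0:
            raise ValueError(f"ca_excreted must be positive, got {exc}")
        x, dy = self._y_offset(delta, exc)
        half = float(self.band_halfwidth(x))
        if dy < -half:
            position = "below"
        elif dy > half:
            position = "above"
        else:
            position = "within"
        return DiagnosticCall(
            subject_id=subj,
            day_label=day,
            delta_urine=delta,
            ca_excreted=exc,
            vertical_offset=_offset_to_permil(dy, self.mode),
            band_position=position,
        )

    def classify_frame(self, data) -> pd.DataFrame:
        """Classify every row of a sample table; returns a call table."""
        df = _coerce_frame(data)
        calls = [
            self.classify(
                UrineSample(
                    subject_id=str(r.subject_id),
                    day_label=str(r.day_label),
                    phase=str(getattr(r, "phase", "")) or "BDC",
                    delta_urine=float(r.delta4442_permil),
                    se=float(getattr(r, "se_permil", 0.0)),
                    ca_excreted=float(r.ca_excreted_mmol_d),
                )
            )
            for r in df.itertuples()
        ]
        return pd.DataFrame(
            {
                "subject_id": [c.subject_id for c in calls],
                "day_label": [c.day_label for c in calls],
                "delta4442_permil": [c.delta_urine for c in calls],
                "ca_excreted_mmol_d": [c.ca_excreted for c in calls],
                "vertical_offset_permil": [c.vertical_offset for c in calls],
                "band_position": [c.band_position for c in calls],
            }
        )

    # -- comparison ---------------------------------------------------------

    def compare_to(self, other: "BaselineTrendResults", n_grid: int = 201) -> TrendComparison:
        """Compare this trend (a) with another (b = other) in the same mode.

        Reports slope/intercept differences (b - a), the mean vertical
        separation in permil over the shared x-range, and a two-sample t-test
        of slope equality (the parallelism check).
        """
        if self.mode is not other.mode:
            raise ValueError(
                f"cannot compare trends in different modes: "
                f"{self.mode.value} vs {other.mode.value}"
            )
        lo, hi = max(self.x_min, other.x_min), min(self.x_max, other.x_max)
        if not lo < hi:  # disjoint observed ranges: fall back to the union
            lo, hi = min(self.x_min, other.x_min), max(self.x_max, other.x_max)
        grid = np.linspace(lo, hi, n_grid)
        dy = other.predict_y(grid) - self.predict_y(grid)
        mean_offset = float(np.mean(_offset_to_permil(dy, self.mode)))
        d_slope = other.slope - self.slope
        se = math.hypot(self.se_slope, other.se_slope)
        if se > 0:
            tstat = d_slope / se
            dof = max(self.n + other.n - 4, 1)
            p_parallel = float(2.0 * stats.t.sf(abs(tstat), dof))
        else:
            p_parallel = 1.0 if d_slope == 0 else 0.0
        return TrendComparison(
            d_slope=d_slope,
            d_intercept=other.intercept - self.intercept,
            mean_offset_permil=mean_offset,
            p_parallel=p_parallel,
            x_range=(float(lo), float(hi)),
        )

    # -- reporting / persistence -------------------------------------------

    def summary(self) -> str:
        lines = [
            "Baseline trend fit",
            "==================",
            f"mode:             {self.mode.value}",
            f"n samples:        {self.n}",
            f"slope:            {self.slope:.6g}",
            f"intercept:        {self.intercept:.6g}",
            f"r^2:              {self.r2:.4f}",
            f"P (slope != 0):   {self.p_value:.4g}",
            f"residual sd:      {self.residual_sd:.6g}",
            f"band level:       {self.confidence_level:.2f} (prediction band)",
            f"x range (log10):  [{self.x_min:.4f}, {self.x_max:.4f}]",
            f"reference:        {self.reference_name} (44/42 = {self.reference_r44_42})",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialise the fitted trend to a JSON text file."""
        payload = asdict(self)
        payload["mode"] = self.mode.value
        payload["format"] = "caisotope-baseline-v1"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "BaselineTrendResults":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.pop("format", None) != "caisotope-baseline-v1":
            raise ValueError(f"{path}: not a baseline trend file")
        payload["mode"] = BaselineMode(payload["mode"])
        return cls(**payload)


def _offset_to_permil(dy, mode: BaselineMode):
    """Back-transform a vertical offset in fit coordinates to permil."""
    if mode is BaselineMode.LOGLOG_RATIO:
        return 1000.0 * (10.0**np.asarray(dy, float) - 1.0)
    return dy


# -- functional wrappers ----------------------------------------------------


def fit_baseline(
    samples,
    mode: BaselineMode = BaselineMode.SEMILOG_DELTA,
    reference: ReferenceStandard = SRM915A,
    confidence_level: float = 0.95,
    phases: Sequence[str] | None = None,
) -> BaselineTrendResults:
    """Fit the baseline trend; see :class:`BaselineTrend`."""
    return BaselineTrend(samples, mode, reference, confidence_level, phases).fit()


def classify_sample(model: BaselineTrendResults, sample) -> DiagnosticCall:
    """Classify one sample against a fitted baseline trend."""
    return model.classify(sample)


def compare_trends(
    model_a: BaselineTrendResults, model_b: BaselineTrendResults
) -> TrendComparison:
    """Compare two fitted trends (differences reported as b minus a)."""
    return model_a.compare_to(model_b)
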