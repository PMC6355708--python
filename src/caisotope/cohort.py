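"""Synthetic bed-rest cohort generator.

Emulates the statistical structure of a 21-day 6-degree head-down-tilt
(HDT) bed-rest study with urinary Ca isotope sampling: seven male subjects,
two baseline data collection days (BDC), three bed-rest days, inpatient
recovery (R1) and two outpatient follow-ups (R2).  Part of the cohort
receives a KHCO3 countermeasure that attenuates disuse-induced bone
resorption.

Each subject is characterised by an individual renal excreted fraction
``f_excreted`` (the dominant source of inter-individual differences in
urinary delta), a blood delta baseline, and a filtered Ca load.  Bed rest
releases isotopically light bone Ca into blood after an onset delay; the
extra Ca load also raises the excreted fraction, moving samples along the
Rayleigh trajectory.  Both channels can be switched off independently.

Time is measured in days from the start of bed rest: BDC-d is day -d,
HDTn is day n, and R+k is day 21+k.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .isotopes import DeltaScale, DeltaValue, as_delta
from .rayleigh import DEFAULT_ALPHA, FractionationContext, rayleigh_urine_delta

__all__ = [
    "PHASES",
    "DesignDay",
    "StudyDesign",
    "NUC_DESIGN",
    "Subject",
    "CohortParams",
    "BoneResponseParams",
    "UrineSample",
    "SAMPLE_COLUMNS",
    "SUBJECT_COLUMNS",
    "normalize_day_label",
    "generate_cohort",
    "blood_mixing_delta",
    "bone_resorption_flux",
    "simulate_timecourse",
    "samples_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_subjects_csv",
    "read_subjects_csv",
    "SchemaError",
]

PHASES = ("BDC", "HDT", "R1", "R2")


class SchemaError(ValueError):
    """A delimited-text table does not match the expected schema."""


@dataclass(frozen=True)
class DesignDay:
    """One scheduled sampling day: label, study phase, and numeric day."""

    label: str
    phase: str
    day: float


@dataclass(frozen=True)
class StudyDesign:
    """Ordered sampling schedule with phase assignments.

    ``bed_rest_end`` is the day of re-ambulation (start of recovery).
    """

    days: tuple[DesignDay, ...]
    bed_rest_end: float = 21.0

    def __post_init__(self) -> None:
        labels = [d.label for d in self.days]
        if len(set(labels)) != len(labels):
            raise ValueError("design day labels must be unique")
        for d in self.days:
            if d.phase not in PHASES:
                raise ValueError(f"unknown phase {d.phase!r} for day {d.label!r}")
        order = [PHASES.index(d.phase) for d in self.days]
        if order != sorted(order):
            raise ValueError("phases must appear in BDC, HDT, R1, R2 order")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(d.label for d in self.days)

    def phase_of(self, label: str) -> str:
        label = normalize_day_label(label)
        for d in self.days:
            if d.label == label:
                return d.phase
        raise KeyError(f"day label {label!r} not in design")

    def day_number(self, label: str) -> float:
        label = normalize_day_label(label)
        for d in self.days:
            if d.label == label:
                return d.day
        raise KeyError(f"day label {label!r} not in design")


#: Sampling schedule of the NUC bed-rest study: BDC-6/-2, HDT 2/10/21,
#: recovery R+0/+2/+5 and follow-ups R+14/+28.
NUC_DESIGN = StudyDesign(
    days=(
        DesignDay("BDC-6", "BDC", -6.0),
        DesignDay("BDC-2", "BDC", -2.0),
        DesignDay("HDT02", "HDT", 2.0),
        DesignDay("HDT10", "HDT", 10.0),
        DesignDay("HDT21", "HDT", 21.0),
        DesignDay("R+0", "R1", 21.0),
        DesignDay("R+02", "R1", 23.0),
        DesignDay("R+05", "R1", 26.0),
        DesignDay("R+14", "R2", 35.0),
        DesignDay("R+28", "R2", 49.0),
    )
)

_DAY_RE = re.compile(r"^(BDC-|HDT|R\+)(\d+)$")


def normalize_day_label(label: str) -> str:
    """Canonicalise a day label (HDT2 -> HDT02, R+2 -> R+02, R+14 -> R+14).

    HDT days and single-digit recovery days other than R+0 are zero-padded
    to two digits, matching the usual contrast-table printing.
    """
    label = label.strip()
    m = _DAY_RE.match(label)
    if m is None:
        return label
    prefix, num = m.group(1), int(m.group(2))
    if prefix == "BDC-":
        return f"BDC-{num}"
    if prefix == "R+" and num == 0:
        return "R+0"
    return f"{prefix}{num:02d}"


@dataclass(frozen=True)
class Subject:
    """One individual with baseline renal/isotopic physiology.

    ``f_excreted_baseline`` is the fraction of the filtered Ca load that
    escapes tubular reabsorption at steady state; ``filtered_load`` is the
    Ca reaching primary urine per day (mmol/d), so baseline excretion is
    their product.
    """

    id: str
    f_excreted_baseline: float
    delta_blood_baseline: DeltaValue
    filtered_load: float = 220.0
    diet_ca: float = 26.8
    supplemented: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "delta_blood_baseline", as_delta(self.delta_blood_baseline)
        )
        if not 0.0 < self.f_excreted_baseline < 0.1:
            raise ValueError(
                f"f_excreted_baseline must lie in (0, 0.1), got {self.f_excreted_baseline}"
            )
        if not self.filtered_load > 0:
            raise ValueError(f"filtered_load must be positive, got {self.filtered_load}")
        if not self.diet_ca > 0:
            raise ValueError(f"diet_ca must be positive, got {self.diet_ca}")


@dataclass(frozen=True)
class CohortParams:
    """Population distributions the cohort is drawn from.

    f_range
        Baseline excreted fraction, log-uniform.  The default span (factor
        ~7) reproduces the observed factor ~4.3 spread of daily Ca excretion
        between seven subjects and, through the Rayleigh law, a baseline
        urinary delta span of roughly half a permil across the cohort.
    delta_blood_mean, delta_blood_sd
        Blood delta44/42 baseline (permil).  The small default scatter
        reflects tight homeostatic regulation of blood Ca; inter-individual
        urine differences are dominated by renal reabsorption.
    diet_ca_range
        Controlled dietary Ca intake, mmol/d (25-28.7 = 1000-1150 mg/d).
    filtered_load
        Daily Ca load of primary urine, mmol/d, common to all subjects.
    """

    f_range: tuple[float, float] = (0.008, 0.055)
    delta_blood_mean: float = 0.40
    delta_blood_sd: float = 0.02
    diet_ca_range: tuple[float, float] = (25.0, 28.7)
    filtered_load: float = 220.0

    def __post_init__(self) -> None:
        lo, hi = self.f_range
        if not (0.0 < lo <= hi < 0.1):
            raise ValueError(f"f_range must satisfy 0 < lo <= hi < 0.1, got {self.f_range}")
        lo, hi = self.diet_ca_range
        if not (0.0 < lo <= hi):
            raise ValueError(f"invalid diet_ca_range {self.diet_ca_range}")
        if self.delta_blood_sd < 0:
            raise ValueError("delta_blood_sd must be non-negative")
        if not self.filtered_load > 0:
            raise ValueError("filtered_load must be positive")


@dataclass(frozen=True)
class BoneResponseParams:
    """Bed-rest bone response and its coupling into urine.

    Disuse-induced resorption releases isotopically light bone Ca into blood
    at up to ``resorption_flux_max`` mmol/d, starting ``onset_delay`` days
    after the start of bed rest, ramping linearly over ``ramp_time`` days,
    and decaying (same ramp) ``recovery_delay`` days after re-ambulation.
    The extra Ca load raises the excreted fraction,
    f(t) = f_baseline * (1 + f_modulation_gain * flux_bone(t)/flux_diet),
    moving samples along the Rayleigh trajectory.  Subjects on the KHCO3
    countermeasure have the resorption flux multiplied by
    ``khco3_attenuation`` (illustrative, not an estimate).
    """

    resorption_flux_max: float = 5.9
    onset_delay: float = 12.0
    recovery_delay: float = 8.0
    ramp_time: float = 7.0
    delta_bone_offset: float = -0.3
    f_modulation_gain: float = 0.15
    khco3_attenuation: float = 0.5
    diet_absorption_fraction: float = 0.25
    ntx_baseline_mean: float = 450.0
    ntx_baseline_sd: float = 75.0
    ntx_per_bone_flux: float = 67.0
    ntx_noise_sd: float = 50.0

    def __post_init__(self) -> None:
        if self.resorption_flux_max < 0:
            raise ValueError("resorption_flux_max must be >= 0")
        for name in ("onset_delay", "recovery_delay", "ramp_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.diet_absorption_fraction <= 1.0:
            raise ValueError("diet_absorption_fraction must lie in (0, 1]")
        if not 0.0 <= self.khco3_attenuation <= 1.0:
            raise ValueError("khco3_attenuation must lie in [0, 1]")


@dataclass(frozen=True)
class UrineSample:
    """One 24-h pooled urine observation.

    ``delta_urine`` is the delta44/42 in permil vs SRM-915a, ``se`` its
    1-sigma measurement error, ``ca_excreted`` the daily Ca flux (mmol/24 h)
    and ``ntx`` the optional bone-resorption marker (nmol/d).
    """

    subject_id: str
    day_label: str
    phase: str
    delta_urine: float
    se: float
    ca_excreted: float
    ntx: float | None = None

    def __post_init__(self) -> None:
        if not self.ca_excreted > 0:
            raise ValueError(f"ca_excreted must be positive, got {self.ca_excreted}")
        if self.se < 0:
            raise ValueError(f"se must be non-negative, got {self.se}")


SAMPLE_COLUMNS = (
    "subject_id",
    "day_label",
    "phase",
    "delta4442_permil",
    "se_permil",
    "ca_excreted_mmol_d",
    "ntx_nmol_d",
)

SUBJECT_COLUMNS = (
    "subject_id",
    "f_excreted_baseline",
    "delta_blood_permil",
    "filtered_load_mmol_d",
    "diet_ca_mmol_d",
    "supplemented",
)

# NUC-style subject labels and KHCO3 arm for the default seven-subject cohort
# (four supplemented, three controls).
_NUC_IDS = ("A", "B", "C", "D", "F", "G", "H")
_NUC_SUPPLEMENTED = frozenset({"B", "D", "F", "H"})


def generate_cohort(
    n_subjects: int,
    params: CohortParams = CohortParams(),
    seed: int | np.random.SeedSequence | None = None,
) -> list[Subject]:
    """Draw a cohort of subjects from the configured population.

    The excreted fraction is log-uniform over ``params.f_range``, blood delta
    is normal, and dietary Ca is uniform.  Deterministic for a fixed seed.
    A seven-subject cohort uses study-style ids A..H (no E) with subjects
    B, D, F, H on the KHCO3 arm; other sizes alternate arms.
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = params.f_range
    f = np.exp(rng.uniform(math.log(lo), math.log(hi), n_subjects))
    blood = rng.normal(params.delta_blood_mean, params.delta_blood_sd, n_subjects)
    diet = rng.uniform(*params.diet_ca_range, n_subjects)
    if n_subjects == len(_NUC_IDS):
        ids = list(_NUC_IDS)
        suppl = [i in _NUC_SUPPLEMENTED for i in ids]
    else:
        ids = [f"S{i + 1:02d}" for i in range(n_subjects)]
        suppl = [i % 2 == 0 for i in range(n_subjects)]
    return [
        Subject(
            id=ids[i],
            f_excreted_baseline=float(f[i]),
            delta_blood_baseline=DeltaValue(float(blood[i])),
            filtered_load=params.filtered_load,
            diet_ca=float(diet[i]),
            supplemented=suppl[i],
        )
        for i in range(n_subjects)
    ]


def blood_mixing_delta(
    flux_diet: float,
    delta_diet_absorbed: "float | DeltaValue",
    flux_bone: float,
    delta_bone: "float | DeltaValue",
) -> DeltaValue:
    """Blood delta as the flux-weighted mean of dietary and bone Ca inputs.

    Linear mixing in permil is used; at these magnitudes (deltas below a few
    permil, flux ratios of order 1) the error versus exact ratio-space mixing
    is below 0.02 permil and is accepted.
    """
    if flux_diet < 0 or flux_bone < 0:
        raise ValueError("fluxes must be non-negative")
    total = flux_diet + flux_bone
    if total == 0:
        raise ValueError("at least one input flux must be positive")
    dd = as_delta(delta_diet_absorbed).value
    db = as_delta(delta_bone).value
    return DeltaValue((flux_diet * dd + flux_bone * db) / total)


def bone_resorption_flux(
    t: float, bone: BoneResponseParams, bed_rest_end: float = 21.0
) -> float:
    """Bone Ca release (mmol/d) at study day ``t`` (bed rest starts at 0).

    Zero before ``onset_delay``, linear ramp to the plateau over
    ``ramp_time``, and a mirrored linear decay starting ``recovery_delay``
    days after ``bed_rest_end``.
    """
    if t <= 0:
        return 0.0
    if bone.ramp_time > 0:
        up = min(max((t - bone.onset_delay) / bone.ramp_time, 0.0), 1.0)
        down = min(max((t - bed_rest_end - bone.recovery_delay) / bone.ramp_time, 0.0), 1.0)
    else:
        up = 1.0 if t >= bone.onset_delay else 0.0
        down = 1.0 if t >= bed_rest_end + bone.recovery_delay else 0.0
    return bone.resorption_flux_max * min(up, 1.0 - down)


def simulate_timecourse(
    cohort: Sequence[Subject],
    design: StudyDesign = NUC_DESIGN,
    bone: BoneResponseParams = BoneResponseParams(),
    alpha: float = DEFAULT_ALPHA,
    noise_se: float = 0.05,
    seed: int | np.random.SeedSequence | None = None,
    include_ntx: bool = True,
) -> list[UrineSample]:
    """Simulate urine samples for every subject on every design day.

    For each subject and day the bone flux follows the delayed ramp schedule;
    blood delta is the flux-weighted mixture of absorbed dietary Ca (at the
    subject's baseline composition) and isotopically light bone Ca; the
    excreted fraction rises with the excess Ca load; urinary delta follows
    the Rayleigh law plus Gaussian measurement noise of sd ``noise_se``; and
    excretion is exactly filtered_load * f(t).  NTX rises linearly with the
    bone flux plus independent noise, emulating the weak observed coupling
    between the isotope and collagen-marker responses.

    Deterministic for fixed (cohort, parameters, seed).
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    if noise_se < 0:
        raise ValueError("noise_se must be non-negative")
    rng = np.random.default_rng(seed)
    samples: list[UrineSample] = []
    for subj in cohort:
        flux_diet = bone.diet_absorption_fraction * subj.diet_ca
        delta_bone = subj.delta_blood_baseline.value + bone.delta_bone_offset
        flux_max = bone.resorption_flux_max * (
            bone.khco3_attenuation if subj.supplemented else 1.0
        )
        subj_bone = replace(bone, resorption_flux_max=flux_max)
        ntx_base = rng.normal(bone.ntx_baseline_mean, bone.ntx_baseline_sd)
        for d in design.days:
            flux = bone_resorption_flux(d.day, subj_bone, design.bed_rest_end)
            blood = blood_mixing_delta(
                flux_diet, subj.delta_blood_baseline, flux, delta_bone
            )
            f_t = subj.f_excreted_baseline * (
                1.0 + bone.f_modulation_gain * flux / flux_diet
            )
            if not 0.0 < f_t < 1.0:
                raise ValueError(
                    f"f(t) = {f_t:.4g} driven outside (0, 1) for subject "
                    f"{subj.id} on {d.label}"
                )
            delta = rayleigh_urine_delta(
                FractionationContext(blood, f_t, alpha)
            ).value
            delta += rng.normal(0.0, noise_se) if noise_se > 0 else 0.0
            ntx = None
            if include_ntx:
                ntx = float(
                    ntx_base
                    + bone.ntx_per_bone_flux * flux
                    + rng.normal(0.0, bone.ntx_noise_sd)
                )
            samples.append(
                UrineSample(
                    subject_id=subj.id,
                    day_label=d.label,
                    phase=d.phase,
                    delta_urine=float(delta),
                    se=noise_se,
                    ca_excreted=float(subj.filtered_load * f_t),
                    ntx=ntx,
                )
            )
    return samples


def samples_to_frame(samples: Iterable[UrineSample]) -> pd.DataFrame:
    """Tabulate samples with the canonical CSV column names."""
    rows = [
        (
            s.subject_id,
            s.day_label,
            s.phase,
            s.delta_urine,
            s.se,
            s.ca_excreted,
            s.ntx if s.ntx is not None else np.nan,
        )
        for s in samples
    ]
    return pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))


def _validate_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def write_cohort_csv(samples: "Iterable[UrineSample] | pd.DataFrame", path) -> None:
    """Write samples as UTF-8 CSV with the canonical header (lossless floats)."""
    df = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    _validate_columns(df, SAMPLE_COLUMNS, "sample table")
    df = df.loc[:, list(SAMPLE_COLUMNS)]
    df.to_csv(path, index=False, encoding="utf-8")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a sample CSV, validating the schema.

    Returns a DataFrame with the canonical columns; ``ntx_nmol_d`` is NaN
    where blank.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected a header row") from exc
    _validate_columns(df, SAMPLE_COLUMNS, f"{path}")
    if len(df) > 0:
        for col in ("delta4442_permil", "se_permil", "ca_excreted_mmol_d"):
            if df[col].isna().any():
                raise SchemaError(f"{path}: column {col} contains missing values")
        if (df["ca_excreted_mmol_d"] <= 0).any():
            raise SchemaError(f"{path}: column ca_excreted_mmol_d must be positive")
    return df.loc[:, list(SAMPLE_COLUMNS)]


def write_subjects_csv(cohort: Sequence[Subject], path) -> None:
    """Write per-subject physiology (including arm assignment) as CSV."""
    rows = [
        (
            s.id,
            s.f_excreted_baseline,
            s.delta_blood_baseline.value,
            s.filtered_load,
            s.diet_ca,
            s.supplemented,
        )
        for s in cohort
    ]
    pd.DataFrame(rows, columns=list(SUBJECT_COLUMNS)).to_csv(
        path, index=False, encoding="utf-8"
    )


def read_subjects_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected a header row") from exc
    _validate_columns(df, SUBJECT_COLUMNS, f"{path}")
    return df.loc[:, list(SUBJECT_COLUMNS)]
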