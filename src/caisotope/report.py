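"""Summary reporting: per-phase distributions, per-arm changes, diagnostics."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .baseline import BaselineTrendResults
from .cohort import NUC_DESIGN, StudyDesign
from .timecourse import _coerce_frame

__all__ = ["phase_summary", "arm_mean_change", "render_report"]


def phase_summary(samples) -> pd.DataFrame:
    """Per-subject, per-phase distribution of delta (min/median/max/IQR/n)."""
    df = _coerce_frame(samples)
    if len(df) == 0:
        raise ValueError("empty sample table")
    g = df.groupby(["subject_id", "phase"])["delta4442_permil"]
    out = g.agg(
        min="min",
        median="median",
        max="max",
        iqr=lambda v: float(np.subtract(*np.percentile(v, [75, 25]))),
        n="count",
    ).reset_index()
    return out


def arm_mean_change(
    samples, subjects: pd.DataFrame, design: StudyDesign = NUC_DESIGN
) -> pd.DataFrame:
    """Mean change from each subject's BDC baseline, by countermeasure arm.

    The change is averaged over the bed-rest and inpatient-recovery days
    (HDT + R1), the window where the bone response is expressed.
    """
    df = _coerce_frame(samples).copy()
    arm = subjects.set_index("subject_id")["supplemented"]
    missing = sorted(set(df["subject_id"]) - set(arm.index))
    if missing:
        raise ValueError(f"subject(s) missing from subject table: {', '.join(missing)}")
    bdc = df[df["phase"] == "BDC"].groupby("subject_id")["delta4442_permil"].mean()
    window = df[df["phase"].isin(["HDT", "R1"])].copy()
    window["change"] = window["delta4442_permil"] - window["subject_id"].map(bdc).to_numpy(
        float
    )
    window["arm"] = [
        "supplemented" if arm[s] else "control" for s in window["subject_id"]
    ]
    per_subject = window.groupby(["arm", "subject_id"])["change"].mean().reset_index()
    out = (
        per_subject.groupby("arm")["change"]
        .agg(mean_change_permil="mean", n_subjects="count")
        .reset_index()
    )
    return out


def render_report(
    samples,
    subjects: Optional[pd.DataFrame] = None,
    baseline: Optional[BaselineTrendResults] = None,
    design: StudyDesign = NUC_DESIGN,
) -> str:
    """Plain-text study report (all values to 4 decimal places)."""
    df = _coerce_frame(samples)
    if len(df) == 0:
        raise ValueError("empty sample table: nothing to report")
    lines = [
        "Urinary Ca isotope study report",
        "===============================",
        f"samples: {len(df)}   subjects: {df['subject_id'].nunique()}",
        "",
        "Per-subject, per-phase delta44/42 (permil):",
        f"{'subject':>8} {'phase':>6} {'min':>9} {'median':>9} {'max':>9} {'IQR':>9} {'n':>3}",
    ]
    for r in phase_summary(df).itertuples():
        lines.append(
            f"{r.subject_id:>8} {r.phase:>6} {r.min:9.4f} {r.median:9.4f} "
            f"{r.max:9.4f} {r.iqr:9.4f} {r.n:3d}"
        )
    if subjects is not None:
        lines += ["", "Mean change from BDC baseline over HDT+R1, by arm:"]
        for r in arm_mean_change(df, subjects, design).itertuples():
            lines.append(
                f"  {r.arm:>12}: {r.mean_change_permil:8.4f} permil "
                f"(n={r.n_subjects})"
            )
    if baseline is not None:
        lines += ["", "Diagnostic calls against the supplied baseline:"]
        calls = baseline.classify_frame(df)
        counts = calls["band_position"].value_counts()
        for pos in ("below", "within", "above"):
            lines.append(f"  {pos:>6}: {int(counts.get(pos, 0))}")
    return "\n".join(lines)
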