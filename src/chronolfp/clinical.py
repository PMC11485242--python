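"""Clinical-state definitions, responder criteria and cohort summaries.

Response to DBS is defined quantitatively as a ≥35% reduction of the
Yale-Brown Obsessive-Compulsive Scale (Y-BOCS).  Day-level clinical labels
come from manually curated state intervals; the burdened/unburdened
dichotomy used by the pooled statistics and the classifier pools pre-DBS
days with post-DBS non-responder days (burdened) against post-DBS response
days (unburdened).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    BURDENED,
    DISINHIBITED,
    PERSISTENT,
    PRE_DBS,
    RESPONSE,
    UNBURDENED,
    UNLABELED,
    StateInterval,
)

RESPONDER_THRESHOLD_PCT = 35.0


@dataclass
class PatientMeta:
    """Demographic/outcome row for one patient (cohort-summary input)."""

    patient_id: str
    gender: str
    age_at_surgery: float
    followup_months: float
    responder: bool
    lfp_days_L: int
    lfp_days_R: int
    cohort: int = 1

    def __post_init__(self) -> None:
        if self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")
        if self.lfp_days_L < 0 or self.lfp_days_R < 0:
            raise ValueError("recording day counts must be >= 0")


def percent_reduction(initial: float, final: float) -> float:
    """Percent score reduction, 100·(initial − final)/initial, to 2 decimals."""
    if initial <= 0:
        raise ValueError("initial score must be positive")
    return round(100.0 * (initial - final) / initial, 2)


def responder_status(initial: float, final: float,
                     threshold: float = RESPONDER_THRESHOLD_PCT) -> bool:
    """True iff the percent reduction meets the threshold (inclusive ≥)."""
    return percent_reduction(initial, final) >= threshold


def day_labels(intervals: list[StateInterval], day_range) -> pd.DataFrame:
    """Map each day to its clinical state and the burdened/unburdened dichotomy.

    ``day_range`` is an iterable of day indices relative to DBS activation.
    Days outside every interval are ``unlabeled``; disinhibited and
    unlabeled days belong to neither dichotomy class (dichotomy = NaN).
    """
    days = np.asarray(list(day_range), dtype=int)
    spans = sorted(intervals, key=lambda iv: iv.start_day)
    for a, b in zip(spans, spans[1:]):
        if b.start_day <= a.end_day:
            raise ValueError(
                f"overlapping intervals: {a.state}[{a.start_day},{a.end_day}] "
                f"and {b.state}[{b.start_day},{b.end_day}]")
    states = np.full(len(days), UNLABELED, dtype=object)
    for iv in spans:
        states[(days >= iv.start_day) & (days <= iv.end_day)] = iv.state
    dicho = np.full(len(days), None, dtype=object)
    dicho[np.isin(states, [PRE_DBS, PERSISTENT])] = BURDENED
    dicho[states == RESPONSE] = UNBURDENED
    return pd.DataFrame({"day": days, "state": states, "dichotomy": dicho})


def cohort_summary(metas: list[PatientMeta], followup_cutoff_months: float = 6.0
                   ) -> dict:
    """Cohort-level summary statistics.

    Follow-up counts use a strict ``> cutoff`` rule.  Each patient's total
    recording duration is ``max(left, right)`` recording days.  SDs are
    sample SDs (ddof=1) and NaN for singleton groups.
    """
    if not metas:
        raise ValueError("need at least one patient")
    df = pd.DataFrame([vars(m) for m in metas])
    df["total_days"] = df[["lfp_days_L", "lfp_days_R"]].max(axis=1)

    long_fu = df[df["followup_months"] > followup_cutoff_months]
    n_long = len(long_fu)
    out = {
        "n_patients": len(df),
        "n_followup_gt_cutoff": n_long,
        "responder_count_gt_cutoff": int(long_fu["responder"].sum()),
        "responder_fraction_gt_cutoff":
            float(long_fu["responder"].mean()) if n_long else float("nan"),
        "mean_followup_months": float(long_fu["followup_months"].mean())
            if n_long else float("nan"),
        "sd_followup_months": float(long_fu["followup_months"].std(ddof=1))
            if n_long > 1 else float("nan"),
        "grand_total_recording_hours": float(df["total_days"].sum() * 24),
    }
    for cohort, g in df.groupby("cohort"):
        out[f"cohort{cohort}_mean_total_days"] = float(g["total_days"].mean())
        out[f"cohort{cohort}_sd_total_days"] = (
            float(g["total_days"].std(ddof=1)) if len(g) > 1 else float("nan"))
    return out


def example_cohort_table() -> pd.DataFrame:
    """The published 12-patient OCD DBS demo cohort (demographics/outcomes).

    Columns mirror the study's demographics table: Y-BOCS-II and Y-BOCS
    initial/final scores (NaN where not administered), follow-up months and
    per-hemisphere chronic recording day counts.  Used by the worked
    examples and the summary-arithmetic checks.
    """
    rows = [
        # pid, gender, age, fu_mo, responder, yb2_i, yb_i, yb2_f, yb_f, L, R, cohort
        ("B001", "F", 42, 35, True,  41, 40, 26, 24, 150, 150, 1),
        ("B002", "F", 31, 13, False, 44, 37, 42, 35,  99, 210, 1),
        ("B004", "M", 31, 25, True,  np.nan, 34, 21, 15, 411,  11, 1),
        ("B005", "M", 20, 20, True,  42, 34, 14, 12, 380, 380, 1),
        ("B006", "F", 55, 22, False, 43, 38, 35, 31, 344, 432, 1),
        ("B007", "M", 23, 19, True,  35, 28,  9,  8,  15,  59, 2),
        ("B008", "F", 33, 12, False, 36, 31, 26, 24, 138, 117, 2),
        ("B009", "F", 31, 36, True,  48, 38,  4,  4, 120, 120, 2),
        ("B010", "F", 21,  1, False, 32, 30, 30, 26,  24,  24, 2),
        ("U001", "F", 33,  4, False, np.nan, 34, np.nan, 31, 69, 69, 2),
        ("U002", "M", 23,  5, True,  np.nan, 30, np.nan, 15, 16, 30, 2),
        ("U003", "F", 24,  1, False, np.nan, 36, np.nan, 34, 29, 29, 2),
    ]
    return pd.DataFrame(rows, columns=[
        "patient_id", "gender", "age_at_surgery", "followup_months",
        "responder", "ybocs2_initial", "ybocs_initial", "ybocs2_final",
        "ybocs_final", "lfp_days_L", "lfp_days_R", "cohort",
    ])


def metas_from_table(table: pd.DataFrame) -> list[PatientMeta]:
    """Convert a demographics table into :class:`PatientMeta` rows."""
    return [
        PatientMeta(
            patient_id=r.patient_id, gender=r.gender,
            age_at_surgery=float(r.age_at_surgery),
            followup_months=float(r.followup_months),
            responder=bool(r.responder),
            lfp_days_L=int(r.lfp_days_L), lfp_days_R=int(r.lfp_days_R),
            cohort=int(r.cohort),
        )
        for r in table.itertuples()
    ]
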