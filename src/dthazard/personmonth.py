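"""Person-month expansion and survey-weighted score standardization.

The analysis backbone is the discrete-time person-month array: every subject
contributes one row per month under observation, inclusive of the month of
first event; the event indicator is 1 only on that final row. Subjects are
censored after the month of first occurrence, attrition, or the
administrative cutoff, whichever comes first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SurveyDesign",
    "PERSON_MONTH_COLUMNS",
    "expand_to_person_months",
    "standardize_scores",
    "validate_person_months",
    "write_person_months",
    "read_person_months",
]

PERSON_MONTH_COLUMNS = [
    "subject_id",
    "month",
    "score_A",
    "score_S",
    "event",
    "weight",
    "cluster_id",
]


@dataclass(frozen=True)
class SurveyDesign:
    """Survey design: one weight and one sampling cluster per subject.

    ``weights`` and ``clusters`` are aligned pandas Series indexed by
    subject_id; ``strata`` is an optional label series (single-stratum designs
    leave it None).
    """

    weights: pd.Series
    clusters: pd.Series
    strata: pd.Series | None = None

    def __post_init__(self):
        if not self.weights.index.equals(self.clusters.index):
            raise ValueError("weights and clusters must be indexed by the same subjects")
        if self.weights.index.has_duplicates:
            raise ValueError("each subject must have exactly one weight and cluster")
        if (self.weights <= 0).any() or not np.isfinite(self.weights).all():
            raise ValueError("weights must be positive and finite")

    @classmethod
    def from_subjects(cls, subjects: pd.DataFrame) -> "SurveyDesign":
        idx = pd.Index(subjects["subject_id"], name="subject_id")
        return cls(
            weights=pd.Series(subjects["weight"].to_numpy(), index=idx),
            clusters=pd.Series(subjects["cluster_id"].to_numpy(), index=idx),
        )


def expand_to_person_months(
    subjects: pd.DataFrame,
    scores: pd.DataFrame,
    design: SurveyDesign | None = None,
) -> pd.DataFrame:
    """Expand subject records into the discrete-time person-month array.

    Parameters
    ----------
    subjects : one row per subject with subject_id, static_score, event_month,
        last_observed_month (plus weight/cluster_id if ``design`` is None).
    scores : long table (subject_id, month, score_A) covering every observed
        subject-month.
    design : optional survey design supplying weights and clusters; defaults
        to the columns embedded in ``subjects``.

    Returns a DataFrame with columns ``PERSON_MONTH_COLUMNS``: months run
    0..last_observed_month per subject, and ``event`` is 1 only on the event
    month (which, when present, is the subject's final row).
    """
    if design is None:
        design = SurveyDesign.from_subjects(subjects)

    ev = subjects["event_month"]
    last = subjects["last_observed_month"]
    bad = ev.notna() & (ev.astype("Int64") > last)
    if bad.any():
        raise ValueError("event_month exceeds last_observed_month for some subjects")

    n_rows = (last.to_numpy() + 1).astype(int)
    sid = np.repeat(subjects["subject_id"].to_numpy(), n_rows)
    month = np.concatenate([np.arange(k) for k in n_rows]) if len(n_rows) else np.array([], int)

    out = pd.DataFrame({"subject_id": sid, "month": month})
    out = out.merge(scores[["subject_id", "month", "score_A"]], on=["subject_id", "month"], how="left")
    if out["score_A"].isna().any():
        raise ValueError("scores table is missing observed subject-months")

    per_subject = subjects.set_index("subject_id")
    out["score_S"] = per_subject["static_score"].reindex(out["subject_id"]).to_numpy()
    ev_arr = (
        per_subject["event_month"]
        .astype("Float64")
        .reindex(out["subject_id"])
        .to_numpy(dtype=float, na_value=np.nan)
    )
    out["event"] = (out["month"].to_numpy() == ev_arr).astype(int)  # NaN compares False
    out["weight"] = design.weights.reindex(out["subject_id"]).to_numpy()
    out["cluster_id"] = design.clusters.reindex(out["subject_id"]).to_numpy()
    return out[PERSON_MONTH_COLUMNS]


def weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted mean and (population-style) weighted variance."""
    w = np.asarray(w, float)
    x = np.asarray(x, float)
    m = float(np.average(x, weights=w))
    v = float(np.average((x - m) ** 2, weights=w))
    return m, v


def standardize_scores(
    array: pd.DataFrame, design: SurveyDesign | None = None
) -> pd.DataFrame:
    """Standardize both scores to weighted mean 0, weighted variance 1.

    The monthly score A varies within subject and is standardized over
    person-month rows; the static score S is constant within subject and is
    standardized over subjects, so each subject keeps a single standardized
    value. Both use survey weights; rescaling every weight by a constant
    leaves the result unchanged.
    """
    out = array.copy()
    w_rows = out["weight"].to_numpy()

    m_a, v_a = weighted_mean_var(out["score_A"].to_numpy(), w_rows)
    if v_a <= 0:
        raise ValueError("score_A has zero weighted variance; cannot standardize")
    out["score_A"] = (out["score_A"] - m_a) / np.sqrt(v_a)

    per_subject = out.drop_duplicates("subject_id")
    m_s, v_s = weighted_mean_var(
        per_subject["score_S"].to_numpy(), per_subject["weight"].to_numpy()
    )
    if v_s <= 0:
        raise ValueError("score_S has zero weighted variance; cannot standardize")
    out["score_S"] = (out["score_S"] - m_s) / np.sqrt(v_s)
    return out


def validate_person_months(array: pd.DataFrame) -> None:
    """Check the structural invariants of a person-month array."""
    grouped = array.groupby("subject_id", sort=False)
    months_ok = grouped["month"].agg(lambda m: (m.to_numpy() == np.arange(len(m))).all())
    if not months_ok.all():
        raise ValueError("per-subject months must be consecutive from 0")
    n_events = grouped["event"].sum()
    if (n_events > 1).any():
        raise ValueError("at most one event row per subject")
    last_event_ok = grouped.apply(
        lambda g: g["event"].sum() == 0 or g["event"].to_numpy()[-1] == 1,
        include_groups=False,
    )
    if not last_event_ok.all():
        raise ValueError("the event row must be the subject's last row")


def write_person_months(array: pd.DataFrame, path: str | Path) -> None:
    array[PERSON_MONTH_COLUMNS].to_csv(path, index=False)


def read_person_months(path: str | Path) -> pd.DataFrame:
    out = pd.read_csv(path)
    missing = set(PERSON_MONTH_COLUMNS) - set(out.columns)
    if missing:
        raise ValueError(f"person-month table missing columns: {sorted(missing)}")
    return out[PERSON_MONTH_COLUMNS]
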