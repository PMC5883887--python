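"""Ventile construction and concentration-of-risk / PPV evaluation.

Respondents are ranked by a per-person risk summary from a fitted hazard
model and divided into 20 weighted ventiles of 5% of the (weighted)
population each, ventile 20 highest risk. For each ventile the evaluation
reports:

* concentration of risk — the percentage of all observed cases falling in
  the ventile (5% expected by chance);
* observed PPV — events per 1000 person-months at risk in the ventile;
* projected PPV — cases per 1000 soldiers projected to 36 months by the
  actuarial method, adjusting for variable follow-up;

plus cumulative top-1/2/3-ventile aggregates and the proportional
improvement of one model over another, (best/base - 1) x 100.

The per-person ranking score is the predicted 36-month cumulative risk
``1 - prod_m (1 - h_m)``: observed months use the fitted monthly hazards;
months beyond a subject's observation are extrapolated with the fitted time
effects, carrying the subject's mean observed administrative score forward.
Carrying the *last* observed score is available behind a flag but is not the
default: a first event truncates observation in a month where the monthly
score tends to be high, so the last value is outcome-contaminated and
systematically flatters monthly-score-heavy models in within-sample
evaluation. A simpler mean-log-odds summary is also available.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .actuarial import MAX_HORIZON, projected_ppv
from .model import HazardResults
from .personmonth import SurveyDesign

__all__ = [
    "person_risk_summary",
    "assign_ventiles",
    "concentration_of_risk",
    "observed_ppv",
    "proportional_improvement",
    "ventile_report",
    "top_k",
    "N_VENTILES",
]

N_VENTILES = 20


def _extended_array(array: pd.DataFrame, horizon: int, carry: str) -> pd.DataFrame:
    """Person-month rows padded to ``horizon`` months per subject, carrying
    an administrative-score value forward for extrapolated months."""
    per = array.groupby("subject_id", sort=False).agg(
        last_month=("month", "max"),
        score_S=("score_S", "first"),
        weight=("weight", "first"),
        cluster_id=("cluster_id", "first"),
    )
    if carry == "mean":
        per["carry_A"] = array.groupby("subject_id", sort=False)["score_A"].mean()
    else:
        last_rows = array.loc[
            array.groupby("subject_id", sort=False)["month"].idxmax(),
            ["subject_id", "score_A"],
        ].set_index("subject_id")
        per["carry_A"] = last_rows["score_A"]

    n_extra = (horizon - 1 - per["last_month"]).clip(lower=0).astype(int)
    sid = np.repeat(per.index.to_numpy(), n_extra.to_numpy())
    month = np.concatenate(
        [np.arange(lm + 1, lm + 1 + k) for lm, k in zip(per["last_month"], n_extra)]
    ) if len(per) else np.array([], int)
    extra = pd.DataFrame({"subject_id": sid, "month": month})
    for col, src in (
        ("score_A", "carry_A"),
        ("score_S", "score_S"),
        ("weight", "weight"),
        ("cluster_id", "cluster_id"),
    ):
        extra[col] = per[src].reindex(extra["subject_id"]).to_numpy()
    extra["event"] = 0

    base = array[array["month"] < horizon]
    return pd.concat([base, extra[base.columns]], ignore_index=True)


def person_risk_summary(
    fit: HazardResults,
    array: pd.DataFrame,
    horizon: int = MAX_HORIZON,
    method: str = "cumulative",
    carry: str = "mean",
) -> pd.Series:
    """One predicted-risk score per person from a fitted hazard model.

    ``method="cumulative"`` (default): predicted cumulative risk over
    ``horizon`` months, 1 - prod(1 - h_m). ``method="mean_log_odds"``: the
    mean monthly linear predictor. ``carry`` chooses the administrative-score
    value used for months beyond observation: the subject's ``"mean"``
    observed value (default; robust to the event-month contamination
    described in the module docstring) or the ``"last"`` observed value.
    """
    if method not in ("cumulative", "mean_log_odds"):
        raise ValueError("method must be 'cumulative' or 'mean_log_odds'")
    if carry not in ("mean", "last"):
        raise ValueError("carry must be 'mean' or 'last'")
    counts = array.groupby("subject_id", sort=False)["month"].count()
    if (counts < 1).any() or len(counts) == 0:
        raise ValueError("every person needs at least one observed month")

    ext = _extended_array(array, horizon, carry)
    eta = fit.predict_log_odds(ext)
    df = pd.DataFrame({"subject_id": ext["subject_id"].to_numpy(), "eta": eta})
    if method == "mean_log_odds":
        return df.groupby("subject_id", sort=False)["eta"].mean()
    df["log_surv"] = -np.logaddexp(0.0, df["eta"])  # log(1 - expit(eta))
    log_s = df.groupby("subject_id", sort=False)["log_surv"].sum()
    return 1.0 - np.exp(log_s)


def assign_ventiles(
    summaries: pd.Series,
    design: SurveyDesign | None = None,
    weights: pd.Series | None = None,
    n_ventiles: int = N_VENTILES,
) -> pd.Series:
    """Weighted ventile labels 1..20 (20 = highest risk).

    Cut points are weighted quantiles at 5% increments: persons are sorted by
    score (stable, so ties keep subject order) and each person's ventile is
    determined by the midpoint of its weight interval on the cumulative-weight
    scale. Boundary ties go to the lower ventile.
    """
    if len(summaries) < n_ventiles:
        raise ValueError(f"need at least {n_ventiles} persons to form ventiles")
    if weights is None:
        weights = (
            design.weights.reindex(summaries.index)
            if design is not None
            else pd.Series(1.0, index=summaries.index)
        )
    if summaries.nunique() == 1:
        warnings.warn(
            "all risk summaries are equal; ventiles assigned by stable subject order",
            stacklevel=2,
        )
    order = np.argsort(summaries.to_numpy(), kind="stable")
    w = weights.to_numpy(dtype=float)[order]
    mid = np.cumsum(w) - w / 2.0
    labels = np.minimum(
        (mid / w.sum() * n_ventiles).astype(int) + 1, n_ventiles
    )
    out = pd.Series(0, index=summaries.index, dtype=int)
    out.iloc[order] = labels
    return out


def concentration_of_risk(
    labels: pd.Series,
    subjects: pd.DataFrame,
    design: SurveyDesign | None = None,
    n_ventiles: int = N_VENTILES,
) -> pd.Series:
    """Percentage of all observed (weighted) cases falling in each ventile."""
    sub = subjects.set_index("subject_id") if "subject_id" in subjects else subjects
    if not labels.index.isin(sub.index).all():
        raise ValueError("labels index must match subjects")
    w = (
        design.weights.reindex(sub.index)
        if design is not None
        else sub["weight"]
    ).to_numpy(dtype=float)
    has_event = sub["event_month"].notna().to_numpy()
    total = float(w[has_event].sum())
    if total == 0:
        raise ValueError("no events observed; concentration undefined")
    lab = labels.reindex(sub.index).to_numpy()
    conc = np.zeros(n_ventiles)
    np.add.at(conc, lab[has_event] - 1, w[has_event])
    return pd.Series(
        100.0 * conc / total, index=pd.RangeIndex(1, n_ventiles + 1, name="ventile")
    )


def observed_ppv(
    labels: pd.Series,
    array: pd.DataFrame,
    design: SurveyDesign | None = None,
    n_ventiles: int = N_VENTILES,
) -> pd.Series:
    """Observed events per 1000 weighted person-months at risk, per ventile."""
    lab = labels.reindex(array["subject_id"]).to_numpy()
    if np.isnan(lab.astype(float)).any():
        raise ValueError("labels must cover every subject in the array")
    w = (
        design.weights.reindex(array["subject_id"]).to_numpy()
        if design is not None
        else array["weight"].to_numpy(dtype=float)
    )
    ev = array["event"].to_numpy(dtype=float)
    pm = np.zeros(n_ventiles)
    events = np.zeros(n_ventiles)
    np.add.at(pm, lab.astype(int) - 1, w)
    np.add.at(events, lab.astype(int) - 1, w * ev)
    if (pm == 0).any():
        empty = np.nonzero(pm == 0)[0] + 1
        raise ValueError(f"empty ventiles: {empty.tolist()}")
    return pd.Series(
        1000.0 * events / pm, index=pd.RangeIndex(1, n_ventiles + 1, name="ventile")
    )


def proportional_improvement(best: float, base: float) -> float:
    """Proportional improvement (best/base - 1) x 100, to one decimal."""
    if base <= 0:
        raise ValueError("base metric must be positive")
    return round((best / base - 1.0) * 100.0, 1)


def top_k(per_ventile: pd.Series, k: int, kind: str = "share") -> float:
    """Aggregate the top-k ventiles.

    ``kind="share"`` sums (concentration percentages); ``kind="rate"`` is not
    meaningful from per-ventile rates alone and is rejected — recompute rates
    on the pooled top-k subgroup instead.
    """
    if kind != "share":
        raise ValueError("top_k only aggregates additive shares")
    return float(per_ventile.loc[N_VENTILES - k + 1 :].sum())


def ventile_report(
    fits: dict[str, HazardResults],
    array: pd.DataFrame,
    subjects: pd.DataFrame,
    design: SurveyDesign | None = None,
    horizon: int = MAX_HORIZON,
    ranking_method: str = "cumulative",
    best_label: str = "best",
    base_label: str = "hads_only",
) -> pd.DataFrame:
    """Performance table for a set of fitted models.

    For each model label in ``fits`` and each ventile set (top 1, 2, 3):
    concentration of risk, observed PPV and projected PPV, plus the
    proportional improvement of ``best_label`` over ``base_label``.
    Rates for top-k sets are recomputed on the pooled top-k subgroup.
    """
    sub = subjects.set_index("subject_id") if "subject_id" in subjects else subjects
    rows = []
    for label, fit in fits.items():
        summaries = person_risk_summary(fit, array, horizon, ranking_method)
        labels = assign_ventiles(summaries, design=design,
                                 weights=sub["weight"] if design is None else None)
        conc = concentration_of_risk(labels, subjects, design)
        for k in (1, 2, 3):
            in_top = labels >= N_VENTILES - k + 1
            top_ids = labels.index[in_top]
            top_subjects = sub.loc[top_ids].reset_index()
            top_array = array[array["subject_id"].isin(set(top_ids))]
            w_top = top_array["weight"].to_numpy()
            rows.append(
                {
                    "model": label,
                    "ventile_set": f"top{k}",
                    "concentration_pct": top_k(conc, k),
                    "observed_ppv_per_1000pm": 1000.0
                    * float((w_top * top_array["event"]).sum())
                    / float(w_top.sum()),
                    "projected_ppv_per_1000": projected_ppv(
                        top_subjects, design=design, horizon=horizon
                    ),
                }
            )
    out = pd.DataFrame(rows)

    if best_label in fits and base_label in fits:
        improvements = []
        for k in (1, 2, 3):
            sel_best = (out["model"] == best_label) & (out["ventile_set"] == f"top{k}")
            sel_base = (out["model"] == base_label) & (out["ventile_set"] == f"top{k}")
            row = {"model": "improvement_pct", "ventile_set": f"top{k}"}
            for col in (
                "concentration_pct",
                "observed_ppv_per_1000pm",
                "projected_ppv_per_1000",
            ):
                row[col] = proportional_improvement(
                    float(out.loc[sel_best, col].iloc[0]),
                    float(out.loc[sel_base, col].iloc[0]),
                )
            improvements.append(row)
        out = pd.concat([out, pd.DataFrame(improvements)], ignore_index=True)
    return out
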