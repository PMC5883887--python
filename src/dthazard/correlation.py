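"""Within-month correlation between the two composite risk scores.

The administrative score updates monthly while the survey score is fixed at
enlistment, so their association drifts with time in service. This module
tracks the weighted Pearson correlation between the two scores among the
subjects observed in each month (months 36 and later pooled into a "36+"
cell, whose tail samples are individually too thin), summarizes the series
by quartiles, and measures the month trend as the Pearson correlation of
month index versus monthly correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationSeries",
    "within_month_correlations",
    "summarize_series",
    "trend_correlation",
    "POOLED_LABEL",
    "POOL_FROM_MONTH",
]

POOLED_LABEL = "36+"
POOL_FROM_MONTH = 36


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


@dataclass
class CorrelationSeries:
    """Monthly correlation series: months 0..35 plus the pooled "36+" cell.

    ``table`` has index [0..35, "36+"] (months with no data omitted) and
    columns ``r`` (weighted Pearson correlation; NaN where undefined) and
    ``n`` (subjects contributing).
    """

    table: pd.DataFrame

    def __post_init__(self):
        r = self.table["r"]
        if ((r < -1 - 1e-12) | (r > 1 + 1e-12)).any():
            raise ValueError("correlations must lie in [-1, 1]")

    @classmethod
    def from_values(cls, values, n: int | None = None) -> "CorrelationSeries":
        """Build a series from 37 raw values (months 0-35 then pooled 36+),
        e.g. a published monthly correlation column."""
        values = list(values)
        if len(values) != POOL_FROM_MONTH + 1:
            raise ValueError(f"expected {POOL_FROM_MONTH + 1} values, got {len(values)}")
        idx = list(range(POOL_FROM_MONTH)) + [POOLED_LABEL]
        return cls(pd.DataFrame({"r": values, "n": n if n is not None else np.nan},
                                index=idx))

    @property
    def defined(self) -> pd.Series:
        return self.table["r"].dropna()

    def monthly(self) -> pd.Series:
        """The non-pooled part of the series (integer month index)."""
        r = self.table["r"]
        return r[r.index != POOLED_LABEL]


def within_month_correlations(
    array: pd.DataFrame, min_subjects: int = 3
) -> CorrelationSeries:
    """Weighted Pearson correlation of score_A and score_S per month.

    One contribution per subject per month at risk; months >= 36 pooled into
    "36+". Months with fewer than ``min_subjects`` subjects, or zero variance
    in either score, are flagged undefined (NaN).
    """
    month = array["month"].to_numpy()
    key = np.where(month >= POOL_FROM_MONTH, -1, month)
    rows = []
    index = []
    for m in sorted(set(key.tolist())):
        sel = key == m
        label = POOLED_LABEL if m == -1 else int(m)
        n = int(sel.sum())
        if n < min_subjects:
            r = np.nan
        else:
            r = _weighted_pearson(
                array["score_A"].to_numpy()[sel],
                array["score_S"].to_numpy()[sel],
                array["weight"].to_numpy()[sel],
            )
        rows.append({"r": r, "n": n})
        index.append(label)
    table = pd.DataFrame(rows, index=index)
    # keep the pooled cell last
    if POOLED_LABEL in table.index:
        table = pd.concat([table.drop(index=POOLED_LABEL),
                           table.loc[[POOLED_LABEL]]])
    return CorrelationSeries(table)


def summarize_series(
    series: CorrelationSeries, interpolation: str = "lower"
) -> tuple[float, float, float]:
    """(median, 25% quartile, 75% quartile) over the defined monthly values,
    pooled "36+" cell included.

    The default ``interpolation="lower"`` takes quantiles as order statistics
    rounded down, the convention that reproduces the published quartile
    summaries of this series; "linear" is exposed for sensitivity.
    """
    values = series.defined.to_numpy(dtype=float)
    if len(values) == 0:
        raise ValueError("series has no defined months")
    q25, q50, q75 = np.percentile(values, [25, 50, 75], method=interpolation)
    return float(q50), float(q25), float(q75)


def trend_correlation(series: CorrelationSeries) -> float:
    """Pearson correlation between month index and monthly correlation.

    The pooled "36+" cell is excluded (its month index is undefined). A
    constant series has no defined trend: returns NaN with a warning.
    """
    monthly = series.monthly().dropna()
    if len(monthly) < 3:
        raise ValueError("need at least 3 defined months for a trend")
    x = monthly.index.to_numpy(dtype=float)
    y = monthly.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        warnings.warn("constant correlation series; trend undefined", stacklevel=2)
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])
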