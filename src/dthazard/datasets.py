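"""Published reference values used as worked-example inputs.

These are printed summary statistics from the large U.S. Army new-soldier
cohort study of violence-risk prediction that this package's analysis
emulates: the monthly correlation series between the administrative and
survey composite risk scores (three outcome profiles, months 0-35 plus a
pooled 36+ cell), and the ventile performance table (concentration of risk,
observed PPV per 1000 person-months, projected 36-month PPV per 1000
soldiers) for the administrative-only, survey-only and best combined models.

They serve as fixed inputs to the series-summary and
proportional-improvement operations; nothing in the package estimates them.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "published_monthly_correlations",
    "published_ventile_performance",
    "OUTCOMES",
]

OUTCOMES = ("physical_perpetration", "sexual_perpetration", "victimization")

# months 0..35 then the pooled 36+ cell (37 values per outcome)
_MONTHLY_R = {
    "physical_perpetration": [
        0.46, 0.45, 0.44, 0.42, 0.37, 0.39, 0.41, 0.42, 0.42, 0.41, 0.39, 0.39,
        0.38, 0.37, 0.36, 0.35, 0.34, 0.34, 0.34, 0.34, 0.34, 0.34, 0.34, 0.34,
        0.34, 0.35, 0.36, 0.35, 0.36, 0.36, 0.36, 0.36, 0.37, 0.38, 0.36, 0.34,
        0.36,
    ],
    "sexual_perpetration": [
        0.04, 0.03, 0.02, 0.03, 0.03, 0.04, 0.04, 0.04, 0.05, 0.05, 0.05, 0.06,
        0.06, 0.06, 0.07, 0.07, 0.07, 0.07, 0.07, 0.07, 0.07, 0.06, 0.06, 0.06,
        0.06, 0.07, 0.07, 0.07, 0.07, 0.07, 0.07, 0.07, 0.06, 0.06, 0.06, 0.05,
        0.06,
    ],
    "victimization": [
        0.34, 0.35, 0.34, 0.33, 0.33, 0.30, 0.26, 0.27, 0.28, 0.28, 0.27, 0.26,
        0.27, 0.26, 0.25, 0.24, 0.24, 0.24, 0.25, 0.26, 0.27, 0.27, 0.27, 0.26,
        0.26, 0.25, 0.24, 0.26, 0.25, 0.24, 0.22, 0.22, 0.24, 0.24, 0.25, 0.28,
        0.24,
    ],
}


def published_monthly_correlations() -> pd.DataFrame:
    """Monthly score-correlation series, one column per outcome profile.

    Index: months 0-35 followed by the pooled "36+" cell.
    """
    idx = list(range(36)) + ["36+"]
    return pd.DataFrame(_MONTHLY_R, index=idx)


# (outcome, panel, ventile_set) -> administrative-only, survey-only, best
# combined model, and the improvement figure as printed. Panels:
# concentration (%), observed_ppv (per 1000 person-months), projected_ppv
# (per 1000 soldiers at 36 months).
_VENTILE_CELLS = [
    # outcome, panel, set, hads_only, nss_only, best, printed_improvement
    ("physical_perpetration", "concentration", "top1", 33.9, 24.8, 39.5, 16.6),
    ("physical_perpetration", "concentration", "top2", 45.2, 38.4, 50.2, 11.2),
    ("physical_perpetration", "concentration", "top3", 52.3, 48.7, 56.3, 7.8),
    ("sexual_perpetration", "concentration", "top1", 20.7, 21.8, 26.1, 26.0),
    ("sexual_perpetration", "concentration", "top2", 32.4, 33.8, 42.0, 29.6),
    ("sexual_perpetration", "concentration", "top3", 35.5, 46.5, 51.8, 45.9),
    ("victimization", "concentration", "top1", 17.5, 27.6, 29.4, 67.9),
    ("victimization", "concentration", "top2", 32.1, 38.3, 41.3, 28.7),
    ("victimization", "concentration", "top3", 47.6, 47.9, 49.8, 4.8),
    ("physical_perpetration", "observed_ppv", "top1", 2.9, 2.2, 3.4, 17.2),
    ("physical_perpetration", "observed_ppv", "top2", 2.0, 1.7, 2.2, 10.0),
    ("physical_perpetration", "observed_ppv", "top3", 1.5, 1.4, 1.6, 6.7),
    ("sexual_perpetration", "observed_ppv", "top1", 1.2, 1.2, 1.5, 25.0),
    ("sexual_perpetration", "observed_ppv", "top2", 0.9, 1.0, 1.2, 33.3),
    ("sexual_perpetration", "observed_ppv", "top3", 0.7, 0.9, 1.0, 42.9),
    ("victimization", "observed_ppv", "top1", 6.8, 10.6, 11.5, 69.1),
    ("victimization", "observed_ppv", "top2", 6.3, 7.4, 8.1, 28.6),
    ("victimization", "observed_ppv", "top3", 6.2, 6.2, 6.5, 4.8),
    ("physical_perpetration", "projected_ppv", "top1", 68.2, 50.4, 79.1, 16.0),
    ("physical_perpetration", "projected_ppv", "top2", 46.0, 39.2, 51.0, 10.9),
    ("physical_perpetration", "projected_ppv", "top3", 35.5, 33.1, 38.4, 8.2),
    ("sexual_perpetration", "projected_ppv", "top1", 27.6, 29.0, 34.6, 25.4),
    ("sexual_perpetration", "projected_ppv", "top2", 21.6, 22.6, 27.9, 29.2),
    ("sexual_perpetration", "projected_ppv", "top3", 15.8, 20.7, 23.0, 45.6),
    ("victimization", "projected_ppv", "top1", 151.6, 225.9, 241.7, 59.4),
    ("victimization", "projected_ppv", "top2", 139.8, 163.8, 176.4, 26.2),
    ("victimization", "projected_ppv", "top3", 138.3, 139.0, 144.6, 4.6),
]


def published_ventile_performance() -> pd.DataFrame:
    """Ventile performance cells for the three outcome profiles.

    Columns: outcome, panel, ventile_set, hads_only, nss_only, best,
    printed_improvement. The printed improvement column is retained verbatim;
    a handful of printed cells are not reproducible from the rounded
    hads_only/best pair (e.g. 16.6 where 39.5/33.9 gives 16.5) and should not
    be used as recomputation targets.
    """
    return pd.DataFrame(
        _VENTILE_CELLS,
        columns=[
            "outcome",
            "panel",
            "ventile_set",
            "hads_only",
            "nss_only",
            "best",
            "printed_improvement",
        ],
    )
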