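"""Two-step nested model selection for combining the two composite risk scores.

Step 1 finds the best model using the administrative score only: starting
from month effects alone (M1), the score main effect ``A`` (M2) is tested at
the nominal level, then the candidate expansions — the time interaction
``T*A`` (M3) and the quadratic ``A^2`` (M4), jointly M5 — are screened.
Step 2 adds the one-time survey score to the selected base: the main effect
``S`` (M6) is tested at the nominal level, then the expansions ``T*S`` (M7),
``S^2`` (M8, jointly M9) and ``A*S`` (M10, with ``T*S`` M11) are screened.

Every comparison is a design-based Wald chi-square test of the added block
inside the larger fit. The two score main effects are the primary hypotheses
and are tested at ``alpha`` unadjusted; the expansion blocks form a
multiplicity family and are screened, by default, with a Holm correction at
level ``alpha/2`` within each step — the two steps split the selection error
budget, holding the ladder-wise probability of admitting any spurious
expansion near ``alpha``. A selection procedure should not inflate its error
rate with the number of expansions it tries; ``correction="none"`` reproduces
the per-comparison behaviour of examining each difference test at the
nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    LADDER_BASE_SPECS,
    DiscreteTimeHazardModel,
    HazardResults,
    ModelSpec,
    compare_nested,
    extend_base,
)

__all__ = ["LadderResults", "run_model_ladder"]


def _holm_adjust(pvalues: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjusted p-values."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted: dict[str, float] = {}
    running = 0.0
    for rank, (key, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[key] = running
    return adjusted


@dataclass
class LadderResults:
    """All fits, all difference tests, and the selected model of a ladder run."""

    fits: dict[str, HazardResults]
    tests: pd.DataFrame
    base_name: str
    selected_name: str
    alpha: float
    correction: str
    notes: list[str] = field(default_factory=list)

    @property
    def selected(self) -> HazardResults:
        return self.fits[self.selected_name]

    @property
    def base(self) -> HazardResults:
        """The selected administrative-score-only model."""
        return self.fits[self.base_name]

    def summary(self) -> str:
        lines = [
            f"Model ladder (alpha={self.alpha}, correction={self.correction})",
            f"selected base: {self.base_name}   selected model: {self.selected_name}",
            "",
            self.tests.to_string(index=False,
                                 float_format=lambda v: f"{v:.4f}"),
        ]
        if self.notes:
            lines += [""] + [f"note: {n}" for n in self.notes]
        return "\n".join(lines)


def _fit(array, spec, fits, **fit_kwargs) -> HazardResults:
    if spec.name not in fits:
        fits[spec.name] = DiscreteTimeHazardModel(array, spec).fit(**fit_kwargs)
    return fits[spec.name]


def run_model_ladder(
    array: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "holm",
    include_a_s: bool = True,
    **fit_kwargs,
) -> LadderResults:
    """Run the two-step model ladder on a standardized person-month array.

    Parameters
    ----------
    array : person-month DataFrame with both scores standardized.
    alpha : significance level for selection (primary score effects at
        ``alpha`` unadjusted; expansion blocks screened per ``correction``).
    correction : "holm" (default; familywise alpha per selection step) or
        "none" (each comparison at the nominal level).
    include_a_s : whether the score-product expansions M10/M11 are fitted.

    Returns
    -------
    LadderResults with every fit, a difference-test table (comparison, block,
    df, chi2, p, p_adjusted, significant), the selected base and final model.
    """
    if correction not in ("holm", "none"):
        raise ValueError("correction must be 'holm' or 'none'")
    if array["event"].sum() == 0:
        raise ValueError("no events in the person-month array")

    fits: dict[str, HazardResults] = {}
    rows: list[dict] = []
    notes: list[str] = []

    def record(comparison, block, test, p_adj, significant):
        rows.append(
            {
                "comparison": comparison,
                "block": block,
                "df": test.df,
                "chi2": test.statistic,
                "p": test.pvalue,
                "p_adjusted": p_adj,
                "significant": significant,
            }
        )

    # ---- step 1: administrative score only -------------------------------
    m1 = _fit(array, LADDER_BASE_SPECS["M1"], fits, **fit_kwargs)
    m2 = _fit(array, LADDER_BASE_SPECS["M2"], fits, **fit_kwargs)
    t_a = compare_nested(m1, m2)
    a_sig = t_a.pvalue < alpha
    record("M2-M1", "A", t_a, t_a.pvalue, a_sig)

    if not a_sig:
        base_spec = LADDER_BASE_SPECS["M1"]
        notes.append("A not significant; base model carries month effects only")
    else:
        m3 = _fit(array, LADDER_BASE_SPECS["M3"], fits, **fit_kwargs)
        m4 = _fit(array, LADDER_BASE_SPECS["M4"], fits, **fit_kwargs)
        step1_p = {
            "T_A": compare_nested(m2, m3),
            "A2": compare_nested(m2, m4),
        }
        raw1 = {k: t.pvalue for k, t in step1_p.items()}
        adj1 = _holm_adjust(raw1) if correction == "holm" else raw1
        thresh = alpha / 2 if correction == "holm" else alpha
        keep1 = {k for k, p in adj1.items() if p < thresh}
        record("M3-M2", "T_A", step1_p["T_A"], adj1["T_A"], "T_A" in keep1)
        record("M4-M2", "A2", step1_p["A2"], adj1["A2"], "A2" in keep1)
        base_name_map = {
            frozenset(): "M2",
            frozenset({"T_A"}): "M3",
            frozenset({"A2"}): "M4",
            frozenset({"T_A", "A2"}): "M5",
        }
        base_spec = LADDER_BASE_SPECS[base_name_map[frozenset(keep1)]]
        if base_spec.name == "M5":
            m5 = _fit(array, LADDER_BASE_SPECS["M5"], fits, **fit_kwargs)
            record("M5-M3", "A2", compare_nested(m3, m5), np.nan, True)
            record("M5-M4", "T_A", compare_nested(m4, m5), np.nan, True)
    base_fit = _fit(array, base_spec, fits, **fit_kwargs)

    # ---- step 2: add the survey score ------------------------------------
    m6_spec = extend_base(base_spec, "M6")
    m6 = _fit(array, m6_spec, fits, **fit_kwargs)
    t_s = compare_nested(base_fit, m6)
    s_sig = t_s.pvalue < alpha
    record(f"M6-{base_spec.name}", "S", t_s, t_s.pvalue, s_sig)

    if not s_sig:
        selected_spec = base_spec
        notes.append("S not significant; the administrative-only base is retained")
    else:
        m7 = _fit(array, extend_base(base_spec, "M7"), fits, **fit_kwargs)
        m8 = _fit(array, extend_base(base_spec, "M8"), fits, **fit_kwargs)
        step2_p = {
            "T_S": compare_nested(m6, m7),
            "S2": compare_nested(m6, m8),
        }
        comparisons = {"T_S": "M7-M6", "S2": "M8-M6"}
        if include_a_s:
            m10 = _fit(array, extend_base(base_spec, "M10"), fits, **fit_kwargs)
            step2_p["A_S"] = compare_nested(m6, m10)
            comparisons["A_S"] = "M10-M6"
        raw2 = {k: t.pvalue for k, t in step2_p.items()}
        adj2 = _holm_adjust(raw2) if correction == "holm" else raw2
        thresh = alpha / 2 if correction == "holm" else alpha
        keep2 = {k for k, p in adj2.items() if p < thresh}
        for k, t in step2_p.items():
            record(comparisons[k], k, t, adj2[k], k in keep2)
        # map the supported expansion set onto the ladder's named models;
        # combinations without a named model drop the lowest-priority block
        # (S2 before A_S before T_S), noted in the run log
        name_map = {
            frozenset(): "M6",
            frozenset({"T_S"}): "M7",
            frozenset({"S2"}): "M8",
            frozenset({"T_S", "S2"}): "M9",
            frozenset({"A_S"}): "M10",
            frozenset({"A_S", "T_S"}): "M11",
        }
        chosen = frozenset(keep2)
        while chosen not in name_map:
            for drop in ("S2", "A_S", "T_S"):
                if drop in chosen:
                    notes.append(
                        f"expansion set {sorted(chosen)} has no named model; "
                        f"dropping {drop}"
                    )
                    chosen = chosen - {drop}
                    break
        selected_spec = extend_base(base_spec, name_map[chosen])
        if selected_spec.name in ("M9", "M11"):
            _fit(array, selected_spec, fits, **fit_kwargs)

    selected_fit = _fit(array, selected_spec, fits, **fit_kwargs)
    assert selected_fit is fits[selected_spec.name]

    tests = pd.DataFrame(rows)
    return LadderResults(
        fits=fits,
        tests=tests,
        base_name=base_spec.name,
        selected_name=selected_spec.name,
        alpha=alpha,
        correction=correction,
        notes=notes,
    )
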