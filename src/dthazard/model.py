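"""Survey-weighted discrete-time logistic hazard models with design-based inference.

The unit of analysis is the person-month: the conditional probability of a
first event in month ``T`` given survival to ``T`` is modelled with a logistic
link,

    logit h_i(T) = alpha_T + x_i(T)' beta,

where ``alpha_T`` is a full set of month dummies (reference month 0) and the
covariates are the two standardized composite risk scores — ``A`` (monthly
administrative score) and ``S`` (one-time survey score) — optionally with
quadratic terms, their product, and interactions with time in service coded
by indicator blocks for months 13-24 and 25+.

Estimation maximizes the survey-weighted Bernoulli log-likelihood by
Newton-Raphson / IRLS with step-halving. Inference is design-based: a
Taylor-linearization (cluster sandwich) covariance aggregated at the sampling
cluster, with-replacement assumption and an optional c/(c-1) small-sample
factor, feeding Wald chi-square tests of coefficient blocks. Model-based
(inverse observed information) covariance is retained for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import expit, logit
from scipy.stats import chi2, norm

__all__ = [
    "ModelSpec",
    "LADDER_BASE_SPECS",
    "extend_base",
    "TIME_BIN_EDGES",
    "build_design_matrix",
    "DiscreteTimeHazardModel",
    "HazardResults",
    "WaldTest",
    "wald_test",
    "compare_nested",
    "sandwich_covariance",
]

#: interaction time bins: 0-12 (reference), 13-24, 25+ months
TIME_BIN_EDGES = (13, 25)

_VALID_TERMS = ("A", "A2", "T_A", "S", "S2", "T_S", "A_S")

#: number of design-matrix columns contributed by each score term
TERM_WIDTHS = {"A": 1, "A2": 1, "T_A": 2, "S": 1, "S2": 1, "T_S": 2, "A_S": 1}

_REQUIRED_MAIN = {"A2": ("A",), "T_A": ("A",), "S2": ("S",), "T_S": ("S",), "A_S": ("A", "S")}


@dataclass(frozen=True)
class ModelSpec:
    """A hazard-model specification: month main effects plus score terms.

    Month dummies (``T``) are always included. ``terms`` is drawn from
    A, A2, T_A, S, S2, T_S, A_S, where the time factor inside T_A / T_S is
    coded with indicators for months 13-24 and 25+.
    """

    name: str
    terms: tuple[str, ...] = ()

    def __post_init__(self):
        seen = []
        for t in self.terms:
            if t not in _VALID_TERMS:
                raise ValueError(f"unknown term {t!r}")
            if t in seen:
                raise ValueError(f"duplicate term {t!r}")
            seen.append(t)
        for t in self.terms:
            for main in _REQUIRED_MAIN.get(t, ()):
                if main not in self.terms:
                    raise ValueError(f"term {t!r} requires main effect {main!r}")

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.terms) <= set(other.terms)


#: the administrative-score-only half of the model ladder (step 1)
LADDER_BASE_SPECS = {
    "M1": ModelSpec("M1", ()),
    "M2": ModelSpec("M2", ("A",)),
    "M3": ModelSpec("M3", ("A", "T_A")),
    "M4": ModelSpec("M4", ("A", "A2")),
    "M5": ModelSpec("M5", ("A", "T_A", "A2")),
}

#: added term blocks of the survey-score extensions (step 2), applied to the
#: best administrative-only base model
_EXTENSION_TERMS = {
    "M6": ("S",),
    "M7": ("S", "T_S"),
    "M8": ("S", "S2"),
    "M9": ("S", "T_S", "S2"),
    "M10": ("S", "A_S"),
    "M11": ("S", "A_S", "T_S"),
}


def extend_base(base: ModelSpec, name: str) -> ModelSpec:
    """Survey-score extension ``name`` (M6-M11) of a selected base model."""
    if name not in _EXTENSION_TERMS:
        raise ValueError(f"unknown extension {name!r}")
    added = tuple(t for t in _EXTENSION_TERMS[name] if t not in base.terms)
    return ModelSpec(name, base.terms + added)


def _time_bin_columns(month: np.ndarray) -> np.ndarray:
    """Indicator columns for the 13-24 and 25+ month bins."""
    lo, hi = TIME_BIN_EDGES
    return np.column_stack(
        [((month >= lo) & (month < hi)).astype(float), (month >= hi).astype(float)]
    )


def build_design_matrix(
    array: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for a person-month array under ``spec``.

    Column order: const, one dummy per observed month above the reference
    (month 0, i.e. the smallest month present), then score terms in the fixed
    order A, A2, T_A(13-24), T_A(25+), S, S2, T_S(13-24), T_S(25+), A_S.
    """
    month = array["month"].to_numpy()
    months_present = np.unique(month)  # smallest month present is the reference
    dummies = (month[:, None] == months_present[None, 1:]).astype(float)
    cols = [np.ones((len(array), 1)), dummies]
    names = ["const"] + [f"T_{m}" for m in months_present[1:]]

    a = array["score_A"].to_numpy(dtype=float)
    s = array["score_S"].to_numpy(dtype=float)
    bins = _time_bin_columns(month)
    pieces = {
        "A": (a[:, None], ["A"]),
        "A2": ((a**2)[:, None], ["A2"]),
        "T_A": (bins * a[:, None], ["T13_24_A", "T25p_A"]),
        "S": (s[:, None], ["S"]),
        "S2": ((s**2)[:, None], ["S2"]),
        "T_S": (bins * s[:, None], ["T13_24_S", "T25p_S"]),
        "A_S": ((a * s)[:, None], ["A_S"]),
    }
    for term in _VALID_TERMS:
        if term in spec.terms:
            block, block_names = pieces[term]
            cols.append(block)
            names.extend(block_names)
    return np.hstack(cols), names


def term_columns(spec: ModelSpec, names: list[str], term: str) -> list[str]:
    """Design-matrix column names belonging to one score term."""
    mapping = {
        "A": ["A"],
        "A2": ["A2"],
        "T_A": ["T13_24_A", "T25p_A"],
        "S": ["S"],
        "S2": ["S2"],
        "T_S": ["T13_24_S", "T25p_S"],
        "A_S": ["A_S"],
    }
    cols = mapping[term]
    missing = [c for c in cols if c not in names]
    if missing:
        raise ValueError(f"term {term!r} not present in fitted model")
    return cols


@dataclass
class WaldTest:
    """A design-based Wald chi-square test of a coefficient block."""

    statistic: float
    df: int
    pvalue: float
    block: tuple[str, ...]

    def __post_init__(self):
        if self.df < 1:
            raise ValueError("df must be >= 1")


def _block_wald(beta: np.ndarray, cov: np.ndarray, block: tuple[str, ...]) -> WaldTest:
    try:
        stat = float(beta @ scipy.linalg.solve(cov, beta, assume_a="pos"))
    except scipy.linalg.LinAlgError as err:
        raise ValueError("singular covariance submatrix in Wald test") from err
    if not np.isfinite(stat) or stat < -1e-8:
        raise ValueError("singular covariance submatrix in Wald test")
    stat = max(stat, 0.0)
    df = len(beta)
    return WaldTest(stat, df, float(chi2.sf(stat, df)), block)


def sandwich_covariance(
    X: np.ndarray,
    resid: np.ndarray,
    weights: np.ndarray,
    clusters: np.ndarray,
    bread_inv: np.ndarray,
    small_sample: bool = True,
) -> np.ndarray:
    """Taylor-linearization (cluster sandwich) covariance.

    ``resid`` is y - mu; per-row score contributions ``w * (y - mu) * x`` are
    summed within sampling clusters (with-replacement single-stage design),
    outer-producted, and wrapped in the inverse observed information. With the
    default small-sample factor the meat is scaled by c/(c-1), c the number of
    clusters.
    """
    codes, uniques = pd.factorize(clusters)
    c = len(uniques)
    if c < 2:
        raise ValueError("cluster-sandwich variance requires at least 2 clusters")
    U = X * (weights * resid)[:, None]
    G = np.zeros((c, X.shape[1]))
    np.add.at(G, codes, U)
    meat = G.T @ G
    if small_sample:
        meat *= c / (c - 1)
    return bread_inv @ meat @ bread_inv


class DiscreteTimeHazardModel:
    """Weighted person-month logistic hazard model (statsmodels-style).

    Parameters
    ----------
    array : person-month DataFrame with columns subject_id, month, score_A,
        score_S, event, weight, cluster_id (see ``personmonth``).
    spec : a ModelSpec, or the name of a base ladder model ("M1".."M5").

    ``fit()`` returns a :class:`HazardResults`.
    """

    def __init__(self, array: pd.DataFrame, spec: ModelSpec | str):
        if isinstance(spec, str):
            spec = LADDER_BASE_SPECS[spec]
        self.array = array
        self.spec = spec
        self.endog = array["event"].to_numpy(dtype=float)
        self.weights = array["weight"].to_numpy(dtype=float)
        self.clusters = array["cluster_id"].to_numpy()
        self.exog, self.exog_names = build_design_matrix(array, spec)
        self.months_present = np.unique(array["month"].to_numpy())

    def loglike(self, params: np.ndarray) -> float:
        eta = self.exog @ params
        # numerically stable weighted Bernoulli log-likelihood
        ll = self.endog * eta - np.logaddexp(0.0, eta)
        return float(self.weights @ ll)

    def score(self, params: np.ndarray) -> np.ndarray:
        mu = expit(self.exog @ params)
        return self.exog.T @ (self.weights * (self.endog - mu))

    def fit(
        self,
        maxiter: int = 100,
        tol_grad: float = 1e-8,
        tol_llf: float = 1e-10,
        small_sample: bool = True,
    ) -> "HazardResults":
        """Maximize the weighted log-likelihood by Newton-Raphson with
        step-halving; convergence when the relative log-likelihood change
        falls below ``tol_llf`` or the gradient infinity-norm below
        ``tol_grad``."""
        X, y, w = self.exog, self.endog, self.weights
        n, k = X.shape
        if y.sum() == 0:
            raise ValueError("no events in the person-month array")

        beta = np.zeros(k)
        rate = float(np.average(y, weights=w))
        beta[0] = logit(min(max(rate, 1e-10), 1 - 1e-10))
        llf = self.loglike(beta)
        converged = False
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            mu = expit(X @ beta)
            grad = X.T @ (w * (y - mu))
            wls = w * mu * (1 - mu)
            H = X.T @ (X * wls[:, None])
            try:
                c_fac = scipy.linalg.cho_factor(H)
                step = scipy.linalg.cho_solve(c_fac, grad)
            except scipy.linalg.LinAlgError as err:
                if np.linalg.matrix_rank(H) < k:
                    raise ValueError(
                        "design matrix is rank deficient on the observed data"
                    ) from err
                step = scipy.linalg.lstsq(H, grad)[0]
            # step-halving to guarantee ascent
            scale = 1.0
            for _ in range(30):
                llf_new = self.loglike(beta + scale * step)
                if llf_new >= llf - 1e-13:
                    break
                scale /= 2.0
            beta = beta + scale * step
            rel_change = abs(llf_new - llf) / (abs(llf) + 1e-12)
            llf = llf_new
            if np.max(np.abs(grad)) < tol_grad or rel_change < tol_llf:
                converged = True
                break

        mu = expit(X @ beta)
        wls = w * mu * (1 - mu)
        H = X.T @ (X * wls[:, None])
        try:
            cov_model = scipy.linalg.inv(H)
        except scipy.linalg.LinAlgError:
            cov_model = np.linalg.pinv(H)
        bread_inv = cov_model
        cov_design = sandwich_covariance(
            X, y - mu, w, self.clusters, bread_inv, small_sample=small_sample
        )

        separated = [
            name for name, b in zip(self.exog_names, beta) if abs(b) > 15.0
        ]
        diagnostics = {
            "converged": converged,
            "n_iter": n_iter,
            "grad_inf_norm": float(np.max(np.abs(self.score(beta)))),
            "separated_terms": separated,
        }
        if not converged:
            diagnostics["warning"] = "maximum iterations reached without convergence"

        return HazardResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            llf=llf,
            cov_model=cov_model,
            cov_design=cov_design,
            nobs=n,
            diagnostics=diagnostics,
        )


@dataclass
class HazardResults:
    """Fitted hazard model: coefficients, likelihood, model- and design-based
    covariance, and design-based Wald tests."""

    model: DiscreteTimeHazardModel
    params: pd.Series
    llf: float
    cov_model: np.ndarray
    cov_design: np.ndarray
    nobs: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def exog_names(self) -> list[str]:
        return list(self.params.index)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def bse(self, kind: str = "design") -> pd.Series:
        cov = self.cov_design if kind == "design" else self.cov_model
        # tiny negative diagonals can appear for separated month dummies
        return pd.Series(np.sqrt(np.clip(np.diag(cov), 0.0, None)),
                         index=self.params.index)

    def conf_int(self, alpha: float = 0.05, kind: str = "design") -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        se = self.bse(kind)
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se}
        )

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Exponentiated coefficients with design-based confidence intervals."""
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "CI_low": np.exp(ci["lower"]),
                "CI_high": np.exp(ci["upper"]),
            }
        )

    def wald_test(self, columns: list[str], kind: str = "design") -> WaldTest:
        """Design-based Wald chi-square test that a block of coefficients is
        zero. ``columns`` are design-matrix column names."""
        missing = [c for c in columns if c not in self.params.index]
        if missing:
            raise ValueError(f"unknown coefficients: {missing}")
        idx = [self.exog_names.index(c) for c in columns]
        beta = self.params.to_numpy()[idx]
        cov = (self.cov_design if kind == "design" else self.cov_model)[
            np.ix_(idx, idx)
        ]
        return _block_wald(beta, cov, tuple(columns))

    def predict_log_odds(self, array: pd.DataFrame) -> np.ndarray:
        """Linear predictor per person-month row of ``array``.

        Months absent from the fitted dummy basis fall back to reference
        coding (dummy contribution 0); the affected months are recorded in
        ``diagnostics["extrapolated_months"]``.
        """
        X, names = build_design_matrix(array, self.spec)
        beta = pd.Series(0.0, index=names)
        common = [c for c in names if c in self.params.index]
        beta[common] = self.params[common]
        unseen_months = sorted(
            int(c[2:]) for c in set(names) - set(common) if c.startswith("T_")
        )
        if unseen_months:
            self.diagnostics.setdefault("extrapolated_months", unseen_months)
        return X @ beta.to_numpy()

    def predict_hazard(self, array: pd.DataFrame) -> np.ndarray:
        return expit(self.predict_log_odds(array))

    def summary(self, alpha: float = 0.05) -> str:
        """Plain-text coefficient table (design-based inference)."""
        se_d = self.bse("design")
        se_m = self.bse("model")
        ors = self.odds_ratios(alpha)
        lines = [
            f"Discrete-time logistic hazard model  [{self.spec.name}]",
            f"terms: T + {' + '.join(self.spec.terms) if self.spec.terms else '(none)'}",
            f"person-months: {self.nobs}   log-likelihood (weighted): {self.llf:.4f}",
            f"converged: {self.converged} in {self.diagnostics.get('n_iter', '?')} iterations",
            "",
            f"{'term':>12} {'coef':>10} {'SE(model)':>10} {'SE(design)':>11} "
            f"{'OR':>8} {'CI_low':>8} {'CI_high':>8}",
        ]
        for name in self.params.index:
            if name.startswith("T_"):
                continue  # month dummies suppressed for readability
            lines.append(
                f"{name:>12} {self.params[name]:>10.4f} {se_m[name]:>10.4f} "
                f"{se_d[name]:>11.4f} {ors.loc[name, 'OR']:>8.3f} "
                f"{ors.loc[name, 'CI_low']:>8.3f} {ors.loc[name, 'CI_high']:>8.3f}"
            )
        return "\n".join(lines)

    def coefficient_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Delimited-friendly coefficient table (all terms)."""
        ors = self.odds_ratios(alpha)
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "SE_model": self.bse("model").to_numpy(),
                "SE_design": self.bse("design").to_numpy(),
                "OR": ors["OR"].to_numpy(),
                "CI_low": ors["CI_low"].to_numpy(),
                "CI_high": ors["CI_high"].to_numpy(),
            }
        )


def wald_test(
    fit: HazardResults, block: list[str], kind: str = "design"
) -> WaldTest:
    """Functional form of :meth:`HazardResults.wald_test`."""
    return fit.wald_test(block, kind=kind)


def compare_nested(fit_small: HazardResults, fit_large: HazardResults) -> WaldTest:
    """Wald test of the terms the larger model adds over the smaller.

    Implemented as a block Wald test of the added coefficients within the
    larger fit (the design-based analogue of a difference test); requires the
    smaller spec's terms to be a strict subset of the larger's.
    """
    small, large = fit_small.spec, fit_large.spec
    if not small.is_nested_in(large):
        raise ValueError(f"{small.name} is not nested in {large.name}")
    added = [t for t in large.terms if t not in small.terms]
    if not added:
        raise ValueError("models are identical; nothing to test")
    cols: list[str] = []
    for t in added:
        cols.extend(term_columns(large, fit_large.exog_names, t))
    return fit_large.wald_test(cols)
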