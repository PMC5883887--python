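"""Hazard model: design matrix, ML fit, sandwich covariance, Wald tests."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import chi2

import dthazard as dt
from dthazard.model import (
    LADDER_BASE_SPECS,
    HazardResults,
    ModelSpec,
    build_design_matrix,
    compare_nested,
    extend_base,
    sandwich_covariance,
)


def _single_month_array(n=100, events=5, weight=1.0):
    return pd.DataFrame(
        dict(subject_id=np.arange(n), month=0,
             score_A=np.zeros(n), score_S=np.zeros(n),
             event=[1] * events + [0] * (n - events),
             weight=weight, cluster_id=np.arange(n) % 5)
    )


def _fake_results(params: dict, cov: np.ndarray) -> HazardResults:
    """Results shell for closed-form Wald-test checks."""
    s = pd.Series(params)
    return HazardResults(
        model=SimpleNamespace(spec=ModelSpec("fake")),
        params=s, llf=0.0, cov_model=cov, cov_design=cov, nobs=len(s),
    )


class TestDesignMatrix:
    def test_month_dummy_count(self, pm_fixture):
        three = pm_fixture[pm_fixture["month"] < 3]
        X, names = build_design_matrix(three, LADDER_BASE_SPECS["M1"])
        assert names == ["const", "T_1", "T_2"]
        assert X.shape[1] == 3

    def test_nesting_adds_single_column(self, pm_fixture):
        X1, n1 = build_design_matrix(pm_fixture, LADDER_BASE_SPECS["M1"])
        X2, n2 = build_design_matrix(pm_fixture, LADDER_BASE_SPECS["M2"])
        assert X2.shape[1] == X1.shape[1] + 1
        assert n2 == n1 + ["A"]

    def test_time_interaction_adds_two_bin_columns(self, pm_fixture):
        base = LADDER_BASE_SPECS["M2"]
        m6 = extend_base(base, "M6")
        m7 = extend_base(base, "M7")
        X6, n6 = build_design_matrix(pm_fixture, m6)
        X7, n7 = build_design_matrix(pm_fixture, m7)
        assert X7.shape[1] == X6.shape[1] + 2
        assert set(n7) - set(n6) == {"T13_24_S", "T25p_S"}
        # bins: 0-12 reference, 13-24, 25+
        month = pm_fixture["month"].to_numpy()
        col = n7.index("T13_24_S")
        active = X7[:, col] != 0
        assert ((month[active] >= 13) & (month[active] <= 24)).all()

    def test_interaction_requires_main_effect(self):
        with pytest.raises(ValueError, match="main effect"):
            ModelSpec("bad", ("T_S",))


class TestFit:
    def test_intercept_only_closed_form(self):
        arr = _single_month_array(n=100, events=5)
        fit = dt.DiscreteTimeHazardModel(arr, "M1").fit()
        assert fit.params["const"] == pytest.approx(logit(0.05), abs=1e-8)
        assert fit.converged

    def test_duplicated_rows_half_weight_equivalence(self, small_array):
        fit = dt.DiscreteTimeHazardModel(small_array, "M2").fit()
        doubled = pd.concat([small_array, small_array], ignore_index=True)
        doubled["weight"] /= 2.0
        fit2 = dt.DiscreteTimeHazardModel(doubled, "M2").fit()
        pd.testing.assert_series_equal(fit.params, fit2.params, atol=1e-8, rtol=0)
        assert fit2.llf == pytest.approx(fit.llf, rel=1e-10)

    def test_matches_statsmodels_glm(self, small_array):
        """Independent cross-check: weighted MLE equals a GLM fit of the same
        weighted Bernoulli objective."""
        import statsmodels.api as sm

        spec = ModelSpec("M6", ("A", "S"))
        model = dt.DiscreteTimeHazardModel(small_array, spec)
        fit = model.fit()
        glm = sm.GLM(
            model.endog, model.exog, family=sm.families.Binomial(),
            var_weights=model.weights,
        ).fit()
        # months with zero events have no finite MLE (separation); both
        # optimizers drift arbitrarily far, so compare identified terms only
        identified = fit.params.abs().to_numpy() < 10
        sep = [n for n, keep in zip(fit.exog_names, identified) if not keep]
        assert sep == fit.diagnostics["separated_terms"] or not sep
        np.testing.assert_allclose(
            fit.params.to_numpy()[identified], np.asarray(glm.params)[identified],
            atol=1e-6,
        )
        np.testing.assert_allclose(
            fit.bse("model").to_numpy()[identified],
            np.asarray(glm.bse)[identified], rtol=1e-3,
        )

    def test_no_events_rejected(self):
        arr = _single_month_array(events=0)
        with pytest.raises(ValueError, match="no events"):
            dt.DiscreteTimeHazardModel(arr, "M1").fit()

    def test_rank_deficiency_rejected(self):
        arr = _single_month_array(n=200, events=10)
        arr["score_A"] = 1.0  # collinear with the intercept
        with pytest.raises(ValueError, match="rank deficient"):
            dt.DiscreteTimeHazardModel(arr, ModelSpec("x", ("A",))).fit()

    def test_llf_nondecreasing_along_nested_specs(self, small_array):
        llfs = [
            dt.DiscreteTimeHazardModel(small_array, LADDER_BASE_SPECS[name]).fit().llf
            for name in ("M1", "M2", "M3", "M5")
        ]
        assert all(b >= a - 1e-8 for a, b in zip(llfs, llfs[1:]))


class TestSandwich:
    def test_reduces_to_heteroskedasticity_robust(self):
        """One unit per cluster, equal weights: the cluster sandwich equals
        the standard HC sandwich."""
        arr = _single_month_array(n=120, events=8)
        arr["cluster_id"] = np.arange(len(arr))  # each row its own cluster
        arr["score_A"] = np.random.default_rng(0).standard_normal(len(arr))
        model = dt.DiscreteTimeHazardModel(arr, ModelSpec("x", ("A",)))
        fit = model.fit(small_sample=False)
        X = model.exog
        mu = expit(X @ fit.params.to_numpy())
        resid = model.endog - mu
        bread_inv = fit.cov_model
        hc0 = bread_inv @ (X * (resid**2)[:, None]).T @ X @ bread_inv
        np.testing.assert_allclose(fit.cov_design, hc0, atol=1e-12)

    def test_weight_scale_invariance(self, small_array):
        fit = dt.DiscreteTimeHazardModel(small_array, "M2").fit()
        scaled = small_array.assign(weight=small_array["weight"] * 7.0)
        fit2 = dt.DiscreteTimeHazardModel(scaled, "M2").fit()
        np.testing.assert_allclose(fit.cov_design, fit2.cov_design, rtol=1e-6)

    def test_matches_naive_double_loop(self, pm_fixture):
        model = dt.DiscreteTimeHazardModel(pm_fixture, ModelSpec("x", ("A", "S")))
        fit = model.fit()
        X, y, w = model.exog, model.endog, model.weights
        mu = expit(X @ fit.params.to_numpy())
        clusters = pm_fixture["cluster_id"].to_numpy()
        meat = np.zeros((X.shape[1], X.shape[1]))
        for c in np.unique(clusters):
            g = np.zeros(X.shape[1])
            for i in np.nonzero(clusters == c)[0]:
                g += w[i] * (y[i] - mu[i]) * X[i]
            meat += np.outer(g, g)
        n_c = len(np.unique(clusters))
        meat *= n_c / (n_c - 1)
        expected = fit.cov_model @ meat @ fit.cov_model
        np.testing.assert_allclose(fit.cov_design, expected, atol=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="cluster"):
            sandwich_covariance(
                np.ones((5, 1)), np.zeros(5), np.ones(5),
                np.zeros(5, dtype=int), np.eye(1),
            )

    def test_design_and_model_se_agree_without_design_features(self):
        """With one subject per cluster and equal weights the two SEs are
        asymptotically the same; check a 20% sanity band."""
        arr = conftest_array = None
        from conftest import make_person_months

        arr = make_person_months(n_subjects=400, n_months=20, seed=3,
                                 event_rate=0.03, weighted=False)
        arr["cluster_id"] = arr["subject_id"]
        fit = dt.DiscreteTimeHazardModel(
            dt.standardize_scores(arr), ModelSpec("x", ("A", "S"))
        ).fit()
        for term in ("A", "S"):
            ratio = fit.bse("design")[term] / fit.bse("model")[term]
            assert 0.8 < ratio < 1.2


class TestWald:
    def test_single_coefficient_closed_form(self):
        fit = _fake_results({"A": 2.0}, np.eye(1))
        t = fit.wald_test(["A"])
        assert t.statistic == pytest.approx(4.0)
        assert t.df == 1
        assert t.pvalue == pytest.approx(chi2.sf(4.0, 1), abs=1e-12)
        assert t.pvalue == pytest.approx(0.0455, abs=5e-4)

    def test_zero_block(self):
        fit = _fake_results({"A": 0.0, "S": 0.0}, np.eye(2))
        t = fit.wald_test(["A", "S"])
        assert t.statistic == 0.0
        assert t.pvalue == 1.0

    def test_three_coefficient_block_matches_linear_solve(self):
        rng = np.random.default_rng(5)
        L = rng.standard_normal((3, 3))
        cov = L @ L.T + 3 * np.eye(3)
        beta = rng.standard_normal(3)
        fit = _fake_results(dict(zip(["a", "b", "c"], beta)), cov)
        t = fit.wald_test(["a", "b", "c"])
        expected = beta @ np.linalg.solve(cov, beta)
        assert t.statistic == pytest.approx(expected, rel=1e-12)
        assert t.df == 3

    def test_singular_submatrix_rejected(self):
        fit = _fake_results({"a": 1.0, "b": 1.0}, np.ones((2, 2)))
        with pytest.raises(ValueError, match="singular"):
            fit.wald_test(["a", "b"])


class TestCompareNested:
    def test_added_block_dfs(self, small_array):
        m1 = dt.DiscreteTimeHazardModel(small_array, "M1").fit()
        m2 = dt.DiscreteTimeHazardModel(small_array, "M2").fit()
        t = compare_nested(m1, m2)
        assert t.df == 1 and t.block == ("A",)

        base = LADDER_BASE_SPECS["M2"]
        m6 = dt.DiscreteTimeHazardModel(small_array, extend_base(base, "M6")).fit()
        m7 = dt.DiscreteTimeHazardModel(small_array, extend_base(base, "M7")).fit()
        t = compare_nested(m6, m7)
        assert t.df == 2 and t.block == ("T13_24_S", "T25p_S")

    def test_identical_and_non_nested_rejected(self, small_array):
        m2 = dt.DiscreteTimeHazardModel(small_array, "M2").fit()
        with pytest.raises(ValueError, match="identical"):
            compare_nested(m2, m2)
        s_only = dt.DiscreteTimeHazardModel(small_array, ModelSpec("S", ("S",))).fit()
        with pytest.raises(ValueError, match="not nested"):
            compare_nested(m2, s_only)


class TestPredict:
    def test_intercept_only_constant(self, small_array):
        fit = dt.DiscreteTimeHazardModel(
            small_array[small_array["month"] == 0], "M1"
        ).fit()
        eta = fit.predict_log_odds(small_array[small_array["month"] == 0])
        assert np.ptp(eta) == 0.0

    def test_ml_balance_identity(self, small_array):
        """Weighted mean fitted hazard equals the weighted event rate (score
        equation for the intercept)."""
        fit = dt.DiscreteTimeHazardModel(small_array, "M2").fit()
        h = fit.predict_hazard(small_array)
        w = small_array["weight"].to_numpy()
        assert np.average(h, weights=w) == pytest.approx(
            np.average(small_array["event"], weights=w), abs=1e-8
        )

    def test_manual_dot_product(self):
        arr = pd.DataFrame(
            dict(subject_id=[0, 0, 1, 1, 1], month=[0, 1, 0, 1, 2],
                 score_A=[0.5, -1.0, 2.0, 0.0, 1.0], score_S=[1.0] * 2 + [-0.5] * 3,
                 event=[0, 0, 0, 0, 1], weight=1.0, cluster_id=[0, 0, 1, 1, 1])
        )
        params = pd.Series(
            {"const": -3.0, "T_1": 0.2, "T_2": 0.4, "A": 0.5, "S": -0.3}
        )
        fit = _fake_results(params.to_dict(), np.eye(5))
        fit.model = SimpleNamespace(spec=ModelSpec("x", ("A", "S")))
        eta = fit.predict_log_odds(arr)
        X = np.column_stack([
            np.ones(5),
            (arr["month"] == 1).astype(float),
            (arr["month"] == 2).astype(float),
            arr["score_A"], arr["score_S"],
        ])
        np.testing.assert_allclose(eta, X @ params.to_numpy(), atol=1e-12)

    def test_summary_and_tables_render(self, small_array):
        fit = dt.DiscreteTimeHazardModel(
            small_array, ModelSpec("M6", ("A", "S"))
        ).fit()
        text = fit.summary()
        assert "log-likelihood" in text and " A " not in text.split("\n")[0]
        table = fit.coefficient_table()
        assert set(table.columns) == {
            "term", "estimate", "SE_model", "SE_design", "OR", "CI_low", "CI_high"
        }
        assert (table["SE_design"] >= 0).all()
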