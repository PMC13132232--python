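"""NB-GAM engine: bases, penalized IRLS, REML selection, AIC, prediction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize, stats
from shapely.geometry import Polygon

import surveygam as sg
from surveygam.gam import ModelSpec, TermSpec, _nb_loglik, fit_gam
from surveygam.smooths import Standardizer, build_term


class TestBases:
    def test_year_random_effect_columns_and_penalty(self):
        data = pd.DataFrame({"year": np.repeat(np.arange(2000, 2016), 3),
                             "x_c": 0.0, "y_c": 0.0})
        term = build_term("re_year")
        term.build(data, Standardizer.from_data(data.assign(x_c=1.0 * data.index)))
        assert term.ncol == 16
        assert np.array_equal(term.penalties[0], np.eye(16))

    def test_sum_to_zero_removes_one_dimension(self, small_nb_data):
        term = build_term("s_space", 30)
        std = Standardizer.from_data(small_nb_data)
        term.build(small_nb_data, std)
        # 6x6 marginal tensor loses exactly one dimension to the constraint
        assert term.ncol == 35
        M = term.matrix(small_nb_data, std)
        assert np.abs(M.mean(axis=0)).max() < 1e-10

    def test_all_smooth_terms_centred_in_m2_fit(self, triangle_run):
        fit = fit_gam(
            sg.standard_models(which=["M2"], k_space=16, k_year=8,
                               k_tensor=(4, 4, 4))["M2"],
            triangle_run["segments"].iloc[:800],
            fixed_lambda=[1.0, 1.0, 1.0, 1.0], fixed_theta=1.0,
        )
        data = triangle_run["segments"].iloc[:800]
        for term in fit.terms:
            M = term.matrix(data, fit.std)
            assert np.abs(M.mean(axis=0)).max() < 1e-8, term.name

    def test_large_lambda_collapses_1d_smooth_to_line(self, small_nb_data):
        spec = ModelSpec("m", (TermSpec("s_year", 8),))
        fit = fit_gam(spec, small_nb_data, fixed_lambda=[1e9], fixed_theta=2.0)
        term, sl = fit.terms[0], fit.term_cols["s(Year)"]
        vals = term.matrix(small_nb_data, fit.std) @ fit.beta[sl]
        t = small_nb_data["year"].to_numpy(float)
        resid = vals - np.polyval(np.polyfit(t, vals, 1), t)
        assert np.abs(resid).max() < 1e-6

    def test_basis_dimension_reduced_with_warning(self):
        data = pd.DataFrame({"year": np.tile([2000, 2001, 2002, 2003], 10),
                             "x_c": np.arange(40.0), "y_c": 0.0,
                             "area": 1.0, "count": 1})
        with pytest.warns(UserWarning, match="unique covariate support"):
            fit_gam(ModelSpec("m", (TermSpec("s_year", 10),)), data,
                    fixed_lambda=[1.0], fixed_theta=1.0)


class TestFitting:
    def test_poisson_limit_closed_form(self, small_nb_data):
        fit = fit_gam(ModelSpec("icpt", ()), small_nb_data, fixed_theta=1e8)
        expected = np.log(small_nb_data["count"].sum() / small_nb_data["area"].sum())
        assert fit.beta[0] == pytest.approx(expected, abs=1e-6)

    def test_offset_shift_moves_only_intercept(self, small_nb_data):
        doubled = small_nb_data.assign(area=2 * small_nb_data["area"])
        f1 = fit_gam(ModelSpec("icpt", ()), small_nb_data, fixed_theta=2.0)
        f2 = fit_gam(ModelSpec("icpt", ()), doubled, fixed_theta=2.0)
        assert f2.beta[0] - f1.beta[0] == pytest.approx(-np.log(2.0), abs=1e-6)

    def test_glm_special_case_matches_statsmodels(self, small_nb_data):
        spec = ModelSpec("lin", (TermSpec("s_year", 5),))
        fit = fit_gam(spec, small_nb_data, fixed_lambda=[1e-12], fixed_theta=2.0)
        glm = sm.GLM(
            small_nb_data["count"].to_numpy(), fit.X,
            family=sm.families.NegativeBinomial(alpha=0.5), offset=fit.offset,
        ).fit(scale=1.0, tol=1e-12, maxiter=500)
        assert np.abs(fit.beta - glm.params).max() < 1e-4
        assert np.abs(fit.V_b - glm.cov_params()).max() < 1e-4

    def test_intercept_and_dispersion_recovery(self):
        rng = np.random.default_rng(11)
        n, theta, b0 = 2000, 2.0, -0.5
        data = pd.DataFrame({"x_c": rng.uniform(0, 10, n),
                             "y_c": rng.uniform(0, 10, n),
                             "year": rng.integers(2000, 2010, n),
                             "area": rng.uniform(0.5, 2.0, n)})
        mu = np.exp(b0) * data["area"]
        data["count"] = rng.negative_binomial(theta, theta / (theta + mu))
        fit = fit_gam(ModelSpec("icpt", ()), data)
        se = np.sqrt(fit.V_b[0, 0])
        assert abs(fit.beta[0] - b0) < 3 * se
        assert 1.5 <= fit.theta <= 2.7

    def test_log_linear_trend_shrinks_year_smooth_to_line(self):
        rng = np.random.default_rng(2)
        n = 1500
        d = pd.DataFrame({"x_c": rng.uniform(0, 10, n),
                          "y_c": rng.uniform(0, 10, n),
                          "year": rng.integers(2000, 2016, n),
                          "area": np.ones(n)})
        mu = np.exp(-1.0 + 0.08 * (d["year"] - 2008))
        d["count"] = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        fit = fit_gam(sg.standard_models(which=["M1"], k_space=12, k_year=10)["M1"], d)
        assert fit.edf_term["s(Year)"] <= 1.5

    def test_all_zero_counts_rejected(self, small_nb_data):
        bad = small_nb_data.assign(count=0)
        with pytest.raises(ValueError, match="zero"):
            fit_gam(ModelSpec("icpt", ()), bad)


class TestModelSelection:
    def test_aic_equals_classical_glm_aic_without_penalty(self, small_nb_data):
        spec = ModelSpec("lin", (TermSpec("s_year", 5),))
        fit = fit_gam(spec, small_nb_data, fixed_lambda=[1e-12], fixed_theta=2.0)
        p = fit.X.shape[1]
        assert fit.edf_total == pytest.approx(p, abs=1e-4)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * p, abs=1e-3)

    def test_interaction_data_ranks_m2_above_m0(self):
        sq = Polygon([(0, 0), (12, 0), (12, 12), (0, 12)])
        sv = sg.SurveyDesign("d", (sg.Stratum("a", sq, spacing=1.0),),
                             years=tuple(range(2000, 2016)), seg_km=1.0)
        cfg = sg.SimConfig(surveys=(sv,), baseline=0.8, gradient=1.0,
                           amplitude=0.6, drift=0.03, theta=2.0,
                           detection=1.0, seed=5)
        obs, tr, _, _ = sg.simulate(cfg, truth_cell_km=1.0)
        obs = sg.indicated_units(sg.apply_inclusion_rules(obs))
        segs = sg.assign_counts(sg.segment_transects(tr, 1.0, 0.4), obs)
        tab = sg.select_model(
            sg.standard_models(which=["M0", "M2"], k_space=16, k_year=8,
                               k_tensor=(4, 4, 4)),
            segs,
        )
        assert tab.iloc[0]["model"] == "M2"
        assert tab.iloc[0]["delta_aic"] == 0.0

    def test_unneeded_observer_effect_shrinks_to_identical_aic(self):
        cfg = sg.preset("acp_like", seed=3)
        obs, tr, _, _ = sg.simulate(cfg, truth_cell_km=1.0)
        obs = sg.indicated_units(sg.apply_inclusion_rules(obs))
        segs = sg.assign_counts(sg.segment_transects(tr, 6.0, 0.4), obs)
        segs["observer"] = np.random.default_rng(0).choice(["A", "B"], len(segs))
        f4 = fit_gam(sg.standard_models(which=["M4"])["M4"], segs)
        f4o = fit_gam(sg.standard_models(which=["M4"], observer=True)["M4.obs"], segs)
        assert abs(f4.aic - f4o.aic) < 0.01
        assert f4o.edf_term["s(Observer)"] < 0.01

    def test_single_candidate_delta_zero(self, small_nb_data):
        tab = sg.select_model([ModelSpec("icpt", ())], small_nb_data,
                              fixed_theta=2.0)
        assert tab["delta_aic"].iloc[0] == 0.0


class TestPrediction:
    def test_exclusion_linearity(self, triangle_m1_fit, triangle_run):
        fit = triangle_m1_fit
        new = triangle_run["segments"].iloc[:50]
        _, full = sg.predict_linear(fit, new)
        parts = fit.beta[0] * np.ones(len(new))
        for name in ["s(X,Y)", "s(Year)"]:
            _, only = sg.predict_linear(
                fit, new, exclude=[t for t in fit.term_cols
                                   if t not in (name, "intercept")]
            )
            parts = parts + (only - fit.beta[0])
        assert np.abs(parts - full).max() < 1e-10

    def test_exclude_everything_but_intercept_constant(self, triangle_m1_fit,
                                                        triangle_run):
        fit = triangle_m1_fit
        new = triangle_run["segments"].iloc[:20]
        dens = sg.predict_density(fit, new, exclude=["s(X,Y)", "s(Year)"])
        assert np.allclose(dens, np.exp(fit.beta[0]))

    def test_unknown_exclude_name_rejected(self, triangle_m1_fit, triangle_run):
        with pytest.raises(ValueError, match="exclude"):
            sg.predict_linear(triangle_m1_fit, triangle_run["segments"].iloc[:5],
                              exclude=["s(Moon)"])

    def test_factor_settings_fix_survey_level(self, small_nb_data):
        d = small_nb_data.assign(survey_id="dense")
        d.loc[d.index[:30], "survey_id"] = "sparse"
        spec = ModelSpec("f", (TermSpec("factor_survey"),))
        fit = fit_gam(spec, d, fixed_theta=2.0)
        new = d.drop(columns=["survey_id"]).iloc[:5]
        base = sg.predict_density(fit, new, factor_settings={"survey_id": "dense"})
        other = sg.predict_density(fit, new, factor_settings={"survey_id": "sparse"})
        # "dense" is the baseline level; the other level shifts density by
        # a constant multiplicative survey effect
        assert np.allclose(base, np.exp(fit.beta[0]))
        ratio = other / base
        assert np.allclose(ratio, ratio[0])

    def test_unknown_factor_level_rejected(self, small_nb_data):
        d = small_nb_data.assign(survey_id="a")
        d.loc[d.index[:30], "survey_id"] = "b"
        spec = ModelSpec("f", (TermSpec("factor_survey"),))
        fit = fit_gam(spec, d, fixed_theta=2.0)
        with pytest.raises(ValueError, match="factor level"):
            sg.predict_linear(fit, d.iloc[:3].assign(survey_id="zzz"))


class TestDiagnostics:
    def test_quantile_residuals_uniform_under_truth(self, triangle_m1_fit):
        tab, summ = sg.quantile_residuals(triangle_m1_fit, seed=3)
        ks = stats.kstest(tab["uniform"], "uniform")
        assert ks.pvalue > 0.01
        assert 0.8 < summ["dispersion_ratio"] < 1.2

    def test_injected_extra_zeros_flagged(self, triangle_m1_fit):
        fit = triangle_m1_fit
        rigged = fit.y.copy()
        rigged[fit.y > 0] = np.where(
            np.random.default_rng(1).uniform(size=(fit.y > 0).sum()) < 0.5,
            0, rigged[fit.y > 0],
        )
        y_orig = fit.y
        try:
            fit.y = rigged
            _, summ = sg.quantile_residuals(fit, seed=4)
        finally:
            fit.y = y_orig
        assert summ["zero_inflation_ratio"] > 1.02
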