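"""Prediction grids, coefficient samplers, totals, detection, trend."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

import surveygam as sg
from surveygam.gam import ModelSpec, fit_gam


@pytest.fixture(scope="module")
def small_fit():
    rng = np.random.default_rng(7)
    n = 200
    data = pd.DataFrame({"x_c": rng.uniform(0, 10, n),
                         "y_c": rng.uniform(0, 10, n),
                         "year": rng.integers(2000, 2010, n),
                         "area": np.ones(n)})
    data["count"] = rng.negative_binomial(2.0, 2.0 / 3.0, n)  # mu = 1
    return fit_gam(ModelSpec("m", (sg.TermSpec("s_year", 6),)), data,
                   fixed_theta=2.0)


class TestGrid:
    def test_square_area(self, unit_square_area):
        g = sg.make_grid(unit_square_area, 1.0, [2000])
        assert len(g.cells) == 100
        assert g.total_area == pytest.approx(100.0)

    def test_right_triangle_clipped_cells(self):
        tri = sg.StudyArea(polygons={"t": Polygon([(0, 0), (2, 0), (0, 2)])})
        g = sg.make_grid(tri, 1.0, [2000])
        assert g.total_area == pytest.approx(2.0, abs=1e-3)
        assert (g.cells["area"] <= 1.0 + 1e-12).all()
        assert (g.cells["area"] < 1.0).sum() >= 2  # boundary cells are smaller

    def test_years_replicate_rows(self, unit_square_area):
        g = sg.make_grid(unit_square_area, 1.0, [2000, 2001, 2002])
        assert len(g.years) == 3
        assert len(g.year_table(2001)) == len(g.cells)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(Exception):
            area = sg.StudyArea(polygons={"z": Polygon([(0, 0), (1, 0), (2, 0)])})
            sg.make_grid(area, 1.0, [2000])


class TestSamplers:
    def test_mvn_moments(self, small_fit):
        draws = sg.sample_coefficients_mvn(small_fit, 10_000, seed=1)
        se = np.sqrt(np.diag(small_fit.V_b) / 10_000)
        assert np.all(np.abs(draws.mean(axis=0) - small_fit.beta) < 4 * se)
        cov_err = np.linalg.norm(np.cov(draws.T) - small_fit.V_b)
        assert cov_err < 0.1 * np.linalg.norm(small_fit.V_b)

    def test_degenerate_covariance_returns_mean(self, small_fit):
        import copy

        fit0 = copy.copy(small_fit)
        fit0.V_b = np.zeros_like(small_fit.V_b)
        draws = sg.sample_coefficients_mvn(fit0, 10, seed=2)
        assert np.allclose(draws, small_fit.beta)

    def test_mh_matches_mvn_moments(self, small_fit):
        mvn = sg.sample_coefficients_mvn(small_fit, 4000, seed=1)
        mh = sg.sample_coefficients_mh(small_fit, 3000, burnin=300, seed=2)
        sd = np.sqrt(np.diag(small_fit.V_b))
        assert np.max(np.abs(mvn.mean(0) - mh.mean(0)) / sd) < 0.15
        assert np.all(np.abs(mh.std(0) / mvn.std(0) - 1.0) < 0.2)

    def test_mh_seeded_chains_identical(self, small_fit):
        a = sg.sample_coefficients_mh(small_fit, 200, burnin=50, seed=9)
        b = sg.sample_coefficients_mh(small_fit, 200, burnin=50, seed=9)
        assert np.array_equal(a, b)

    def test_mh_thinning_invariance_of_moments(self, small_fit):
        t1 = sg.sample_coefficients_mh(small_fit, 2000, burnin=200, thin=1, seed=3)
        t5 = sg.sample_coefficients_mh(small_fit, 800, burnin=200, thin=5, seed=4)
        sd = np.sqrt(np.diag(small_fit.V_b))
        assert np.max(np.abs(t1.mean(0) - t5.mean(0)) / sd) < 0.2


class TestTotals:
    def test_intercept_zero_gives_total_area(self, unit_square_area, small_fit):
        import copy

        fit0 = copy.copy(small_fit)
        fit0.beta = np.zeros_like(small_fit.beta)
        grid = sg.make_grid(unit_square_area, 1.0, [2005])
        draws = np.zeros((5, len(fit0.beta)))
        post = sg.totals_from_draws(draws, fit0, grid)
        assert np.allclose(post.index_totals, 100.0)

    def test_grid_refinement_changes_totals_little(self, unit_square_area,
                                                    small_fit):
        draws = sg.sample_coefficients_mvn(small_fit, 20, seed=5)
        g1 = sg.make_grid(unit_square_area, 1.0, [2005])
        g2 = sg.make_grid(unit_square_area, 0.5, [2005])
        y1 = sg.totals_from_draws(draws, small_fit, g1).index_totals
        y2 = sg.totals_from_draws(draws, small_fit, g2).index_totals
        assert np.all(np.abs(y1 / y2 - 1.0) < 0.005)

    def test_random_effect_year_refuses_extrapolation(self, triangle_run):
        segs = triangle_run["segments"]
        fit = fit_gam(sg.standard_models(which=["M4"])["M4"],
                      segs[segs["year"] < 2010])
        grid = sg.make_grid(triangle_run["area"], 2.0, [2015])
        draws = sg.sample_coefficients_mvn(fit, 3, seed=0)
        with pytest.raises(ValueError, match="cannot extrapolate"):
            sg.totals_from_draws(draws, fit, grid)


class TestDetectionCorrection:
    def _post(self, totals):
        return sg.PosteriorDraws(years=(2000,),
                                 index_totals=np.full((2000, 1), totals))

    def test_fixed_half_detection_quadruples(self):
        near_degenerate = sg.BetaPrior(5e6, 5e6)  # d = 0.5 essentially
        out = sg.detection_correct(self._post(100.0), near_degenerate, seed=1)
        assert np.allclose(out.corrected_totals, 400.0, rtol=1e-2)

    def test_rowwise_identity_exact(self):
        out = sg.detection_correct(self._post(100.0), sg.canonical_prior(), seed=2)
        manual = 2.0 * out.index_totals / out.detection_draws[:, None]
        assert np.array_equal(out.corrected_totals, manual)

    def test_full_detection_doubles_exactly(self):
        prior = sg.BetaPrior(1e9, 1e-6)  # essentially d = 1
        out = sg.detection_correct(self._post(100.0), prior, seed=3)
        assert np.allclose(out.corrected_totals, 2.0 * out.index_totals, rtol=1e-6)

    def test_correction_skews_posterior_right(self):
        out = sg.detection_correct(self._post(100.0), sg.canonical_prior(), seed=4)
        n = out.corrected_totals[:, 0]
        assert n.mean() > np.median(n)


class TestTrend:
    def _post(self):
        totals = np.tile([100.0, 150.0, 200.0], (50, 1))
        return sg.PosteriorDraws(years=(2000, 2005, 2010), index_totals=totals)

    def test_doubling_over_ten_years(self):
        t = sg.trend(self._post(), 2000, 10, use_corrected=False)
        assert t["mean"] == pytest.approx(np.log(2.0) / 10.0)

    def test_antisymmetry_under_reversal(self):
        post = self._post()
        fwd = sg.trend(post, 2000, 10, use_corrected=False)["draws"]
        # reversed endpoints: same years relabelled in reverse order
        rev = sg.PosteriorDraws(years=(2000, 2005, 2010),
                                index_totals=post.index_totals[:, ::-1])
        bwd = sg.trend(rev, 2000, 10, use_corrected=False)["draws"]
        assert np.array_equal(fwd, -bwd)

    def test_constant_detection_cancels_drawwise(self):
        post = sg.detection_correct(self._post(), sg.canonical_prior(), seed=5)
        t_index = sg.trend(post, 2000, 10, use_corrected=False)["draws"]
        t_corr = sg.trend(post, 2000, 10, use_corrected=True)["draws"]
        assert np.allclose(t_index, t_corr, atol=1e-12)

    def test_missing_year_rejected(self):
        with pytest.raises(ValueError, match="not among"):
            sg.trend(self._post(), 2000, 3)


class TestSummarize:
    def test_type7_quantiles(self):
        draws = np.arange(1.0, 101.0)[:, None]
        s = sg.summarize(draws, years=[2000])
        assert s["median"].iloc[0] == pytest.approx(50.5)
        assert s["q025"].iloc[0] == pytest.approx(3.475)

    def test_constant_draws(self):
        s = sg.summarize(np.full((10, 1), 7.0), years=[2000])
        row = s.iloc[0]
        assert row["mean"] == row["median"] == row["q025"] == row["q975"] == 7.0

    def test_lognormal_mean_exceeds_median(self):
        rng = np.random.default_rng(0)
        s = sg.summarize(np.exp(rng.standard_normal((5000, 1))), years=[2000])
        assert s["mean"].iloc[0] > s["median"].iloc[0]
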