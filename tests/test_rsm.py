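"""Quadratic response-surface fitting, pruning, and optimization."""

import numpy as np
import pytest
from scipy import stats

import dbltune as dt
from dbltune.design import Factor, HyperparameterSpace
from dbltune.rsm import AccuracyMatrix, quadratic_terms

from conftest import ols_normal_equations

EQ_SUPPORT = ("intercept", "nf", "pc", "nf^2", "pc^2")


class TestDesignMatrix:
    def test_rows_by_hand(self):
        pts = [
            {"nf": 0.0, "pc": 0.0, "depth": 0.0},
            {"nf": 1.0, "pc": 1.0, "depth": 1.0},
            {"nf": 500.0, "pc": 5.0, "depth": 2.0},
        ]
        X, terms = dt.build_design_matrix(pts, ["nf", "pc", "depth"])
        assert terms == quadratic_terms(["nf", "pc", "depth"])
        assert X[0].tolist() == [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        assert X[1].tolist() == [1] * 10
        assert X[2].tolist() == [1, 500, 5, 2, 250000, 25, 4, 2500, 1000, 10]

    def test_missing_factor_is_an_error(self):
        with pytest.raises(KeyError):
            dt.build_design_matrix([{"nf": 1.0}], ["nf", "pc", "depth"])


class TestOLS:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n, k = rng.integers(15, 60), rng.integers(2, 8)
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
            y = rng.normal(size=n)
            terms = [f"t{j}" for j in range(k)]
            fit = dt.fit_ols(X, y, terms, ["x"])
            expected = ols_normal_equations(X, y)
            got = np.array([fit.params[t] for t in terms])
            assert np.allclose(got, expected, rtol=1e-6)

    def test_noise_free_generative_round_trip(self, scdbl_space, eq_reduced_coeffs):
        data = dt.simulate_response_surface(scdbl_space, eq_reduced_coeffs, 0.0, 1, 0)[0]
        fit = dt.fit_quadratic(data)
        for t, v in eq_reduced_coeffs.items():
            assert fit.params[t] == pytest.approx(v, rel=1e-8)
        assert np.abs(fit.residuals).max() < 1e-8
        assert fit.r_squared == pytest.approx(1.0)
        # residuals sum to ~0 with an intercept
        assert abs(fit.residuals.sum()) < 1e-8 * max(1.0, np.abs(data.response).sum())

    def test_constant_response(self, scdbl_space):
        pts = dt.full_factorial(scdbl_space)
        data = AccuracyMatrix(pts, np.full(len(pts), 0.37))
        fit = dt.fit_quadratic(data)
        assert fit.params["intercept"] == pytest.approx(0.37)
        for t in fit.terms:
            if t != "intercept":
                assert fit.params[t] == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficiency_names_collinear_terms(self):
        # a two-level factor makes its square collinear with (1, x)
        space = HyperparameterSpace(
            (Factor("a", 1, (1, 2, 3)), Factor("b", 1, (1, 3, 5)),
             Factor("c", 1, (0, 1)))
        )
        pts = dt.full_factorial(space)
        rng = np.random.default_rng(1)
        data = AccuracyMatrix(pts, rng.normal(size=len(pts)))
        with pytest.raises(ValueError, match="rank deficient"):
            dt.fit_quadratic(data)


class TestCoefficientTests:
    def test_pvalues_follow_t_distribution_formula(self, scdbl_space, eq_reduced_coeffs):
        mats = dt.simulate_response_surface(scdbl_space, eq_reduced_coeffs, 1e-3, 1, 3)
        fit = dt.fit_quadratic(mats[0])
        pvals = dt.coefficient_tests(fit)
        for t in fit.terms:
            expected = 2 * stats.t.sf(abs(fit.tvalues[t]), fit.df_resid)
            assert pvals[t] == pytest.approx(expected)
            assert 0 <= pvals[t] <= 1

    def test_noise_free_nonzero_terms_have_zero_pvalue(self, scdbl_space, eq_reduced_coeffs):
        data = dt.simulate_response_surface(scdbl_space, eq_reduced_coeffs, 0.0, 1, 0)[0]
        fit = dt.fit_quadratic(data)
        assert fit.pvalues["pc"] < 1e-30

    def test_type_one_error_rate_near_alpha(self, scdbl_space, eq_reduced_coeffs):
        # depth is absent from the generating model; its linear term should
        # be rejected at alpha=0.01 about 1% of the time
        rng_seeds = range(500)
        rejections = 0
        for s in rng_seeds:
            m = dt.simulate_response_surface(
                scdbl_space, eq_reduced_coeffs, 1e-3, 1, seed=20_000 + s
            )[0]
            fit = dt.fit_quadratic(m)
            rejections += fit.pvalues["depth"] < 0.01
        rate = rejections / 500
        assert abs(rate - 0.01) < 0.015  # ~3.4 binomial sd


class TestPruning:
    def test_zero_effect_factor_is_pruned(self, scdbl_space, eq_reduced_coeffs):
        m = dt.simulate_response_surface(scdbl_space, eq_reduced_coeffs, 1e-4, 1, 42)[0]
        fit = dt.prune_and_refit(m, alpha=0.01)
        assert set(fit.retained_terms) == set(EQ_SUPPORT)
        for t in ("depth", "depth^2", "nf:depth", "pc:depth"):
            assert t not in fit.retained_terms

    def test_alpha_one_retains_everything(self, scdbl_space, eq_reduced_coeffs):
        m = dt.simulate_response_surface(scdbl_space, eq_reduced_coeffs, 1e-2, 1, 7)[0]
        fit = dt.prune_and_refit(m, alpha=1.0)
        assert set(fit.retained_terms) == set(quadratic_terms(["nf", "pc", "depth"]))

    def test_all_strong_terms_keep_full_model(self, scdbl_space):
        beta = {
            t: c
            for t, c in zip(
                quadratic_terms(["nf", "pc", "depth"]),
                [0.5, 1e-4, 1e-2, 1e-2, -5e-8, -3e-4, -1e-3, 1e-6, 1e-6, 1e-4],
            )
        }
        m = dt.simulate_response_surface(scdbl_space, beta, 1e-5, 1, 11)[0]
        fit = dt.prune_and_refit(m, alpha=0.01)
        assert len(fit.retained_terms) == 10

    def test_flat_surface_flagged(self, scdbl_space):
        pts = dt.full_factorial(scdbl_space)
        rng = np.random.default_rng(2)
        data = AccuracyMatrix(pts, 0.5 + rng.normal(0, 1e-3, len(pts)))
        fit = dt.prune_and_refit(data, alpha=1e-6)
        assert fit.flags["flat_surface"]
        assert fit.retained_terms == ("intercept",)

    def test_refit_is_idempotent(self, scdbl_space, eq_reduced_coeffs):
        # every term surviving the prune stays significant on refit
        m = dt.simulate_response_surface(scdbl_space, eq_reduced_coeffs, 1e-4, 1, 42)[0]
        fit = dt.prune_and_refit(m, alpha=0.01)
        for t in fit.retained_terms:
            if t != "intercept":
                assert fit.pvalues[t] < 0.01

    def test_support_recovery_rate(self, scdbl_space, eq_reduced_coeffs):
        # with 5 truly-null terms, perfect recovery at alpha=0.01 caps out
        # near 0.99^5 ~ 0.951 in expectation; require >= 0.90 over 200 sims
        # and a stationary point within one grid step whenever recovered
        step = {"nf": 500.0, "pc": 5.0}
        true_stat = {"nf": 1.016e-5 / 7.520e-9, "pc": 1.336e-3 / 6.968e-5}
        for noise in (1e-4, 1e-3):
            hits = 0
            for s in range(200):
                m = dt.simulate_response_surface(
                    scdbl_space, eq_reduced_coeffs, noise, 1, seed=10_000 + s
                )[0]
                fit = dt.prune_and_refit(m, alpha=0.01)
                if set(fit.retained_terms) == set(EQ_SUPPORT):
                    hits += 1
                    opt = dt.stationary_point(fit, scdbl_space)
                    for f, v in true_stat.items():
                        assert abs(opt.stationary[f] - v) <= step[f]
            assert hits / 200 >= 0.90


class TestStationaryPoint:
    def test_published_reduced_model(self, scdbl_space):
        fit = dt.scdblfinder_reduced_model()
        opt = dt.stationary_point(fit, scdbl_space)
        assert opt.curvature == "maximum"
        assert not opt.fallback_used
        assert opt.stationary["pc"] == pytest.approx(19.1734, abs=1e-3)
        assert opt.optimum["pc"] == 19.0
        assert opt.stationary["nf"] == pytest.approx(1351.06, abs=0.01)
        # depth carries no retained terms: pinned to its default
        assert opt.inactive_factors == {"depth": 4.0}

    def test_one_factor_parabola_vertex(self):
        space = HyperparameterSpace((Factor("x", 0, (-2, -1, 0, 1, 2)),))
        fit = dt.fit_from_coefficients(
            {"intercept": 0.0, "x": 2.0, "x^2": -1.0}, ["x"]
        )
        opt = dt.stationary_point(fit, space)
        assert opt.stationary["x"] == pytest.approx(1.0)
        assert opt.curvature == "maximum"

    def test_saddle_falls_back_to_grid_argmax(self):
        space = HyperparameterSpace(
            (Factor("a", 0, (-2, -1, 0, 1, 2)), Factor("b", 0, (-2, -1, 0, 1, 2)))
        )
        fit = dt.fit_from_coefficients(
            {"intercept": 0.0, "a^2": 1.0, "b^2": -1.0}, ["a", "b"]
        )
        opt = dt.stationary_point(fit, space)
        assert opt.curvature == "saddle"
        assert opt.fallback_used
        grid = dt.full_factorial(space)
        best = max(grid, key=lambda p: dt.predict(fit, p))
        assert dt.predict(fit, {**opt.optimum}) == pytest.approx(
            dt.predict(fit, best)
        )

    def test_out_of_hull_maximum_falls_back(self):
        space = HyperparameterSpace((Factor("x", 0, (0, 1, 2)),))
        # concave with vertex at x=10, far outside [0, 2]
        fit = dt.fit_from_coefficients(
            {"intercept": 0.0, "x": 20.0, "x^2": -1.0}, ["x"]
        )
        opt = dt.stationary_point(fit, space)
        assert opt.fallback_used
        assert opt.optimum["x"] == 2.0  # grid argmax on the rising branch

    def test_no_quadratic_terms_is_an_error(self, scdbl_space):
        fit = dt.fit_from_coefficients({"intercept": 0.5, "nf": 1e-5}, ["nf", "pc", "depth"])
        with pytest.raises(ValueError, match="no quadratic"):
            dt.stationary_point(fit, scdbl_space)

    def test_concave_fit_dominates_design_grid(self, scdbl_space):
        fit = dt.scdblfinder_reduced_model()
        opt = dt.stationary_point(fit, scdbl_space)
        full = {**opt.stationary, **opt.inactive_factors}
        at_stationary = dt.predict(fit, full)
        for p in dt.full_factorial(scdbl_space):
            assert at_stationary >= dt.predict(fit, p) - 1e-10


class TestPredict:
    def test_intercept_only(self, scdbl_space):
        fit = dt.fit_from_coefficients({"intercept": 0.42}, ["nf", "pc", "depth"])
        for p in dt.full_factorial(scdbl_space)[:5]:
            assert dt.predict(fit, p) == 0.42

    def test_published_model_by_hand(self):
        fit = dt.scdblfinder_reduced_model()
        nf, pc = 1352, 19
        expected = (
            5.444e-1 + 1.016e-5 * nf + 1.336e-3 * pc
            - 3.760e-9 * nf**2 - 3.484e-5 * pc**2
        )
        assert dt.predict(fit, {"nf": nf, "pc": pc, "depth": 4}) == pytest.approx(
            expected, rel=1e-12
        )

    def test_noise_free_predictions_equal_observations(self, scdbl_space, eq_reduced_coeffs):
        data = dt.simulate_response_surface(scdbl_space, eq_reduced_coeffs, 0.0, 1, 0)[0]
        fit = dt.fit_quadratic(data)
        for p, y in list(zip(data.points, data.response))[::25]:
            assert dt.predict(fit, p) == pytest.approx(y, abs=1e-8)
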