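"""Response-surface fitting, ANOVA identities, and constrained optimum."""

import numpy as np
import pandas as pd
import pytest

from acepep import (
    BBDExperiment,
    DEFAULT_CODING,
    FactorCoding,
    anova,
    find_optimum,
    fit_quadratic,
)
from acepep.rsm import TERM_NAMES, _design_matrix
from acepep.simulate import BBD_CODED_RUNS, gen_bbd


def quadratic_surface(coded, beta):
    return _design_matrix(np.atleast_2d(coded)) @ np.asarray(beta)


def make_experiment(beta, noise=None):
    y = quadratic_surface(BBD_CODED_RUNS, beta)
    if noise is not None:
        y = y + noise
    return BBDExperiment(coded=BBD_CODED_RUNS.copy(), response=y)


class TestFactorCoding:
    def test_round_trip_at_the_three_levels(self):
        for name, levels in DEFAULT_CODING.levels.items():
            for code, nat in zip((-1, 0, 1), levels):
                assert DEFAULT_CODING.encode(name, nat) == pytest.approx(code)
                assert DEFAULT_CODING.decode(name, code) == pytest.approx(nat)

    def test_linear_interpolation_between_levels(self):
        assert DEFAULT_CODING.decode("pH", 0.4) == pytest.approx(8.7)
        assert DEFAULT_CODING.encode("temperature", 56.03) == pytest.approx(0.206)

    def test_non_midpoint_center_rejected(self):
        with pytest.raises(ValueError, match="midpoint"):
            FactorCoding({"a": (0, 1, 4), "b": (0, 1, 2), "c": (0, 1, 2)})


class TestDesignValidation:
    def test_bundled_design_is_a_valid_bbd(self, design_table):
        design = BBDExperiment.from_natural(design_table, DEFAULT_CODING)
        assert design.is_center.sum() == 5

    def test_wrong_run_count_rejected(self):
        with pytest.raises(ValueError):
            BBDExperiment(coded=BBD_CODED_RUNS[:16], response=np.zeros(16))

    def test_broken_structure_rejected(self):
        coded = BBD_CODED_RUNS.copy()
        coded[0] = (0, 0, 0)  # 6 centers, 11 edges
        with pytest.raises(ValueError, match="Box-Behnken structure"):
            BBDExperiment(coded=coded, response=np.zeros(17))


class TestFitQuadratic:
    def test_noiseless_surface_recovered_exactly(self):
        beta = np.array([60.0, 1.5, -2.0, 0.7, 0.3, -0.4, 1.1, -3.0, -1.0, -5.0])
        fit = fit_quadratic(make_experiment(beta))
        got = np.array([fit.coefficients[t] for t in TERM_NAMES])
        np.testing.assert_allclose(got, beta, atol=1e-8)

    def test_constant_response_gives_intercept_only(self):
        fit = fit_quadratic(
            BBDExperiment(coded=BBD_CODED_RUNS.copy(), response=np.full(17, 42.0))
        )
        assert fit.coefficients["Intercept"] == pytest.approx(42.0)
        for term in TERM_NAMES[1:]:
            assert fit.coefficients[term] == pytest.approx(0.0, abs=1e-10)
        report = anova(fit)
        assert report.table.loc["Model", "sum_sq"] == pytest.approx(0.0, abs=1e-16)

    def test_fitted_plus_residual_equals_observed(self, bbd_fit):
        np.testing.assert_allclose(
            bbd_fit.fitted + bbd_fit.residuals, bbd_fit.design.response, atol=1e-10
        )

    def test_bundled_design_r_squared(self, bbd_fit):
        report = anova(bbd_fit)
        assert report.diagnostics["r_squared"] == pytest.approx(0.9868, abs=0.005)


class TestAnova:
    def test_ss_additivity_and_df_bookkeeping(self, bbd_fit):
        t = anova(bbd_fit).table
        assert t.loc["Model", "sum_sq"] + t.loc["Residual", "sum_sq"] == pytest.approx(
            t.loc["Cor Total", "sum_sq"], rel=1e-6
        )
        assert t.loc["Lack of Fit", "sum_sq"] + t.loc["Pure Error", "sum_sq"] == (
            pytest.approx(t.loc["Residual", "sum_sq"], rel=1e-9)
        )
        assert (t.loc["Model", "df"], t.loc["Residual", "df"]) == (9, 7)
        assert (t.loc["Lack of Fit", "df"], t.loc["Pure Error", "df"]) == (3, 4)
        assert t.loc["Cor Total", "df"] == 16

    def test_main_effect_ss_equals_eight_beta_squared(self):
        # BBD orthogonality: each main effect has 8 runs at +/-1
        rng = np.random.default_rng(7)
        beta = rng.normal(size=10)
        fit = fit_quadratic(make_experiment(beta, noise=0.1 * rng.standard_normal(17)))
        t = anova(fit).table
        for term in ("A", "B", "C"):
            assert t.loc[term, "sum_sq"] == pytest.approx(
                8 * fit.coefficients[term] ** 2, rel=1e-9
            )

    def test_partial_ss_equal_sequential_on_orthogonal_design(self, bbd_fit):
        # drop-one refits: SS_j = SS_resid(without j) - SS_resid(full)
        design = bbd_fit.design
        X = _design_matrix(design.coded)
        y = design.response
        full_res = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        t = anova(bbd_fit).table
        for j, term in enumerate(TERM_NAMES):
            if term == "Intercept":
                continue
            Xr = np.delete(X, j, axis=1)
            red_res = y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]
            extra = float(red_res @ red_res - full_res @ full_res)
            assert t.loc[term, "sum_sq"] == pytest.approx(extra, rel=1e-6)

    def test_noiseless_data_has_zero_residual_and_lack_of_fit(self):
        beta = np.array([60.0, 1.0, 1.0, 1.0, 0.5, 0.5, 0.5, -2.0, -2.0, -2.0])
        t = anova(fit_quadratic(make_experiment(beta))).table
        assert t.loc["Residual", "sum_sq"] == pytest.approx(0.0, abs=1e-16)
        assert t.loc["Lack of Fit", "sum_sq"] == pytest.approx(0.0, abs=1e-16)

    def test_p_values_match_f_distribution(self, bbd_fit):
        from scipy import stats

        t = anova(bbd_fit).table
        row = t.loc["A"]
        assert row["p"] == pytest.approx(stats.f.sf(row["F"], 1, 7), rel=1e-12)
        # reference point of the F table: F(0.05; 1, 7) = 5.59
        assert stats.f.isf(0.05, 1, 7) == pytest.approx(5.59, abs=0.01)

    def test_center_replicate_sd_feeds_pure_error(self, bbd_fit):
        y = bbd_fit.design.response[bbd_fit.design.is_center]
        expected = float(((y - y.mean()) ** 2).sum())
        t = anova(bbd_fit).table
        assert t.loc["Pure Error", "sum_sq"] == pytest.approx(expected, rel=1e-12)


class TestFindOptimum:
    def test_bundled_design_optimum_matches_reported_conditions(self, bbd_fit):
        opt = find_optimum(bbd_fit, DEFAULT_CODING)
        assert opt.interior
        assert opt.natural["pH"] == pytest.approx(8.70, abs=0.05)
        assert opt.natural["temperature"] == pytest.approx(56.0, abs=0.5)
        assert opt.natural["time"] == pytest.approx(3.1, abs=0.1)
        assert opt.predicted == pytest.approx(66.31, abs=0.5)

    def test_concave_separable_surface_peaks_at_center(self):
        beta = np.array([50.0, 0, 0, 0, 0, 0, 0, -1.0, -1.0, -1.0])
        opt = find_optimum(fit_quadratic(make_experiment(beta)))
        np.testing.assert_allclose(opt.coded, np.zeros(3), atol=1e-8)
        assert opt.predicted == pytest.approx(50.0)

    def test_vertex_optimum_found_with_warning(self):
        # purely linear rising surface -> maximum at the (1,1,1) vertex
        beta = np.array([50.0, 2.0, 1.0, 3.0, 0, 0, 0, 0, 0, 0])
        opt = find_optimum(fit_quadratic(make_experiment(beta)))
        np.testing.assert_allclose(opt.coded, np.ones(3), atol=1e-6)
        assert not opt.interior
        assert opt.warning is not None

    def test_agrees_with_coarse_grid_oracle_on_random_quadratics(self):
        # a light version of the dense-grid comparison in the acceptance suite
        rng = np.random.default_rng(314)
        grid = np.linspace(-1, 1, 41)  # step 0.05
        A, B, C = np.meshgrid(grid, grid, grid, indexing="ij")
        for _ in range(12):
            beta = np.concatenate(
                [[50.0], rng.normal(0, 2, 3), rng.normal(0, 1, 3), rng.normal(-2, 2, 3)]
            )
            fit = fit_quadratic(make_experiment(beta))
            vals = (
                beta[0] + beta[1] * A + beta[2] * B + beta[3] * C
                + beta[4] * A * B + beta[5] * A * C + beta[6] * B * C
                + beta[7] * A**2 + beta[8] * B**2 + beta[9] * C**2
            )
            opt = find_optimum(fit)
            assert opt.predicted >= vals.max() - 1e-6
            k = np.argmax(vals)
            x_grid = np.array([A.ravel()[k], B.ravel()[k], C.ravel()[k]])
            assert np.max(np.abs(opt.coded - x_grid)) <= 0.05 + 1e-9


class TestParameterRecovery:
    def test_coefficient_estimates_unbiased_across_seeds(self):
        sigma = 0.9
        estimates = []
        for seed in range(200):
            design, truth = gen_bbd(seed, sigma=sigma)
            fit = fit_quadratic(design)
            estimates.append([fit.coefficients[t] for t in TERM_NAMES])
        estimates = np.asarray(estimates)
        truth_vec = np.array([truth[t] for t in TERM_NAMES])
        mean_est = estimates.mean(axis=0)
        se_mean = estimates.std(axis=0, ddof=1) / np.sqrt(len(estimates))
        assert np.all(np.abs(mean_est - truth_vec) < 3 * se_mean + 1e-12)
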