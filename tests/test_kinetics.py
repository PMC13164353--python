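"""Inhibition percentages, Michaelis-Menten fits, mode calls, Ki, IC50."""

import numpy as np
import pytest

from acepep import (
    AbsorbanceAssay,
    KineticSeries,
    classify,
    estimate_ki,
    fit_ic50,
    fit_series,
    inhibition_percent,
    mg_per_ml_to_micromolar,
)
from acepep.kinetics import _four_pl, _michaelis_menten
from acepep.simulate import gen_dose_response, gen_kinetics


class TestInhibitionPercent:
    def test_printed_formula(self):
        assay = AbsorbanceAssay(a1=1.0, a2=0.4, b1=0.9, b2=0.6)
        assert inhibition_percent(assay) == pytest.approx(50.0)

    def test_sample_matching_blank_is_zero(self):
        assert inhibition_percent(
            AbsorbanceAssay(a1=1.0, a2=0.4, b1=0.8, b2=0.2)
        ) == pytest.approx(0.0)

    def test_flat_sample_is_complete_inhibition(self):
        assert inhibition_percent(
            AbsorbanceAssay(a1=1.0, a2=0.4, b1=0.7, b2=0.7)
        ) == pytest.approx(100.0)

    def test_affine_invariance_under_common_rescaling(self):
        base = AbsorbanceAssay(1.0, 0.4, 0.9, 0.6)
        scaled = AbsorbanceAssay(2.5, 1.0, 2.25, 1.5)
        assert inhibition_percent(base) == pytest.approx(inhibition_percent(scaled))

    def test_activation_warns_but_returns(self):
        with pytest.warns(UserWarning, match="negative inhibition"):
            value = inhibition_percent(AbsorbanceAssay(1.0, 0.6, 1.0, 0.5))
        assert value == pytest.approx(-25.0)

    def test_stalled_blank_rejected(self):
        with pytest.raises(ValueError, match="a1 > a2"):
            AbsorbanceAssay(a1=0.4, a2=0.4, b1=0.9, b2=0.6)


class TestFitSeries:
    def make_series(self, vmax=1.0, km=0.5, inhibitor=0.0, s=None):
        s = np.array([0.25, 0.5, 1.0, 2.0]) if s is None else s
        return KineticSeries(inhibitor, s, _michaelis_menten(s, vmax, km))

    @pytest.mark.parametrize("method", ["reciprocal", "nls"])
    def test_noiseless_data_recovered_exactly(self, method):
        fit = fit_series(self.make_series(), method=method)
        assert fit.vmax == pytest.approx(1.0, abs=1e-8)
        assert fit.km == pytest.approx(0.5, abs=1e-8)

    def test_reciprocal_plot_intercepts(self):
        fit = fit_series(self.make_series(), method="reciprocal")
        assert fit.y_intercept == pytest.approx(1.0 / fit.vmax)
        assert fit.x_intercept == pytest.approx(-1.0 / fit.km)
        assert fit.slope == pytest.approx(fit.km / fit.vmax)

    def test_competitive_inhibition_at_ki_doubles_km(self):
        # closed form: Km_app = Km (1 + [I]/Ki); at [I]=Ki it doubles
        km_app = 0.5 * 2.0
        fit = fit_series(self.make_series(km=km_app, inhibitor=10.0))
        assert fit.km == pytest.approx(1.0, abs=1e-8)
        assert fit.vmax == pytest.approx(1.0, abs=1e-8)

    def test_methods_agree_on_noisy_data(self):
        rng = np.random.default_rng(8)
        s = np.geomspace(0.1, 5.0, 8)
        v = _michaelis_menten(s, 1.0, 0.5) * (1 + 0.02 * rng.standard_normal(8))
        series = KineticSeries(0.0, s, v)
        fr = fit_series(series, "reciprocal")
        fn = fit_series(series, "nls")
        assert fr.vmax == pytest.approx(fn.vmax, rel=0.05)
        assert fr.km == pytest.approx(fn.km, rel=0.15)

    def test_nls_beats_reciprocal_under_multiplicative_noise(self):
        err = {"reciprocal": [], "nls": []}
        s = np.geomspace(0.1, 5.0, 8)
        for seed in range(150):
            rng = np.random.default_rng(seed)
            v = _michaelis_menten(s, 1.0, 0.5) * (1 + 0.05 * rng.standard_normal(8))
            series = KineticSeries(0.0, s, np.clip(v, 1e-6, None))
            for method in err:
                fit = fit_series(series, method)
                err[method].append((fit.vmax - 1.0) ** 2 + (fit.km - 0.5) ** 2)
        assert np.mean(err["nls"]) < np.mean(err["reciprocal"])

    def test_too_few_substrate_levels_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            KineticSeries(0.0, np.array([1.0, 1.0, 2.0]), np.array([0.5, 0.5, 0.6]))


class TestClassify:
    @pytest.mark.parametrize("mode", ["competitive", "non-competitive", "mixed"])
    def test_generator_round_trip(self, mode):
        series, truth = gen_kinetics(12345, mode, noise_cv=0.01)
        fits = [fit_series(s, "nls") for s in series]
        verdict = classify(fits)
        assert verdict.mode == mode
        assert verdict.ki == pytest.approx(truth["ki"], rel=0.25)

    def test_competitive_ki_recovery(self):
        series, truth = gen_kinetics(7, "competitive", noise_cv=0.0)
        fits = [fit_series(s, "nls") for s in series]
        verdict = classify(fits)
        assert verdict.mode == "competitive"
        assert verdict.ki == pytest.approx(10.0, rel=1e-6)

    def test_km_decrease_yields_none_with_diagnostic(self):
        # an uncompetitive-like trajectory: both parameters shrink
        series = []
        for conc in (0.0, 10.0, 20.0):
            f = 1.0 + conc / 10.0
            s = np.geomspace(0.2, 5.0, 6)
            series.append(KineticSeries(conc, s, _michaelis_menten(s, 1.0 / f, 1.0 / f)))
        verdict = classify([fit_series(s, "nls") for s in series])
        assert verdict.mode == "none"
        assert "Km decreased" in verdict.diagnostic

    def test_duplicate_zero_only_input_rejected(self):
        s = np.geomspace(0.2, 5.0, 6)
        fits = [
            fit_series(KineticSeries(0.0, s, _michaelis_menten(s, 1.0, 1.0)), "nls")
        ]
        with pytest.raises(ValueError, match="no contrast"):
            classify(fits * 2)

    def test_classification_accuracy_over_noise_grid(self):
        # 3 modes x 3 noise levels x 100 seeds of triplicate assays
        correct = total = 0
        for mode in ("competitive", "non-competitive", "mixed"):
            for noise in (0.01, 0.02, 0.05):
                for seed in range(100):
                    series, _ = gen_kinetics(seed, mode, noise_cv=noise)
                    fits = [fit_series(s, "nls") for s in series]
                    total += 1
                    correct += classify(fits).mode == mode
        assert correct / total >= 0.95

    def test_ki_relative_error_below_ten_percent_at_two_percent_noise(self):
        errors = []
        for seed in range(60):
            series, truth = gen_kinetics(seed, "competitive", noise_cv=0.02)
            fits = [fit_series(s, "reciprocal") for s in series]
            errors.append(abs(estimate_ki(fits) - truth["ki"]) / truth["ki"])
        assert np.median(errors) < 0.10


class TestIC50:
    def test_noiseless_round_trip_with_planted_value(self):
        conc, inhibition, truth = gen_dose_response(1, ic50=16.9, noise_sd=0.0)
        dr = fit_ic50(conc, inhibition)
        assert dr.ic50 == pytest.approx(16.9, abs=1e-6)
        assert dr.in_span

    def test_log_symmetry_of_ic50(self):
        conc = 16.9 * np.geomspace(0.1, 10.0, 9)
        y = _four_pl(conc, 0.0, 100.0, 16.9, 1.0)
        reflected = 16.9**2 / conc  # mirror on the log-concentration axis
        dr1 = fit_ic50(conc, y)
        dr2 = fit_ic50(reflected, 100.0 - y + dr1.bottom)
        assert dr1.ic50 == pytest.approx(16.9, abs=1e-6)
        assert dr2.ic50 == pytest.approx(16.9, rel=1e-4)

    def test_median_bias_below_five_percent_over_500_seeds(self):
        estimates = [
            fit_ic50(*gen_dose_response(seed, ic50=16.9, noise_sd=2.0)[:2]).ic50
            for seed in range(500)
        ]
        assert abs(np.median(estimates) / 16.9 - 1.0) < 0.05

    def test_out_of_span_ic50_flagged(self):
        conc = np.geomspace(100.0, 1000.0, 6)
        y = _four_pl(conc, 0.0, 100.0, 5.0, 1.0)
        with pytest.warns(UserWarning, match="outside the measured span"):
            dr = fit_ic50(conc, y)
        assert not dr.in_span

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_ic50([1, 2, 3, 4], [10, 30, 60, 90])


class TestUnitConversion:
    def test_known_pentapeptide_mass(self):
        # IDFDF: average mass ~ 655.7 g/mol -> 1 mg/mL ~ 1525 uM
        assert mg_per_ml_to_micromolar(1.0, "IDFDF") == pytest.approx(1525, rel=0.01)

    def test_linear_in_concentration(self):
        one = mg_per_ml_to_micromolar(1.0, "SFHRL")
        assert mg_per_ml_to_micromolar(0.5, "SFHRL") == pytest.approx(one / 2)
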