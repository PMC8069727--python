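import math

import numpy as np
import pandas as pd
import pytest

from denatkin.io import Thermogram
from denatkin.kinetics import (ConversionCurve, R_GAS, aggregate_fits,
                               coats_redfern_fit, conversion_from_peak,
                               model_f, model_g, reconstruct_alpha,
                               select_model)
from denatkin.peaks import Peak, detect_peaks
from denatkin.published import herring_dsc_results
from denatkin.evaluate import spearman_r

from conftest import BETA, make_peak_spec, single_peak_sim


class TestModelForms:
    @pytest.mark.parametrize("symbol,alpha,expected", [
        ("F1", 0.0, 0.0),
        ("F1", 0.5, math.log(2)),
        ("F2", 0.5, 1.0),
        ("F2", 0.0, 0.0),
    ])
    def test_integral_form_closed_values(self, symbol, alpha, expected):
        assert model_g(symbol, alpha) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("symbol,alpha,expected", [
        ("F1", 0.0, 1.0),
        ("F1", 0.5, 0.5),
        ("F2", 0.5, 0.25),
    ])
    def test_differential_form_closed_values(self, symbol, alpha, expected):
        assert model_f(symbol, alpha) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("symbol", ["F1", "F2"])
    def test_f_is_reciprocal_slope_of_g(self, symbol):
        # finite-difference oracle: f(a) * g'(a) == 1
        a, h = 0.3, 1e-6
        deriv = (model_g(symbol, a + h) - model_g(symbol, a - h)) / (2 * h)
        assert model_f(symbol, a) * deriv == pytest.approx(1.0, abs=1e-6)

    def test_rejects_alpha_one_and_unknown_symbol(self):
        with pytest.raises(ValueError):
            model_g("F1", 1.0)
        with pytest.raises(ValueError):
            model_g("F9", 0.5)
        with pytest.raises(ValueError):
            model_f("F9", 0.5)


class TestConversionFromPeak:
    def test_symmetric_triangle_reaches_half_at_apex(self):
        t = np.arange(40.0, 60.0 + 1e-9, 0.1)
        apex = 50.0
        hf = np.clip(1.0 - np.abs(t - apex) / 5.0, 0.0, None)
        tg = Thermogram(t, hf, mass=10.0, beta=5.0)
        pk = Peak(index=1, T_onset=45.0, T_end=55.0, T_d=apex)
        curve = conversion_from_peak(tg, pk, tail_correction=False)
        mid = np.interp(apex + 273.15, curve.temperature, curve.alpha)
        assert mid == pytest.approx(0.5, abs=1e-3)

    def test_all_zero_window_rejected(self):
        t = np.arange(20.0, 90.0, 0.1)
        tg = Thermogram(t, np.zeros_like(t), mass=10.0, beta=5.0)
        pk = Peak(index=1, T_onset=30.0, T_end=60.0, T_d=45.0)
        with pytest.raises(ValueError, match="zero area"):
            conversion_from_peak(tg, pk)

    def test_matches_forward_simulated_alpha(self, f1_peak_sim):
        from denatkin.simulate import simulate_conversion
        spec, tg, _ = f1_peak_sim
        pk = detect_peaks(tg)[0]
        curve = conversion_from_peak(tg, pk)
        truth = simulate_conversion(spec.peaks[0], spec.beta, curve.temperature)
        assert np.max(np.abs(curve.alpha - truth.alpha)) < 0.01

    def test_endpoint_invariants_after_normalization(self, f1_peak_sim):
        _, tg, _ = f1_peak_sim
        curve = conversion_from_peak(tg, detect_peaks(tg)[0])
        assert curve.alpha[0] <= 0.01
        assert curve.alpha[-1] >= 0.99


class TestCoatsRedfern:
    def test_exact_line_recovers_forced_parameters(self):
        # y = ln(g/T^2) = -18000*x + c with x = 1/T implies E = 18000*R
        T = np.arange(320.0, 340.0, 0.2)
        c = math.log(0.5 / (330.0**2)) + 18000.0 / 330.0
        g = T**2 * np.exp(c - 18000.0 / T)
        alpha = 1.0 - np.exp(-g)          # invert F1
        curve = ConversionCurve(T, alpha)
        fit = coats_redfern_fit(curve, "F1", BETA, (0.01, 0.99))
        assert fit.E == pytest.approx(18000 * R_GAS, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(-18000.0, rel=1e-9)

    def test_ols_equals_brute_force_closed_form(self):
        rng = np.random.default_rng(0)
        T = np.linspace(310.0, 350.0, 60)
        alpha = np.clip(np.sort(rng.uniform(0.02, 0.98, T.size)), 0.02, 0.98)
        curve = ConversionCurve(T, alpha)
        fit = coats_redfern_fit(curve, "F1", BETA)
        mask = (alpha >= 0.05) & (alpha <= 0.95)
        x = 1.0 / T[mask]
        y = np.log(-np.log(1 - alpha[mask]) / T[mask] ** 2)
        n = x.size
        slope = (n * np.sum(x * y) - x.sum() * y.sum()) / (n * np.sum(x * x) - x.sum() ** 2)
        intercept = (y.sum() - slope * x.sum()) / n
        assert fit.slope == pytest.approx(slope, abs=1e-9 * abs(slope))
        assert fit.intercept == pytest.approx(intercept, abs=1e-9 * abs(intercept))

    def test_noiseless_f1_curve_recovery(self):
        from denatkin.simulate import simulate_conversion
        spec = make_peak_spec("F1", 2.0e5, 330.0)
        grid = np.arange(330.0 - 50, 330.0 + 50, 0.1)
        curve = simulate_conversion(spec, BETA, grid)
        fit = coats_redfern_fit(curve, "F1", BETA)
        assert fit.E == pytest.approx(2.0e5, rel=0.01)
        assert abs(math.log10(fit.A / spec.A)) < 0.1

    def test_wrong_model_has_strictly_lower_r_squared(self):
        from denatkin.simulate import simulate_conversion
        spec = make_peak_spec("F1", 2.0e5, 330.0)
        grid = np.arange(280.0, 380.0, 0.1)
        curve = simulate_conversion(spec, BETA, grid)
        good = coats_redfern_fit(curve, "F1", BETA)
        bad = coats_redfern_fit(curve, "F2", BETA)
        assert bad.r_squared < good.r_squared

    def test_too_few_points_rejected(self):
        curve = ConversionCurve(np.linspace(320, 330, 12),
                                np.linspace(0.0, 0.04, 12))
        with pytest.raises(ValueError, match="need >= 10"):
            coats_redfern_fit(curve, "F1", BETA)


class TestSelectModel:
    @pytest.mark.parametrize("model", ["F1", "F2"])
    def test_generating_model_is_selected(self, model):
        from denatkin.simulate import simulate_conversion
        spec = make_peak_spec(model, 1.8e5, 335.0)
        grid = np.arange(285.0, 395.0, 0.1)
        curve = simulate_conversion(spec, BETA, grid)
        fit = select_model(curve, BETA, ("F1", "F2"))
        assert fit.model == model

    def test_single_candidate_always_returned(self, f1_peak_sim):
        _, tg, _ = f1_peak_sim
        curve = conversion_from_peak_from(tg)
        fit = select_model(curve, BETA, ("F1",))
        assert fit.model == "F1"
        assert 0.0 <= fit.r_squared <= 1.0

    def test_empty_candidates_rejected(self, f1_peak_sim):
        _, tg, _ = f1_peak_sim
        with pytest.raises(ValueError):
            select_model(conversion_from_peak_from(tg), BETA, ())


def conversion_from_peak_from(tg):
    return conversion_from_peak(tg, detect_peaks(tg)[0])


class TestReconstruct:
    def test_round_trip_supnorm_below_002(self, f1_peak_sim):
        _, tg, _ = f1_peak_sim
        curve = conversion_from_peak_from(tg)
        fit = select_model(curve, BETA)
        theo = reconstruct_alpha(fit, curve.temperature, BETA)
        assert np.max(np.abs(theo.alpha - curve.alpha)) < 0.02

    def test_spearman_of_round_trip_is_one(self, f1_peak_sim):
        _, tg, _ = f1_peak_sim
        curve = conversion_from_peak_from(tg)
        fit = select_model(curve, BETA)
        theo = reconstruct_alpha(fit, curve.temperature, BETA)
        assert spearman_r(curve.alpha, theo.alpha) > 0.999

    def test_alpha_negligible_far_below_the_transition(self, f1_peak_sim):
        _, tg, _ = f1_peak_sim
        fit = select_model(conversion_from_peak_from(tg), BETA)
        grid = np.arange(330.0 - 70, 330.0 - 40, 0.1)
        theo = reconstruct_alpha(fit, grid, BETA)
        assert np.all(theo.alpha < 0.01)


class TestAggregateFits:
    def test_reference_herring_peak_means_and_sds(self):
        agg = aggregate_fits(herring_dsc_results()).set_index("peak")
        # denaturation temperatures, all four transitions
        assert agg.loc[1, "Td_mean"] == pytest.approx(43.45, abs=0.005)
        assert agg.loc[1, "Td_sd"] == pytest.approx(0.89, abs=0.005)
        assert agg.loc[4, "Td_mean"] == pytest.approx(77.91, abs=0.005)
        assert agg.loc[4, "Td_sd"] == pytest.approx(0.81, abs=0.005)
        # activation energies: self-consistent cells
        assert agg.loc[1, "E_mean"] == pytest.approx(152.7, abs=0.05)
        assert agg.loc[4, "E_mean"] == pytest.approx(158.09, abs=0.005)
        assert agg.loc[4, "E_sd"] == pytest.approx(69.82, abs=0.005)
        assert list(agg["model"]) == ["F1", "F1", "F2", "F1"]

    def test_single_value_mean_is_value_and_sd_zero(self):
        df = pd.DataFrame([{"sample": "A", "peak": 1, "Td_C": 43.5,
                            "model": "F1", "E_J_per_mol": 1e5,
                            "A_per_min": 1e10}])
        agg = aggregate_fits(df)
        assert agg["Td_mean"].iloc[0] == 43.5
        assert agg["Td_sd"].iloc[0] == 0.0
        assert agg["E_sd"].iloc[0] == 0.0

    def test_geometric_mean_option(self):
        df = pd.DataFrame([
            {"sample": "A", "peak": 1, "Td_C": 43.0, "model": "F1",
             "E_J_per_mol": 1e5, "A_per_min": 1e8},
            {"sample": "B", "peak": 1, "Td_C": 44.0, "model": "F1",
             "E_J_per_mol": 1e5, "A_per_min": 1e12},
        ])
        agg = aggregate_fits(df, geometric_A=True)
        assert agg["A_mean"].iloc[0] == pytest.approx(1e10, rel=1e-9)
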