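import dataclasses

import numpy as np
import pytest

from denatkin.kinetics import R_GAS
from denatkin.simulate import (DscSimSpec, KineticPeakSpec, RheoSimSpec,
                               default_dsc_spec, kissinger_preexponential,
                               preexponential_for_peak,
                               rate_maximum_temperature, simulate_conversion,
                               synthesize_dsc, synthesize_rheo)

from conftest import BETA, make_peak_spec, single_peak_sim


class TestSimulateConversion:
    def test_zero_rate_keeps_alpha_constant(self):
        spec = make_peak_spec("F1")
        object.__setattr__(spec, "A", 0.0)  # degenerate case, invariant bypassed
        grid = np.arange(300.0, 340.0, 0.5)
        curve = simulate_conversion(spec, BETA, grid, alpha0=0.2)
        np.testing.assert_array_equal(curve.alpha, 0.2)

    def test_kissinger_placement_of_rate_maximum(self):
        # A solved from E*beta/(R*Tp^2) = A*exp(-E/(R*Tp)) must put the
        # numerical rate maximum at Tp for first-order kinetics
        E, Tp = 2.5e5, 316.6
        A = kissinger_preexponential(E, Tp, BETA)
        spec = KineticPeakSpec("F1", E, A, 1.0)
        assert rate_maximum_temperature(spec, BETA, Tp) == pytest.approx(Tp, abs=0.5)

    @pytest.mark.parametrize("model", ["F1", "F2"])
    def test_numeric_placement_for_both_models(self, model):
        E, Tp = 1.8e5, 340.0
        A = preexponential_for_peak(model, E, Tp, BETA)
        spec = KineticPeakSpec(model, E, A, 1.0)
        assert rate_maximum_temperature(spec, BETA, Tp) == pytest.approx(Tp, abs=0.2)

    def test_completeness_far_past_the_peak(self):
        E, Tp = 2.5e5, 316.6
        spec = make_peak_spec("F1", E, Tp)
        grid = np.arange(Tp - 40, Tp + 60, 0.1)
        curve = simulate_conversion(spec, BETA, grid)
        assert curve.alpha[-1] > 0.999
        # cross-check against a 10x finer internal step
        fine = simulate_conversion(spec, BETA, grid, max_step=0.01)
        assert abs(fine.alpha[-1] - curve.alpha[-1]) < 1e-9

    @pytest.mark.parametrize("model,E,Tp", [("F1", 8e4, 315.0), ("F1", 2.5e5, 350.0),
                                            ("F2", 1.5e5, 330.0)])
    def test_step_halving_changes_alpha_below_1e6(self, model, E, Tp):
        spec = make_peak_spec(model, E, Tp)
        grid = np.arange(Tp - 50, Tp + 50, 0.5)
        a1 = simulate_conversion(spec, BETA, grid, max_step=0.1).alpha
        a2 = simulate_conversion(spec, BETA, grid, max_step=0.05).alpha
        assert np.max(np.abs(a1 - a2)) < 1e-6

    def test_alpha_nondecreasing_and_bounded(self):
        spec = make_peak_spec("F2", 1.2e5, 325.0)
        grid = np.arange(250.0, 420.0, 0.25)
        a = simulate_conversion(spec, BETA, grid).alpha
        assert np.all(np.diff(a) >= 0)
        assert a[0] >= 0 and a[-1] < 1

    def test_invalid_inputs_rejected(self):
        spec = make_peak_spec()
        with pytest.raises(ValueError):
            simulate_conversion(spec, BETA, np.array([330.0, 320.0]))
        with pytest.raises(ValueError):
            simulate_conversion(spec, BETA, np.array([-5.0, 320.0]))
        with pytest.raises(ValueError):
            simulate_conversion(spec, BETA, np.arange(300, 320), alpha0=1.0)


class TestSynthesizeDsc:
    def test_enthalpy_conservation_noiseless(self, f1_peak_sim):
        # noiseless, baseline-free signal must integrate (over time) to
        # mass * sum(delta_H) within 0.5%
        spec, tg, truth = f1_peak_sim
        time_min = tg.temperature / spec.beta
        area_mJ = np.trapezoid(truth.noiseless, time_min) * 60.0
        expected = spec.mass * sum(p.delta_H for p in spec.peaks)
        assert area_mJ == pytest.approx(expected, rel=0.005)

    def test_multi_peak_enthalpy_conservation(self):
        spec = default_dsc_spec()
        tg, truth = synthesize_dsc(spec)
        time_min = tg.temperature / spec.beta
        area_mJ = np.trapezoid(truth.noiseless, time_min) * 60.0
        expected = spec.mass * sum(p.delta_H for p in spec.peaks)
        assert area_mJ == pytest.approx(expected, rel=0.005)

    def test_ground_truth_reports_rate_maximum(self, f1_peak_sim):
        _, _, truth = f1_peak_sim
        assert truth.peaks[0].T_d == pytest.approx(330.0 - 273.15, abs=0.2)

    def test_same_seed_is_bit_identical(self):
        _, tg1, _ = single_peak_sim(noise_sd=0.01, seed=11)
        _, tg2, _ = single_peak_sim(noise_sd=0.01, seed=11)
        assert np.array_equal(tg1.heat_flow, tg2.heat_flow)

    def test_different_seeds_share_the_noiseless_component(self):
        _, tg1, tr1 = single_peak_sim(noise_sd=0.01, seed=1)
        _, tg2, tr2 = single_peak_sim(noise_sd=0.01, seed=2)
        assert np.array_equal(tr1.noiseless, tr2.noiseless)
        assert not np.array_equal(tg1.heat_flow, tg2.heat_flow)

    def test_severe_overlap_sets_warning_flag(self):
        p1 = make_peak_spec("F1", 3.0e5, 330.0)
        p2 = make_peak_spec("F1", 3.0e5, 331.0)
        spec = DscSimSpec(peaks=(p1, p2), T_start=20.0, T_end=95.0)
        _, truth = synthesize_dsc(spec)
        assert truth.overlap_warning

    def test_default_spec_peaks_are_ordered_and_distinct(self):
        _, truth = synthesize_dsc(default_dsc_spec())
        td = [p.T_d for p in truth.peaks]
        assert td == sorted(td)
        assert not truth.overlap_warning


class TestSynthesizeRheo:
    def test_delta_at_start_matches_spec_by_construction(self, default_rheo):
        spec, sweep, _ = default_rheo
        delta0 = np.degrees(np.arctan2(sweep.loss_modulus[0],
                                       sweep.storage_modulus[0]))
        assert delta0 == pytest.approx(spec.delta_start, abs=0.5)

    def test_loss_modulus_drop_to_ip1(self, default_rheo):
        spec, sweep, _ = default_rheo
        g0 = sweep.loss_modulus[0]
        g40 = np.interp(spec.ip1, sweep.temperature, sweep.loss_modulus)
        assert (g0 - g40) / g0 == pytest.approx((2.6 - 1.8) / 2.6, abs=0.01)

    def test_noise_seed_determinism(self):
        s1, _ = synthesize_rheo(RheoSimSpec(noise_rel=0.02, seed=5))
        s2, _ = synthesize_rheo(RheoSimSpec(noise_rel=0.02, seed=5))
        assert np.array_equal(s1.storage_modulus, s2.storage_modulus)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            RheoSimSpec(ip1=50.0, t_gel=45.0)      # landmarks out of order
        with pytest.raises(ValueError):
            RheoSimSpec(g_min=-1.0)                # non-positive anchor
        with pytest.raises(ValueError):
            RheoSimSpec(slope_pre=0.03, slope_post=0.01)
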