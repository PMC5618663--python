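"""Decay mathematics, single-cycle and global fits, recovery, decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import rsfpkit as rk
from rsfpkit.kinetics import _nnls2, fit_single_cycle, model_selection
from rsfpkit.synthetic import reference_field_experiment


KIN = rk.TwoStateKinetics(k_A=2.0, k_B=0.2, f_A=0.0, f_B=0.3, c=0.0)


class TestDecayModel:
    def test_initial_value_is_total_amplitude(self):
        kin = rk.TwoStateKinetics(k_A=2.0, k_B=0.2, f_B=0.3, c=0.5)
        assert rk.decay_model(0.0, kin, a=1.2, b=0.8) == pytest.approx(1.2 + 0.8 + 0.5)

    def test_plateau_at_long_times(self):
        kin = rk.TwoStateKinetics(k_A=2.0, k_B=0.2, f_A=0.1, f_B=0.3, c=0.5)
        assert rk.decay_model(1e6, kin, a=1.0, b=2.0) == pytest.approx(
            1.0 * 0.1 + 2.0 * 0.3 + 0.5
        )

    def test_matches_independent_evaluation(self):
        # term-by-term evaluation with math.exp, independent of the vectorized code
        expected = 1.0 * math.exp(-2.0 * 1.0) + 1.0 * (0.7 * math.exp(-0.2 * 1.0) + 0.3)
        assert rk.decay_model(1.0, KIN, a=1.0, b=1.0) == pytest.approx(expected, rel=1e-14)

    @given(
        t1=st.floats(0.0, 50.0),
        dt=st.floats(0.0, 50.0),
        a=st.floats(0.0, 10.0),
        b=st.floats(0.0, 10.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_non_increasing(self, t1, dt, a, b):
        assert rk.decay_model(t1 + dt, KIN, a, b) <= rk.decay_model(t1, KIN, a, b) + 1e-12

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            rk.TwoStateKinetics(k_A=0.2, k_B=2.0)
        with pytest.raises(ValueError):
            rk.TwoStateKinetics(k_A=2.0, k_B=0.2, f_A=0.5, f_B=0.1)


class TestNNLS:
    def test_two_variable_solver_matches_scipy(self, rng):
        from scipy.optimize import nnls as scipy_nnls

        t = np.linspace(0, 2.4, 25)
        for _ in range(200):
            s1 = np.exp(-rng.uniform(0.5, 8) * t)
            s2 = np.exp(-rng.uniform(0.05, 0.5) * t) + rng.uniform(0, 0.3)
            y = rng.normal(rng.uniform(-1, 2) * s1 + rng.uniform(-1, 2) * s2, 0.05)
            ours = _nnls2(s1, s2, y)
            ref, _ = scipy_nnls(np.column_stack([s1, s2]), y)
            np.testing.assert_allclose(ours, ref, atol=1e-9)


class TestSingleCycleFit:
    def test_mono_exponential_recovered_and_order_one_preferred(self):
        t = np.linspace(0, 2.4, 25)
        y = 1.3 * np.exp(-2.1 * t) + 0.05
        f1, f2, preferred = model_selection(t, y)
        assert preferred == 1
        assert f1.k_A == pytest.approx(2.1, rel=1e-6)
        assert f1.a == pytest.approx(1.3, rel=1e-6)

    def test_loglinear_regression_oracle_for_pure_exponential(self):
        t = np.linspace(0, 2.4, 25)
        y = 0.8 * np.exp(-1.7 * t)
        fit = fit_single_cycle(t, y, order=1)
        slope, *_ = stats.linregress(t, np.log(y))
        assert fit.k_A == pytest.approx(-slope, rel=1e-6)

    def test_two_species_recovered_and_order_two_preferred(self):
        t = np.linspace(0, 2.4, 25)
        kin = rk.TwoStateKinetics(k_A=6.0, k_B=1.0, f_B=0.15, c=0.0)
        y = rk.decay_model(t, kin, a=1.0, b=0.5)
        f1, f2, preferred = model_selection(t, y)
        assert preferred == 2
        assert f2.k_A == pytest.approx(6.0, rel=1e-3)
        assert f2.k_B == pytest.approx(1.0, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_single_cycle(np.linspace(0, 1, 5), np.ones(5))


class TestGlobalFit:
    def test_noiseless_round_trip(self, noiseless_truth):
        truth = noiseless_truth()
        exp = rk.simulate_traces(rk.SwitchingProtocol.hela_default(60), truth)
        kin, amps, result = rk.global_fit(exp)
        assert result.success
        assert kin.k_A == pytest.approx(truth.kinetics.k_A, rel=1e-6)
        assert kin.k_B == pytest.approx(truth.kinetics.k_B, rel=1e-6)
        assert kin.f_B == pytest.approx(truth.kinetics.f_B, rel=1e-5)
        a_true, b_true = rk.population_closed_form(truth.popdyn, np.arange(60.0))
        np.testing.assert_allclose(amps.a, a_true, atol=1e-6)
        np.testing.assert_allclose(amps.b, b_true, atol=1e-6)

    def test_objective_not_worse_than_independent_per_cycle_fits(self):
        """The shared-kinetics objective can never beat the sum of free
        per-cycle fits (relaxation bound), and must be close on consistent data."""
        exp = reference_field_experiment(3, n_cycles=8, n_objects=5)
        kin, amps, result = rk.global_fit(exp)
        t = exp.protocol.off_local_times()
        free_rss = sum(
            fit_single_cycle(t, seg, order=2).result.rss
            for _, _, seg in exp.iter_off_segments()
        )
        assert result.rss >= free_rss - 1e-9

    def test_median_recovery_error_under_noise(self):
        """Median relative error of (k_A, k_B, f_B) across seeded noisy
        replicates stays within 5% at the default noise level."""
        errs = {"k_A": [], "k_B": [], "f_B": []}
        for seed in range(20):
            truth = rk.default_truth(seed)
            exp = reference_field_experiment(seed, n_cycles=120)
            kin, _, _ = rk.global_fit(exp)
            errs["k_A"].append(abs(kin.k_A - truth.kinetics.k_A) / truth.kinetics.k_A)
            errs["k_B"].append(abs(kin.k_B - truth.kinetics.k_B) / truth.kinetics.k_B)
            errs["f_B"].append(abs(kin.f_B - truth.kinetics.f_B) / truth.kinetics.f_B)
        for name, values in errs.items():
            assert np.median(values) <= 0.05, f"{name}: {np.median(values):.3f}"

    def test_single_species_consistent_with_single_cycle_fit(self, noiseless_truth):
        truth = noiseless_truth(k_AB=0.0, k_dA=0.0, k_dB=0.0, b0=0.0)
        proto = rk.SwitchingProtocol.hela_default(2)
        exp = rk.simulate_traces(proto, truth)
        kin, amps, _ = rk.global_fit(exp)
        single = fit_single_cycle(proto.off_local_times(), exp.mean_trace[proto.off_frame_indices(1)], order=1)
        assert kin.k_A == pytest.approx(single.k_A, rel=1e-4)

    def test_requires_multiple_cycles(self, noiseless_truth):
        proto = rk.SwitchingProtocol.hela_default(1)
        exp = rk.simulate_traces(proto, noiseless_truth())
        with pytest.raises(ValueError):
            rk.global_fit(exp)


class TestThermalRecovery:
    def test_noiseless_round_trip(self):
        truth = rk.default_truth(0, noise=rk.NoiseModel.noiseless())
        trace = rk.simulate_recovery_trace(truth, k_th=0.004, F0=0.1, Finf=0.9)
        fit = rk.fit_thermal_recovery(trace["time_s"], trace["intensity"])
        assert fit.k_th == pytest.approx(0.004, rel=1e-6)
        assert fit.F0 == pytest.approx(0.1, abs=1e-8)
        assert fit.Finf == pytest.approx(0.9, abs=1e-6)

    def test_flat_trace_gives_zero_rate_and_fraction(self):
        t = np.arange(0, 601, 30.0)
        fit = rk.fit_thermal_recovery(t, np.full_like(t, 0.4), F_on=1.0)
        assert fit.recovered_fraction == pytest.approx(0.0, abs=1e-6)

    def test_noisy_rate_recovery(self):
        truth = rk.default_truth(13, noise=rk.NoiseModel(shot_scale=0, read_sigma=0.01, background=0))
        trace = rk.simulate_recovery_trace(truth, k_th=0.006, F0=0.1, Finf=0.8)
        fit = rk.fit_thermal_recovery(trace["time_s"], trace["intensity"])
        assert fit.k_th == pytest.approx(0.006, rel=0.15)

    def test_decreasing_trace_flagged_as_positive_switcher(self):
        t = np.arange(0, 301, 30.0)
        y = 0.2 + 0.6 * np.exp(-0.01 * t)
        fit = rk.fit_thermal_recovery(t, y)
        assert any("positive_switcher" in f for f in fit.result.flags)

    def test_recovered_fraction_against_supplied_on_level(self):
        truth = rk.default_truth(0, noise=rk.NoiseModel.noiseless())
        trace = rk.simulate_recovery_trace(truth, duration=600, sampling=30, k_th=0.004, F0=0.1, Finf=0.9)
        fit = rk.fit_thermal_recovery(trace["time_s"], trace["intensity"], horizon=600, F_on=1.0)
        expected = (0.9 - (0.9 - 0.1) * math.exp(-0.004 * 600) - 0.1) / (1.0 - 0.1)
        assert fit.recovered_fraction == pytest.approx(expected, rel=1e-6)


class TestRateDecomposition:
    def test_pure_absorption_enhancement(self):
        out = rk.decompose_rate_enhancement(1.0, 1.2, 65e3, 78e3)
        assert out["intrinsic_factor"] == pytest.approx(1.0)
        assert out["attributed_fraction"] == pytest.approx(1.0)

    def test_half_attributed_case(self):
        out = rk.decompose_rate_enhancement(1.0, 1.4, 65e3, 78e3)
        assert out["intrinsic_factor"] == pytest.approx(7 / 6)
        assert out["attributed_fraction"] == pytest.approx(0.5)

    def test_no_absorption_change_attributes_nothing(self):
        out = rk.decompose_rate_enhancement(1.0, 1.5, 65e3, 65e3)
        assert out["attributed_fraction"] == pytest.approx(0.0)

    def test_equal_rates_undefined_fraction(self):
        out = rk.decompose_rate_enhancement(1.0, 1.0, 65e3, 78e3)
        assert out["attributed_fraction"] is None
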