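"""Generator contracts: determinism, analytic agreement, noise statistics."""

import math

import numpy as np
import pytest

import rsfpkit as rk
from rsfpkit.synthetic import reference_field_experiment


class TestSimulateTraces:
    def test_fixed_seed_regenerates_identical_arrays(self, short_protocol):
        truth = rk.default_truth(seed=11)
        a = rk.simulate_traces(short_protocol, truth, n_objects=3)
        b = rk.simulate_traces(short_protocol, truth, n_objects=3)
        np.testing.assert_array_equal(a.traces, b.traces)

    def test_different_seeds_differ(self, short_protocol):
        a = rk.simulate_traces(short_protocol, rk.default_truth(seed=1))
        b = rk.simulate_traces(short_protocol, rk.default_truth(seed=2))
        assert not np.array_equal(a.traces, b.traces)

    def test_single_species_gives_identical_cycles(self, noiseless_truth, short_protocol):
        """With only species A and no population evolution, every off-decay
        is the same mono-exponential-plus-plateau curve."""
        truth = noiseless_truth(k_AB=0.0, k_dA=0.0, k_dB=0.0, b0=0.0)
        exp = rk.simulate_traces(short_protocol, truth)
        segments = [seg for _, _, seg in exp.iter_off_segments()]
        for seg in segments[1:]:
            np.testing.assert_allclose(seg, segments[0], rtol=1e-12)
        # mono-exponential toward the plateau c (f_A = 0)
        t = short_protocol.off_local_times()
        kin = truth.kinetics
        np.testing.assert_allclose(
            segments[0], truth.popdyn.a0 * np.exp(-kin.k_A * t) + kin.c, rtol=1e-12
        )

    def test_species_b_rises_then_falls(self, noiseless_truth):
        """Slow species initially grows in abundance before declining."""
        truth = noiseless_truth(b0=0.0)
        n = np.arange(500.0)
        _, b = rk.population_closed_form(truth.popdyn, n)
        peak = int(np.argmax(b))
        assert 0 < peak < 499
        assert np.all(np.diff(b[: peak + 1]) > 0)
        assert np.all(np.diff(b[peak + 5 :]) < 0)

    def test_noiseless_off_frames_match_analytic_decay(self, noiseless_truth, short_protocol):
        truth = noiseless_truth()
        exp = rk.simulate_traces(short_protocol, truth)
        kin = truth.kinetics
        a_n, b_n = rk.population_closed_form(
            truth.popdyn, np.arange(short_protocol.n_cycles, dtype=float)
        )
        for cycle, t, seg in exp.iter_off_segments():
            # independent evaluation of the two-species decay, written out longhand
            expect = np.array(
                [
                    a_n[cycle - 1] * ((1 - kin.f_A) * math.exp(-kin.k_A * ti) + kin.f_A)
                    + b_n[cycle - 1] * ((1 - kin.f_B) * math.exp(-kin.k_B * ti) + kin.f_B)
                    + kin.c
                    for ti in t
                ]
            )
            np.testing.assert_allclose(seg, expect, rtol=1e-10)

    def test_conservation_without_destruction(self, noiseless_truth):
        truth = noiseless_truth(k_dA=0.0, k_dB=0.0)
        a, b = rk.population_closed_form(truth.popdyn, np.arange(300.0))
        np.testing.assert_allclose(a + b, truth.popdyn.a0 + truth.popdyn.b0, rtol=1e-10)

    def test_noisy_mean_converges_to_noiseless_value(self, short_protocol):
        """The mean of many noisy replicates of one frame approaches the
        noiseless expectation within 3 standard errors."""
        frame = short_protocol.normalization_frame_index
        clean = rk.simulate_traces(
            short_protocol, rk.default_truth(0, noise=rk.NoiseModel.noiseless())
        ).traces[0, frame]
        noise = rk.NoiseModel()
        vals = np.array(
            [
                rk.simulate_traces(short_protocol, rk.default_truth(seed)).traces[0, frame]
                for seed in range(1000)
            ]
        )
        target = clean + noise.background
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - target) < 3 * se

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            rk.TwoStateKinetics(k_A=float("nan"), k_B=1.0)
        with pytest.raises(ValueError):
            rk.PopulationDynamicsParams(k_AB=float("inf"), k_dA=0, k_dB=0, a0=1)

    def test_field_experiment_is_deterministic(self):
        a = reference_field_experiment(5, n_cycles=10, n_objects=4)
        b = reference_field_experiment(5, n_cycles=10, n_objects=4)
        np.testing.assert_array_equal(a.traces, b.traces)


class TestRecoveryTrace:
    def test_sample_count_includes_t_zero(self):
        trace = rk.simulate_recovery_trace(
            rk.default_truth(0, noise=rk.NoiseModel.noiseless()), duration=600, sampling=30
        )
        assert len(trace) == 21
        assert trace["time_s"].iloc[0] == 0.0

    def test_half_life_identity(self):
        k = 0.01
        truth = rk.default_truth(0, noise=rk.NoiseModel.noiseless())
        trace = rk.simulate_recovery_trace(
            truth, duration=2 * math.log(2) / k, sampling=math.log(2) / k, k_th=k, F0=0.2, Finf=1.0
        )
        halfway = trace["intensity"].iloc[1]
        assert halfway == pytest.approx(0.2 + (1.0 - 0.2) / 2, rel=1e-12)

    def test_zero_rate_gives_flat_trace(self):
        truth = rk.default_truth(0, noise=rk.NoiseModel.noiseless())
        trace = rk.simulate_recovery_trace(truth, duration=300, sampling=30, k_th=0.0, F0=0.3)
        np.testing.assert_allclose(trace["intensity"], 0.3)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rk.simulate_recovery_trace(rk.default_truth(0), duration=300, sampling=30, k_th=-1.0)


class TestTitration:
    def test_half_maximal_at_pka(self):
        table = rk.simulate_titration(pKa=6.2, A_max=2.0, pH_grid=[6.2])
        assert table["absorbance"].iloc[0] == pytest.approx(1.0, rel=1e-12)

    def test_saturates_far_above_pka(self):
        table = rk.simulate_titration(pKa=5.0, A_max=1.5, pH_grid=[11.0])
        assert table["absorbance"].iloc[0] == pytest.approx(1.5, rel=1e-5)

    def test_noiseless_curve_monotone_in_ph(self):
        table = rk.simulate_titration(pKa=6.8, hill=0.9)
        assert (np.diff(table["absorbance"]) > 0).all()


class TestColonyRendering:
    def test_constant_unit_trace_renders_disk_over_background(self, noiseless_truth):
        layout = rk.ColonyLayout(
            image_shape=(40, 40), objects=((20.0, 20.0, 5.0, 3.0),), background_level=1.0
        )
        proto = rk.SwitchingProtocol(n_cycles=1, on_periods=2, off_periods=2, period_duration=1.0)
        exp = rk.SwitchingExperiment(protocol=proto, traces=np.ones((1, 4)))
        stack = rk.render_colony_stack(exp, layout)
        assert stack.shape == (4, 40, 40)
        assert stack[0, 20, 20] == pytest.approx(1.0 + 3.0)
        assert stack[0, 0, 0] == pytest.approx(1.0)

    def test_zero_objects_gives_pure_background(self):
        layout = rk.ColonyLayout(image_shape=(16, 16), objects=(), background_level=0.7)
        proto = rk.SwitchingProtocol(n_cycles=1, on_periods=1, off_periods=1, period_duration=1.0)
        exp = rk.SwitchingExperiment(protocol=proto, traces=np.empty((0, 2)))
        stack = rk.render_colony_stack(exp, layout)
        np.testing.assert_allclose(stack, 0.7)

    def test_trace_object_count_mismatch_rejected(self):
        layout = rk.ColonyLayout(image_shape=(16, 16), objects=((8.0, 8.0, 3.0, 1.0),))
        proto = rk.SwitchingProtocol(n_cycles=1, on_periods=1, off_periods=1, period_duration=1.0)
        with pytest.raises(ValueError, match="objects"):
            rk.render_colony_stack(
                rk.SwitchingExperiment(protocol=proto, traces=np.ones((2, 2))), layout
            )

    def test_two_disks_match_bruteforce_per_pixel_render(self):
        layout = rk.ColonyLayout(
            image_shape=(30, 50),
            objects=((10.0, 12.0, 4.0, 1.5), (20.0, 38.0, 6.0, 0.5)),
            background_level=0.2,
        )
        proto = rk.SwitchingProtocol(n_cycles=1, on_periods=2, off_periods=1, period_duration=1.0)
        traces = np.array([[1.0, 0.5, 0.2], [2.0, 1.0, 0.4]])
        exp = rk.SwitchingExperiment(protocol=proto, traces=traces)
        stack = rk.render_colony_stack(exp, layout)
        # brute force: per-pixel loop, independent of the vectorized renderer
        for f in range(3):
            for r in range(30):
                for cc in range(0, 50, 3):
                    val = 0.2
                    for (orow, ocol, rad, scale), tr in zip(layout.objects, traces):
                        if (r - orow) ** 2 + (cc - ocol) ** 2 <= rad**2:
                            val += scale * tr[f]
                    assert stack[f, r, cc] == pytest.approx(val)

    def test_overlapping_or_outside_disks_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            rk.ColonyLayout(image_shape=(20, 20), objects=((2.0, 2.0, 5.0, 1.0),))
        layout = rk.random_layout(6, image_shape=(128, 128), seed=3)
        assert layout.n_objects == 6
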