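import numpy as np
import pytest

from transcoloc import (
    BoltzmannActivation,
    BoltzmannInactivation,
    SweepProtocol,
    conductance_curve,
    fit_activation,
    fit_inactivation,
    late_current_integral,
    measure_steady_state,
    measure_tail_peak,
    simulate_sweeps,
    subtract_sensitive,
)
from transcoloc.ephys import (
    ProtocolMismatchError,
    SweepSet,
    boltzmann_inactivation,
    boltzmann_iv,
)

IKR = dict(g_max_nS=10.0, v_rev_mV=-88.0, v_half_mV=-20.0, k_mV=-7.0)
VOLTS = tuple(np.arange(-50.0, 31.0, 10.0))


def ikr_sweeps(noise=0.0, seed=0, tau=0.0):
    proto = SweepProtocol(VOLTS, step_s=1.0)
    return simulate_sweeps(proto, tau_act_s=tau, noise_sd_pA=noise, seed=seed, **IKR)


class TestSubtraction:
    def test_identical_inputs_cancel(self):
        ss = ikr_sweeps()
        diff = subtract_sensitive(ss, ss)
        assert np.allclose(diff.currents_pA, 0.0)

    def test_zero_drug_trace_is_identity(self):
        ss = ikr_sweeps()
        zero = SweepSet(ss.time_s, np.zeros_like(ss.currents_pA),
                        ss.step_voltages_mV, epochs=ss.epochs)
        diff = subtract_sensitive(ss, zero)
        assert np.allclose(diff.currents_pA, ss.currents_pA)

    def test_drug_subtraction_recovers_component(self):
        # leak + channel; the drug removes the channel component
        channel = ikr_sweeps()
        leak = SweepSet(
            channel.time_s,
            np.outer(channel.step_voltages_mV * 0.1,
                     np.ones(channel.time_s.size)),
            channel.step_voltages_mV,
            epochs=channel.epochs,
        )
        pre = SweepSet(channel.time_s, channel.currents_pA + leak.currents_pA,
                       channel.step_voltages_mV, epochs=channel.epochs)
        diff = subtract_sensitive(pre, leak)
        assert np.allclose(diff.currents_pA, channel.currents_pA, atol=1e-9)

    def test_protocol_mismatch_rejected(self):
        a = ikr_sweeps()
        proto = SweepProtocol(tuple(np.arange(-40.0, 41.0, 10.0)), step_s=1.0)
        b = simulate_sweeps(proto, tau_act_s=0.0, **IKR)
        with pytest.raises(ProtocolMismatchError):
            subtract_sensitive(a, b)


class TestMeasurements:
    def test_constant_trace_mean(self):
        t = np.arange(0, 1.0, 0.001)
        ss = SweepSet(t, np.full((1, t.size), 10.0), [0.0],
                      epochs={"step": (0.0, 1.0)})
        iv = measure_steady_state(ss)
        assert iv["current_pA"].iloc[0] == pytest.approx(10.0)

    def test_linear_ramp_mean_offset(self):
        # ramp ending at v with slope m: window mean = v - m*window/2
        t = np.arange(0, 1.0, 0.001)
        slope = 40.0  # pA/s
        ss = SweepSet(t, (slope * t)[None, :], [0.0], epochs={"step": (0.0, 1.0)})
        iv = measure_steady_state(ss, window_ms=5.0)
        end_value = slope * t[-1]
        assert iv["current_pA"].iloc[0] == pytest.approx(
            end_value - slope * 0.005 / 2.0, abs=0.05
        )

    def test_window_longer_than_step_rejected(self):
        ss = ikr_sweeps()
        with pytest.raises(ValueError):
            measure_steady_state(ss, window_ms=5000.0)

    def test_noiseless_steady_state_matches_model(self):
        ss = ikr_sweeps()
        iv = measure_steady_state(ss)
        expected = boltzmann_iv(np.array(VOLTS), **{
            "g_max": 10.0, "v_rev": -88.0, "v_half": -20.0, "k": -7.0})
        assert np.allclose(iv["current_pA"], expected, rtol=1e-9)

    def test_tail_peaks_reproduce_envelope(self):
        ss = ikr_sweeps(tau=0.0)
        tails = measure_tail_peak(ss, polarity="auto")
        a_inf = 1.0 / (1.0 + np.exp((np.array(VOLTS) + 20.0) / -7.0))
        expected = 10.0 * a_inf * (-40.0 + 88.0)
        assert np.allclose(tails["current_pA"], expected, rtol=0.01)

    def test_flat_zero_tail(self):
        t = np.arange(0, 0.2, 0.001)
        ss = SweepSet(t, np.zeros((1, t.size)), [0.0],
                      epochs={"tail": (0.1, 0.2)})
        assert measure_tail_peak(ss)["current_pA"].iloc[0] == 0.0


class TestActivationFit:
    def test_noiseless_parameters_recovered_exactly(self):
        iv = measure_steady_state(ikr_sweeps())
        fit = fit_activation(iv["voltage_mV"], iv["current_pA"]).fit
        assert fit.g_max == pytest.approx(10.0, rel=1e-3)
        assert fit.v_rev == pytest.approx(-88.0, rel=1e-3)
        assert fit.v_half == pytest.approx(-20.0, rel=1e-3)
        assert fit.k == pytest.approx(-7.0, rel=1e-3)
        assert fit.direction == "activating"

    def test_midpoint_identity(self):
        fit = fit_activation(
            measure_steady_state(ikr_sweeps())["voltage_mV"],
            measure_steady_state(ikr_sweeps())["current_pA"],
        ).fit
        v = fit.v_half
        assert fit.predict(v) == pytest.approx(
            0.5 * (v - fit.v_rev) * fit.g_max, rel=1e-6
        )

    def test_voltage_order_and_scale_invariance(self):
        iv = measure_steady_state(ikr_sweeps())
        v = iv["voltage_mV"].to_numpy()
        i = iv["current_pA"].to_numpy()
        perm = np.random.default_rng(3).permutation(v.size)
        f1 = fit_activation(v[perm], i[perm], v_rev_mV=-88.0).fit
        f2 = fit_activation(v, 3.0 * i, v_rev_mV=-88.0).fit
        assert f1.v_half == pytest.approx(-20.0, abs=1e-6)
        assert f2.v_half == pytest.approx(-20.0, abs=1e-6)
        assert f2.g_max == pytest.approx(30.0, rel=1e-6)

    def test_noisy_v_half_recovery_within_1mV(self):
        scale = np.abs(ikr_sweeps().currents_pA).max()
        errs = []
        for seed in range(1, 21):
            iv = measure_steady_state(ikr_sweeps(noise=0.05 * scale, seed=seed))
            fit = fit_activation(iv["voltage_mV"], iv["current_pA"],
                                 v_rev_mV=-88.0).fit
            errs.append(abs(fit.v_half + 20.0))
        assert float(np.median(errs)) < 1.0

    def test_normalized_g_mode_on_tail_data(self):
        ss = ikr_sweeps()
        tails = measure_tail_peak(ss)
        res = BoltzmannActivation(tails["voltage_mV"], tails["current_pA"],
                                  mode="normalized_g").fit()
        assert res.fit.v_half == pytest.approx(-20.0, abs=0.1)
        assert abs(res.fit.k) == pytest.approx(7.0, abs=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            BoltzmannActivation([0, 10, 20], [1, 2, 3])


class TestInactivationFit:
    V = np.arange(-140.0, 21.0, 10.0)
    TRUTH = dict(i_min=-50.0, i_max=-900.0, v_max=-75.0, k=6.0)

    def test_noiseless_exact_recovery(self):
        i = boltzmann_inactivation(self.V, **self.TRUTH)
        fit = fit_inactivation(self.V, i).fit
        assert fit.i_min == pytest.approx(-50.0, rel=1e-4)
        assert fit.i_max == pytest.approx(-900.0, rel=1e-4)
        assert fit.v_max == pytest.approx(-75.0, rel=1e-4)
        assert fit.k == pytest.approx(6.0, rel=1e-4)

    def test_hyperpolarized_limit_is_i_min_as_printed(self):
        i = boltzmann_inactivation(np.array([-1000.0]), **self.TRUTH)
        assert i[0] == pytest.approx(self.TRUTH["i_min"])

    def test_noisy_v_max_recovery_within_1mV(self):
        i_true = boltzmann_inactivation(self.V, **self.TRUTH)
        errs = []
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            noisy = i_true + rng.normal(0, 0.05 * np.abs(i_true).max(),
                                        self.V.size)
            fit = BoltzmannInactivation(self.V, noisy).fit().fit
            errs.append(abs(fit.v_max + 75.0))
        assert float(np.median(errs)) < 1.0


class TestConductance:
    def test_ohmic_current_gives_flat_conductance(self):
        v = np.array([-40.0, -20.0, 0.0, 20.0, 40.0])
        gv, _ = conductance_curve(v, (v + 88.0) * 2.5, v_rev_mV=-88.0)
        assert np.allclose(gv["conductance_nS"], 2.5)

    def test_reversal_point_excluded_with_warning(self):
        v = np.array([-88.0, -40.0, -20.0, 0.0, 20.0, 40.0])
        with pytest.warns(UserWarning):
            gv, _ = conductance_curve(v, (v + 88.0) * 2.0, v_rev_mV=-88.0)
        assert len(gv) == 5

    def test_gmax_recovered_from_boltzmann_iv(self):
        iv = measure_steady_state(ikr_sweeps())
        gv, g_max = conductance_curve(iv["voltage_mV"], iv["current_pA"],
                                      v_rev_mV=-88.0)
        assert g_max == pytest.approx(10.0, rel=0.05)


class TestLateCurrent:
    def test_zero_trace_zero_integral(self):
        t = np.arange(0, 1.0, 0.001)
        q = late_current_integral(t, np.zeros_like(t), pulse_start_s=0.05,
                                  baseline="none")
        assert q == 0.0

    def test_exponential_matches_analytic(self):
        proto = SweepProtocol((-30.0,), pre_s=0.05, step_s=0.85, tail_mV=None)
        ss = simulate_sweeps(proto, g_max_nS=0.0, late_plateau_pA=-20.0,
                             late_tau_s=0.2)
        q = late_current_integral(ss.time_s, ss.currents_pA[0],
                                  pulse_start_s=0.05)
        tau, p = 0.2, -20.0
        analytic = p * tau * (np.exp(-0.05 / tau) - np.exp(-0.8 / tau)) * 1000.0
        assert q == pytest.approx(analytic, rel=0.005)

    def test_additive_over_subintervals_and_linear(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 1.0, 0.001)
        i = rng.normal(0, 1, t.size).cumsum()
        kw = dict(pulse_start_s=0.0, baseline="none")
        whole = late_current_integral(t, i, t0_ms=50, t1_ms=800, **kw)
        part = (late_current_integral(t, i, t0_ms=50, t1_ms=400, **kw)
                + late_current_integral(t, i, t0_ms=400, t1_ms=800, **kw))
        assert whole == pytest.approx(part, rel=1e-9)
        doubled = late_current_integral(t, 2 * i, t0_ms=50, t1_ms=800, **kw)
        assert doubled == pytest.approx(2 * whole, rel=1e-12)

    def test_window_outside_trace_rejected(self):
        t = np.arange(0, 0.5, 0.001)
        with pytest.raises(ValueError):
            late_current_integral(t, np.zeros_like(t), pulse_start_s=0.0,
                                  t1_ms=800.0, baseline="none")

    def test_prepulse_baseline_subtracted(self):
        proto = SweepProtocol((-30.0,), pre_s=0.05, step_s=0.85, tail_mV=None)
        ss = simulate_sweeps(proto, g_max_nS=0.0, late_plateau_pA=-2.0)
        shifted = ss.currents_pA[0] + 7.0  # constant amplifier offset
        q = late_current_integral(ss.time_s, shifted, pulse_start_s=0.05)
        assert q == pytest.approx(-1500.0, rel=1e-6)


class TestRoundTripAndIO:
    def test_full_round_trip_recovers_generator_parameters(self):
        scale = np.abs(ikr_sweeps().currents_pA).max()
        vh, gm = [], []
        for seed in range(1, 21):
            ss = ikr_sweeps(noise=0.05 * scale, seed=seed, tau=0.1)
            iv = measure_steady_state(ss)
            fit = fit_activation(iv["voltage_mV"], iv["current_pA"],
                                 v_rev_mV=-88.0).fit
            vh.append(abs(fit.v_half + 20.0))
            gm.append(abs(fit.g_max - 10.0) / 10.0)
        assert float(np.median(vh)) < 1.0
        assert float(np.median(gm)) < 0.05

    def test_frame_round_trip(self):
        ss = ikr_sweeps()
        frame = ss.to_frame()
        back = SweepSet.from_frame(frame, epochs=ss.epochs)
        assert np.allclose(back.currents_pA, ss.currents_pA)
        assert np.allclose(back.step_voltages_mV, ss.step_voltages_mV)
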