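"""Stimuli, voltage clamp with P/n leak subtraction, threshold detection and
rheobase search."""

import dataclasses
import math

import numpy as np
import pytest

import spikeinit as sp


class TestStimulusWaveforms:
    def test_step(self):
        stim = sp.StimulusProtocol.step(100.0, onset=2.0, offset=5.0)
        t = np.array([0.0, 1.9, 2.0, 4.9, 5.0, 10.0])
        assert np.allclose(stim.waveform(t), [0, 0, 100, 100, 0, 0])

    def test_ramp(self):
        stim = sp.StimulusProtocol.ramp(0.0, 100.0, onset=0.0, offset=10.0)
        t = np.array([0.0, 5.0, 9.999])
        w = stim.waveform(t)
        assert w[0] == 0.0 and w[1] == pytest.approx(50.0)
        assert w[2] == pytest.approx(100.0, rel=1e-2)

    def test_invalid_ramp_rejected(self):
        with pytest.raises(ValueError):
            sp.StimulusProtocol.ramp(0.0, 10.0, onset=5.0, offset=5.0)
        with pytest.raises(ValueError):
            sp.StimulusProtocol(kind="noise")


class TestPnCorrection:
    def test_n_identical_subpulses_cancel(self):
        rng = np.random.default_rng(0)
        sub = rng.normal(size=100)
        test = 4 * sub
        out = sp.pn_correction(test, [sub] * 4)
        assert np.abs(out).max() < 1e-12

    def test_linearity(self):
        rng = np.random.default_rng(1)
        test = rng.normal(size=50)
        subs = [rng.normal(size=50) for _ in range(4)]
        one = sp.pn_correction(test, subs)
        scaled = sp.pn_correction(3.0 * test, [3.0 * s for s in subs])
        assert np.allclose(scaled, 3.0 * one)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            sp.pn_correction(np.zeros(10), [np.zeros(9)])

    def test_nulls_linear_membrane(self, passive_single_comp):
        clamp = sp.ClampProtocol(commands=[-50.0], onset=20.0, duration=10.0)
        cr = sp.run_voltage_clamp(passive_single_comp, clamp, dt=5e-3)
        assert np.abs(cr.corrected[0]).max() < 1.0  # < 1 pA residual

    def test_isolates_nonlinear_component(self, twocomp_params):
        """P/n-corrected trace approximates the raw trace minus the response
        of the Na-deleted membrane held at the same potential.  The two
        routes differ only through the Na current's secondary effect on the
        unclamped axonal trajectory."""
        g = sp.two_compartment_graph(twocomp_params)
        hold = float(sp.resting_state(g).v[0])
        clamp = sp.ClampProtocol(commands=[-58.0], onset=20.0, duration=8.0,
                                 holding=hold)
        cr = sp.run_voltage_clamp(twocomp_params, clamp, dt=5e-3)
        # oracle: same command on the model with Na removed entirely
        p_lin = dataclasses.replace(twocomp_params, g_na_soma=0.0,
                                    g_na_axon=0.0)
        clamp_lin = dataclasses.replace(clamp, leak_subtraction=None)
        cr_lin = sp.run_voltage_clamp(p_lin, clamp_lin, dt=5e-3)
        lin_bs = cr_lin.raw[0] - cr_lin.baseline[0]
        direct = (cr.raw[0] - cr.baseline[0]) - lin_bs
        win = (cr.t >= clamp.onset + 0.3) & (cr.t <= clamp.onset + 7.7)
        scale = np.abs(cr.corrected[0][win]).max()
        assert np.abs(cr.corrected[0][win] - direct[win]).max() < 0.10 * scale


class TestVoltageClamp:
    def test_passive_rc_response_matches_circuit_algebra(
            self, passive_single_comp):
        clamp = sp.ClampProtocol(commands=[-50.0], holding=-70.0, r_s=1.0,
                                 onset=20.0, duration=20.0,
                                 leak_subtraction=None)
        cr = sp.run_voltage_clamp(passive_single_comp, clamp, dt=1e-3,
                                  record_stride=10)
        ana = sp.make_passive_rc_clamp(
            capacitance=100.0, g_leak=10.0, r_s=1.0, e_leak=-70.0,
            holding=-70.0, command=-50.0, onset=20.0, duration=20.0, dt=0.01)
        n = min(len(ana.y), cr.raw.shape[1])
        sel = (cr.t[:n] >= 20.2) & (cr.t[:n] <= 39.8)
        assert np.abs(cr.raw[0][:n][sel] - ana.y[:n][sel]).max() < \
            0.01 * np.abs(ana.y).max()

    def test_clamp_fidelity_at_low_series_resistance(self, twocomp_params):
        clamp = sp.ClampProtocol(commands=[-60.0], r_s=0.001, onset=20.0,
                                 duration=10.0, leak_subtraction=None)
        cr = sp.run_voltage_clamp(twocomp_params, clamp, dt=2e-3)
        win = (cr.t >= 20.5) & (cr.t <= 29.5)
        assert np.abs(cr.v_soma[0][win] - (-60.0)).max() < 0.1

    def test_latency_decreases_with_depolarization(self, cable_iv):
        lat = cable_iv.metadata["latencies"]
        supra = cable_iv.peak_currents < -1.0  # discontinuous branch
        assert np.all(np.diff(lat[supra]) < 1e-9)

    def test_open_fraction_steps_with_iv_discontinuity(self, cable_iv):
        frac = cable_iv.metadata["open_fractions"]
        v0 = cable_iv.discontinuity_voltage
        below = cable_iv.voltages < v0
        assert frac[below].max() < 0.01
        assert frac[~below].min() > 0.5

    def test_prepulse_at_holding_is_a_no_op(self, twocomp_params):
        base = sp.ClampProtocol(commands=[-55.0], onset=20.0, duration=8.0)
        g = sp.two_compartment_graph(twocomp_params)
        rest = float(sp.resting_state(g).v[0])
        noop = dataclasses.replace(base, prepulse=(rest, 5.0), holding=rest)
        ref = dataclasses.replace(base, holding=rest)
        cr1 = sp.run_voltage_clamp(twocomp_params, ref, dt=5e-3)
        cr2 = sp.run_prepulse_inactivation(twocomp_params, noop, dt=5e-3)
        assert np.abs(cr1.raw - cr2.raw).max() < 1e-6

    def test_inactivating_prepulse_removes_discontinuity(self, twocomp_params,
                                                         twocomp_iv):
        clamp = sp.ClampProtocol(commands=list(twocomp_iv.voltages),
                                 prepulse=(-20.0, 10.0), onset=20.0,
                                 duration=10.0)
        cr = sp.run_prepulse_inactivation(twocomp_params, clamp, dt=5e-3)
        iv = sp.IVCurve.from_clamp(cr)
        assert sp.find_discontinuity(iv) is None
        assert twocomp_iv.discontinuity_voltage is not None  # vs. control

    def test_prepulse_required(self, twocomp_params):
        clamp = sp.ClampProtocol(commands=[-55.0])
        with pytest.raises(ValueError):
            sp.run_prepulse_inactivation(twocomp_params, clamp)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            sp.ClampProtocol(commands=[-50.0], r_s=0.0)
        with pytest.raises(ValueError):
            sp.ClampProtocol(commands=[-50.0], n_subpulses=1)
        with pytest.raises(ValueError):
            sp.ClampProtocol(commands=[-50.0], onset=5.0)


class TestThresholdDetection:
    def test_exponential_upstroke_analytic_threshold(self):
        # dV/dt = (V - V0)/tau crosses c at V = V0 + c*tau
        tau, v0 = 0.2, -70.0
        tr = sp.make_exponential_upstroke(v0=v0, tau=tau, dt=0.002,
                                          amplitude=0.5)
        thr = sp.detect_threshold(tr.t, tr.y, criterion=5.0)
        assert thr == pytest.approx(v0 + 5.0 * tau, abs=0.02)

    def test_subthreshold_trace_returns_none(self):
        t = np.linspace(0, 10, 1001)
        v = -70.0 + 0.5 * np.sin(t)
        assert sp.detect_threshold(t, v) is None

    def test_invariant_to_time_step(self, default_graph, cable_rheobase):
        stim = sp.StimulusProtocol.step(1.5 * cable_rheobase, onset=1.0)
        thr = {}
        for dt in (1e-3, 2e-3):
            res = sp.run_simulation(default_graph, stim, duration=20.0, dt=dt,
                                    record_stride=1)
            thr[dt] = sp.detect_threshold(res.t, res.v_soma)
        assert abs(thr[1e-3] - thr[2e-3]) < 0.5

    def test_current_and_voltage_clamp_thresholds_agree(self, cable_threshold,
                                                        cable_iv):
        assert abs(cable_iv.discontinuity_voltage - cable_threshold) < 5.0


class TestRheobase:
    def test_bracketing(self, default_graph, cable_rheobase):
        stim_lo = sp.StimulusProtocol.step(cable_rheobase - 3.0, onset=1.0)
        stim_hi = sp.StimulusProtocol.step(cable_rheobase + 1.0, onset=1.0)
        lo = sp.run_simulation(default_graph, stim_lo, duration=30.0, dt=2e-3,
                               record_stride=20)
        hi = sp.run_simulation(default_graph, stim_hi, duration=30.0, dt=2e-3,
                               record_stride=20)
        assert lo.v.max() < -20.0 < hi.v.max()
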