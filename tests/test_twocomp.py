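"""The two-compartment soma-AIS model: resting state, spike shape, Na-influx
partition and the resistive-coupling discontinuity."""

import dataclasses

import numpy as np
import pytest

import spikeinit as sp
from spikeinit.channels import boltzmann_inf


class TestRestingState:
    def test_rest_near_leak_reversal_with_gates_closed(self, twocomp_params):
        g = sp.two_compartment_graph(twocomp_params)
        rest = sp.resting_state(g)
        # the subthreshold Na current depolarizes rest ~1.5 mV above E_L
        assert np.all(np.abs(rest.v - (-80.0)) < 2.5)
        assert np.all(rest.m < 1e-3)   # Na activation nearly closed
        assert np.all(rest.n < 1e-4)   # K closed

    def test_against_damped_fixed_point_oracle(self, twocomp_params):
        """Independent algebraic oracle: damped iteration of the two current
        balances with gates at their Boltzmann steady states."""
        p = twocomp_params
        g_ra = 1e3 / p.r_a  # nS
        vs = va = -80.0
        for _ in range(5000):
            def total(v, gna, gk, gl):
                m = boltzmann_inf(v, p.na_activation)
                h = boltzmann_inf(v, p.na_inactivation)
                n = boltzmann_inf(v, p.k_activation)
                gna_eff = gna * m * h
                gk_eff = gk * n
                num = gna_eff * p.e_na + gk_eff * p.e_k + gl * p.e_leak
                return num, gna_eff + gk_eff + gl
            ns_, ds_ = total(vs, p.g_na_soma, p.g_k_soma, p.g_leak_soma)
            na_, da_ = total(va, p.g_na_axon, p.g_k_axon, p.g_leak_axon_ns)
            vs_new = (ns_ + g_ra * va) / (ds_ + g_ra)
            va_new = (na_ + g_ra * vs) / (da_ + g_ra)
            vs += 0.1 * (vs_new - vs)
            va += 0.1 * (va_new - va)
        rest = sp.resting_state(sp.two_compartment_graph(p))
        assert rest.v[0] == pytest.approx(vs, abs=1e-3)
        assert rest.v[1] == pytest.approx(va, abs=1e-3)

    def test_membrane_time_constant(self, twocomp_params):
        assert twocomp_params.membrane_time_constant == pytest.approx(
            250.0 / 12.0)  # ~20.8 ms

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sp.TwoCompartmentParams(c_s=-1.0)
        with pytest.raises(ValueError):
            sp.TwoCompartmentParams(g_na_axon=-5.0)

    def test_yaml_roundtrip(self, tmp_path, twocomp_params):
        p = dataclasses.replace(twocomp_params, r_a=9.0)
        path = tmp_path / "twocomp.yaml"
        p.to_yaml(str(path))
        assert sp.TwoCompartmentParams.from_yaml(str(path)) == p


class TestSpikeShape:
    def test_somatic_phase_plot_biphasic(self, twocomp_spike):
        win = sp.spike_window(twocomp_spike.t, twocomp_spike.v_soma)
        pp = sp.phase_plot(twocomp_spike.t, twocomp_spike.v_soma, window=win)
        _, info = sp.onset_rapidness(pp, return_details=True)
        assert info["n_components"] >= 2

    def test_ais_phase_plot_monophasic(self, twocomp_spike):
        va = twocomp_spike.v[:, 1]
        pp = sp.phase_plot(twocomp_spike.t, va,
                           window=sp.spike_window(twocomp_spike.t, va))
        _, info = sp.onset_rapidness(pp, return_details=True)
        assert info["n_components"] == 1

    def test_onset_rapidness_scale(self, twocomp_spike, hh_phase_plot):
        win = sp.spike_window(twocomp_spike.t, twocomp_spike.v_soma)
        pp = sp.phase_plot(twocomp_spike.t, twocomp_spike.v_soma, window=win)
        rapid = sp.onset_rapidness(pp)
        assert rapid == pytest.approx(17.0, rel=0.30)
        # far sharper than the isopotential reference membrane
        assert rapid > 3.0 * sp.onset_rapidness(hh_phase_plot)

    def test_rapidness_insensitive_to_stimulus_form(self, twocomp_params,
                                                    twocomp_rheobase,
                                                    twocomp_spike):
        win = sp.spike_window(twocomp_spike.t, twocomp_spike.v_soma)
        pp = sp.phase_plot(twocomp_spike.t, twocomp_spike.v_soma, window=win)
        r_step = sp.onset_rapidness(pp)
        ramp = sp.StimulusProtocol.ramp(0.0, 2.0 * twocomp_rheobase,
                                        onset=1.0, offset=101.0)
        res = sp.simulate_two_compartment(twocomp_params, ramp, duration=110.0,
                                          dt=2e-3, record_stride=1)
        ppr = sp.phase_plot(res.t, res.v_soma,
                            window=sp.spike_window(res.t, res.v_soma))
        assert sp.onset_rapidness(ppr) == pytest.approx(r_step, rel=0.10)

    def test_no_axonal_na_means_graded_response(self, twocomp_params,
                                                twocomp_rheobase):
        p0 = dataclasses.replace(twocomp_params, g_na_axon=0.0)
        peaks = []
        for factor in (2.0, 4.0):
            res = sp.simulate_two_compartment(
                p0, sp.StimulusProtocol.step(factor * twocomp_rheobase, onset=1.0),
                duration=30.0, dt=2e-3, record_stride=10)
            peaks.append(res.v[:, 1].max())
        # no all-or-none axonal event: the AIS never approaches E_Na
        assert all(v < -15.0 for v in peaks)

    def test_dt_must_resolve_activation(self, twocomp_params):
        with pytest.raises(ValueError):
            sp.simulate_two_compartment(twocomp_params, None, duration=1.0,
                                        dt=0.05)


class TestNaInflux:
    def test_zero_conductance_zero_charge(self, twocomp_params):
        p0 = dataclasses.replace(twocomp_params, g_na_soma=0.0, g_na_axon=0.0)
        res = sp.simulate_two_compartment(
            p0, sp.StimulusProtocol.step(300.0, onset=1.0), duration=10.0,
            dt=5e-3, record_stride=10)
        with pytest.warns(UserWarning):
            q = sp.na_influx_charge(res, "soma")
        assert q == 0.0

    def test_ais_excess_about_half(self, twocomp_spike):
        win = sp.spike_window(twocomp_spike.t, twocomp_spike.v_soma)
        q_a = sp.na_influx_charge(twocomp_spike, ("axon", 0), window=win)
        q_s = sp.na_influx_charge(twocomp_spike, "soma", window=win)
        assert q_a > q_s
        excess = 100.0 * (q_a / q_s - 1.0)
        assert 35.0 <= excess <= 65.0

    def test_influx_ratio_robust_to_conductance_scaling(self, twocomp_params,
                                                        twocomp_spike):
        win = sp.spike_window(twocomp_spike.t, twocomp_spike.v_soma)
        ratio0 = (sp.na_influx_charge(twocomp_spike, ("axon", 0), window=win)
                  / sp.na_influx_charge(twocomp_spike, "soma", window=win))
        p2 = dataclasses.replace(twocomp_params, g_na_soma=400.0,
                                 g_na_axon=600.0)
        rheo = sp.find_rheobase(p2, dt=5e-3)
        res = sp.simulate_two_compartment(
            p2, sp.StimulusProtocol.step(1.5 * rheo, onset=1.0),
            duration=30.0, dt=2e-3, record_stride=2)
        win2 = sp.spike_window(res.t, res.v_soma)
        q_a = sp.na_influx_charge(res, ("axon", 0), window=win2)
        q_s = sp.na_influx_charge(res, "soma", window=win2)
        assert q_a / q_s == pytest.approx(ratio0, rel=0.20)

    def test_window_outside_trace_rejected(self, twocomp_spike):
        with pytest.raises(ValueError):
            sp.na_influx_charge(twocomp_spike, "soma", window=(1e4, 2e4))


class TestVoltageClampDiscontinuity:
    def test_peak_current_jumps_at_threshold(self, twocomp_iv):
        assert twocomp_iv.discontinuity_voltage is not None
        assert twocomp_iv.jump_na > 1.0

    def test_weak_coupling_abolishes_discontinuity(self, twocomp_params,
                                                   twocomp_iv):
        p_lo = dataclasses.replace(twocomp_params, r_a=0.045)
        v0 = twocomp_iv.discontinuity_voltage
        clamp = sp.ClampProtocol.scan(v0 - 5.0, v0 + 5.0, 0.5)
        cr = sp.run_voltage_clamp(p_lo, clamp, dt=5e-3)
        iv = sp.IVCurve.from_clamp(cr)
        assert sp.find_discontinuity(iv) is None
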