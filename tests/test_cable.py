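"""Cable discretization, bookkeeping and the implicit integrator."""

import dataclasses
import math

import numpy as np
import pytest

import spikeinit as sp
from spikeinit import units


class TestAxialResistance:
    def test_linear_in_resistivity(self):
        r1 = sp.axial_resistance(150.0, 1.0, 1.0, 1.0, 1.0)
        r2 = sp.axial_resistance(300.0, 1.0, 1.0, 1.0, 1.0)
        assert r2 == pytest.approx(2.0 * r1)

    def test_full_axon_end_to_end(self, default_graph):
        """Summing link resistances plus the distal half-segment recovers
        4 R_i L / (pi d^2) ~ 95.5 MOhm for the default axon."""
        a0, a1 = default_graph.sections["axon"]
        total = default_graph.r_axial[a0:a1].sum()
        # add the distal half-segment not covered by any link
        total += sp.axial_resistance(150.0, 1.0, 1.0, 0.0, 1.0)
        expected = 4.0 * 150.0 * 50.0 / (math.pi * 1.0**2) * 1e4 * 1e-9
        assert total == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.09549, rel=1e-3)  # GOhm

    def test_symmetric_halves_equal_one_segment(self):
        half2 = sp.axial_resistance(150.0, 1.0, 1.0, 1.0, 1.0)
        single = 4.0 * 150.0 * 1.0 / (math.pi * 1.0**2) * 1e4 * 1e-9
        assert half2 == pytest.approx(single)

    def test_zero_diameter_rejected(self):
        with pytest.raises(ValueError):
            sp.axial_resistance(150.0, 1.0, 0.0, 1.0, 1.0)


class TestBuildModel:
    def test_membrane_time_constant(self, default_config):
        assert default_config.membrane_time_constant == pytest.approx(22.5)

    def test_soma_capacitance(self, default_graph):
        # pi * 20 um * 30 um * 0.75 uF/cm^2 ~ 14.1 pF
        assert default_graph.cap[default_graph.soma_index] == pytest.approx(
            14.137, abs=0.01)

    @pytest.mark.parametrize("nseg", [10, 50])
    def test_total_axonal_na_invariant_under_discretization(self, nseg):
        g = sp.build_model(sp.ModelConfig(axon_segments=nseg))
        a0, a1 = g.sections["axon"]
        assert g.g_na[a0:a1].sum() == pytest.approx(
            8000.0 * math.pi * 1.0 * 50.0 * 1e-3, rel=1e-9)  # ~1256.6 nS

    def test_uniform_cable_regime(self):
        cfg = sp.ModelConfig(soma_length=1.0, soma_diameter=1.0)
        g = sp.build_model(cfg)
        assert g.cap[g.soma_index] == pytest.approx(
            units.capacitance_pf(math.pi, 0.75))

    def test_rejects_nonphysical_geometry(self):
        with pytest.raises(ValueError):
            sp.build_model(sp.ModelConfig(axon_diameter=0.0))
        with pytest.raises(ValueError):
            sp.build_model(sp.ModelConfig(axon_segments=0))

    def test_graph_is_a_path_with_positive_links(self, default_graph):
        links = default_graph.links
        assert len(links) == default_graph.n - 1
        assert all(r > 0 for _, _, r in links)

    def test_config_yaml_roundtrip(self, tmp_path, default_config):
        p = tmp_path / "model.yaml"
        cfg = dataclasses.replace(default_config, r_i=250.0,
                                  include_dendrite=True)
        cfg.to_yaml(str(p))
        back = sp.ModelConfig.from_yaml(str(p))
        assert back == cfg


@pytest.fixture(scope="module")
def graph10():
    return sp.build_model(sp.ModelConfig(axon_segments=10))


class TestClusterChannels:
    def test_conserves_total_conductance(self, graph10):
        out = sp.cluster_channels(graph10, 5)
        a0, a1 = out.sections["axon"]
        assert out.g_na[a0:a1].sum() == pytest.approx(
            graph10.g_na[a0:a1].sum())
        assert out.g_k[a0:a1].sum() == pytest.approx(graph10.g_k[a0:a1].sum())

    def test_density_multiplied_by_segment_count(self, graph10):
        out = sp.cluster_channels(graph10, 5)
        a0, _ = out.sections["axon"]
        tgt = a0 + 5
        density = units.total_to_density_ps_um2(out.g_na[tgt], out.area[tgt])
        assert density == pytest.approx(10 * 8000.0, rel=1e-9)
        assert out.g_na[a0] == 0.0

    def test_idempotent(self, graph10):
        once = sp.cluster_channels(graph10, 3)
        twice = sp.cluster_channels(once, 3)
        assert np.allclose(once.g_na, twice.g_na)

    def test_target_outside_axon_rejected(self, graph10):
        with pytest.raises(IndexError):
            sp.cluster_channels(graph10, 10)


class TestSimulation:
    def test_rest_is_a_fixed_point(self, default_graph):
        res = sp.run_simulation(default_graph, None, duration=20.0, dt=2e-3,
                                record_stride=100)
        rest = sp.resting_state(default_graph)
        assert np.abs(res.v - rest.v).max() < 0.01

    def test_gates_stay_in_unit_interval(self, cable_spike):
        for arr in (cable_spike.m, cable_spike.h, cable_spike.n):
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_spike_initiates_in_axon(self, cable_spike):
        site = sp.initiation_site(cable_spike)
        assert site.startswith("axon")
        # distal axon crosses 0 mV before the soma
        t = cable_spike.t
        t_ax = t[np.argmax(cable_spike.v_axon_end > 0)]
        t_so = t[np.argmax(cable_spike.v_soma > 0)]
        assert t_ax < t_so

    def test_low_resistivity_limit_is_isopotential(self):
        g = sp.build_model(sp.ModelConfig(r_i=1.0))
        rheo = sp.find_rheobase(g, dt=2e-3)
        res = sp.run_simulation(g, sp.StimulusProtocol.step(1.5 * rheo, onset=1.0),
                                duration=25.0, dt=2e-3, record_stride=5)
        gap = np.abs(res.v_soma - res.v_axon_end)
        assert res.v.max() > 0  # it still spikes
        assert gap.max() < 3.0  # essentially isopotential

    def test_isopotential_limit_matches_pooled_single_compartment(
            self, default_config):
        g = sp.build_model(dataclasses.replace(default_config, r_i=1e-3))
        pooled = sp.CompartmentGraph(
            cap=np.array([g.cap.sum()]), area=np.array([g.area.sum()]),
            g_na=np.array([g.g_na.sum()]), g_k=np.array([g.g_k.sum()]),
            g_leak=np.array([g.g_leak.sum()]), r_axial=np.array([np.inf]),
            e_na=g.e_na, e_k=g.e_k, e_leak=g.e_leak, soma_index=0,
            sections={"soma": (0, 1)}, x0=np.array([0.0]), x1=np.array([1.0]),
            radius=np.array([0.5]), kinetics=g.kinetics)
        stim = sp.StimulusProtocol.step(40.0, onset=1.0)
        rf = sp.run_simulation(g, stim, duration=25.0, dt=1e-3, record_stride=10)
        rp = sp.run_simulation(pooled, stim, duration=25.0, dt=1e-3,
                               record_stride=10)
        assert np.abs(rf.v_soma - rp.v[:, 0]).max() < 0.5

    def test_time_step_convergence(self, default_graph, cable_rheobase):
        stim = sp.StimulusProtocol.step(1.5 * cable_rheobase, onset=1.0)
        r1 = sp.run_simulation(default_graph, stim, duration=20.0, dt=1e-3,
                               record_stride=1)
        r2 = sp.run_simulation(default_graph, stim, duration=20.0, dt=2e-3,
                               record_stride=1)
        t_peak1 = r1.t[np.argmax(r1.v_soma)]
        t_peak2 = r2.t[np.argmax(r2.v_soma)]
        assert abs(t_peak1 - t_peak2) < 5e-3  # < 5 us
        d1 = np.gradient(r1.v_soma, r1.t).max()
        d2 = np.gradient(r2.v_soma, r2.t).max()
        assert abs(d1 - d2) / d1 < 0.01

    def test_discrete_scheme_charge_conservation(self, cable_spike):
        """The Crank-Nicolson update satisfies the summed current balance
        exactly: axial terms cancel pairwise, so C dV - dt * (average total
        membrane + injected current) sums to solver roundoff."""
        r = cable_spike
        g = r.graph
        pm, ph, pn = g.kinetics.exponents
        gna = g.g_na * r.m[1:] ** pm * r.h[1:] ** ph
        gk = g.g_k * r.n[1:] ** pn
        # theta = 0.5: conductances frozen at the post-update gate state
        def f(v):
            return (gna * (g.e_na - v) + gk * (g.e_k - v)
                    + g.g_leak * (g.e_leak - v))
        inj = r.injected_matrix()
        fl = f(r.v[:-1]) + inj[:-1]
        fr_ = f(r.v[1:]) + inj[1:]
        resid = (g.cap * (r.v[1:] - r.v[:-1]) / r.dt
                 - 0.5 * (fl + fr_)).sum(axis=1)
        peak_na = np.abs(r.i_na().sum(axis=1)).max()
        assert np.abs(resid).max() < 1e-6 * peak_na

    def test_solver_divergence_reports_state(self, default_graph):
        bad = sp.cable.RestingState(
            v=np.full(default_graph.n, np.nan),
            m=np.zeros(default_graph.n), h=np.ones(default_graph.n),
            n=np.zeros(default_graph.n))
        with pytest.raises(sp.SolverDivergence) as exc:
            sp.run_simulation(default_graph, None, duration=1.0, dt=2e-3,
                              initial=bad)
        assert "step" in exc.value.state


class TestJunctionCurrent:
    def test_definition(self, cable_spike):
        g = cable_spike.graph
        jl = g.junction_link
        expected = (cable_spike.v[:, jl] - cable_spike.v[:, jl - 1]) \
            / g.r_axial[jl]
        assert np.allclose(sp.junction_axial_current(cable_spike), expected)

    def test_zero_at_uniform_voltage(self, default_graph):
        rest = sp.resting_state(default_graph)
        flat = sp.cable.RestingState(
            v=np.full(default_graph.n, -70.0), m=rest.m, h=rest.h, n=rest.n)
        res = sp.run_simulation(default_graph, None, duration=0.01, dt=1e-3,
                                record_stride=1, initial=flat)
        assert abs(sp.junction_axial_current(res)[0]) < 1e-12

    def test_axon_to_soma_at_initiation(self, cable_spike):
        j = sp.junction_axial_current(cable_spike)
        ipk = np.argmax(cable_spike.v_axon_end)
        assert j[ipk] > 0  # positive = flowing from axon toward soma

    def test_model_without_axon_rejected(self, hh_graph):
        res = sp.run_simulation(hh_graph, None, duration=0.01, dt=1e-3,
                                record_stride=1)
        with pytest.raises(ValueError):
            sp.junction_axial_current(res)


class TestTwoNodeEquivalence:
    def test_cable_stepper_reproduces_two_compartment_integrator(
            self, twocomp_params):
        stim = sp.StimulusProtocol.step(350.0, onset=1.0)
        ra = sp.simulate_two_compartment(twocomp_params, stim, duration=25.0,
                                         dt=1e-3, record_stride=10)
        rb = sp.run_simulation(sp.two_compartment_graph(twocomp_params), stim,
                               duration=25.0, dt=1e-3, record_stride=10)
        assert np.abs(ra.v - rb.v).max() < 0.1


class TestExports:
    def test_columnar_table(self, tmp_path, cable_spike):
        path = tmp_path / "traces.tsv"
        df = cable_spike.to_table(str(path), compartments=["soma", "axon_end"])
        assert path.exists()
        assert list(df.columns) == ["time_ms", "v_soma_mv", "v_axon[49]_mv"]

    def test_hdf5_dump(self, tmp_path, cable_spike):
        import h5py

        path = tmp_path / "dump.h5"
        cable_spike.to_hdf5(str(path))
        with h5py.File(path) as fh:
            assert fh["state/v"].shape == cable_spike.v.shape
            assert fh.attrs["dt_ms"] == cable_spike.dt
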