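"""Shared fixtures: models and reference simulations reused across the suite.

Expensive simulations are session-scoped; they are deterministic, so sharing
them does not couple tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import spikeinit as sp

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# simple cable model
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_config() -> sp.ModelConfig:
    return sp.ModelConfig()


@pytest.fixture(scope="session")
def default_graph(default_config) -> sp.CompartmentGraph:
    return sp.build_model(default_config)


@pytest.fixture(scope="session")
def cable_rheobase(default_graph) -> float:
    return sp.find_rheobase(default_graph, dt=2e-3)


@pytest.fixture(scope="session")
def cable_spike(default_graph, cable_rheobase) -> sp.SimResult:
    """One spike of the default simple model at 1 us resolution."""
    stim = sp.StimulusProtocol.step(1.5 * cable_rheobase, onset=1.0)
    return sp.run_simulation(default_graph, stim, duration=30.0, dt=1e-3,
                             record_stride=1)


@pytest.fixture(scope="session")
def cable_threshold(cable_spike) -> float:
    return sp.detect_threshold(cable_spike.t, cable_spike.v_soma)


@pytest.fixture(scope="session")
def cable_iv(default_graph, cable_threshold) -> sp.IVCurve:
    clamp = sp.ClampProtocol.scan(cable_threshold - 4.0, cable_threshold + 4.0,
                                  0.5)
    cr = sp.run_voltage_clamp(default_graph, clamp, dt=2e-3)
    iv = sp.IVCurve.from_clamp(cr).annotate_discontinuity()
    iv_latencies = cr.peak_latencies()
    iv_open = cr.peak_open_fractions()
    # stash protocol-level curves for tests that need them
    iv.metadata = {"latencies": iv_latencies, "open_fractions": iv_open}  # type: ignore[attr-defined]
    return iv


# ---------------------------------------------------------------------------
# two-compartment model
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def twocomp_params() -> sp.TwoCompartmentParams:
    return sp.TwoCompartmentParams()


@pytest.fixture(scope="session")
def twocomp_rheobase(twocomp_params) -> float:
    return sp.find_rheobase(twocomp_params, dt=5e-3)


@pytest.fixture(scope="session")
def twocomp_spike(twocomp_params, twocomp_rheobase) -> sp.SimResult:
    stim = sp.StimulusProtocol.step(1.5 * twocomp_rheobase, onset=1.0)
    return sp.simulate_two_compartment(twocomp_params, stim, duration=30.0,
                                       dt=1e-3, record_stride=1)


@pytest.fixture(scope="session")
def twocomp_iv(twocomp_params) -> sp.IVCurve:
    clamp = sp.ClampProtocol.scan(-62.0, -50.0, 0.5)
    cr = sp.run_voltage_clamp(twocomp_params, clamp, dt=5e-3)
    return sp.IVCurve.from_clamp(cr).annotate_discontinuity()


# ---------------------------------------------------------------------------
# isopotential Hodgkin-Huxley reference
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def hh_graph() -> sp.CompartmentGraph:
    return sp.hh_squid_graph()


@pytest.fixture(scope="session")
def hh_rheobase(hh_graph) -> float:
    return sp.find_rheobase(hh_graph, dt=5e-3)


@pytest.fixture(scope="session")
def hh_spike(hh_graph, hh_rheobase) -> sp.SimResult:
    stim = sp.StimulusProtocol.step(1.5 * hh_rheobase, onset=1.0)
    return sp.run_simulation(hh_graph, stim, duration=20.0, dt=1e-3,
                             record_stride=1)


@pytest.fixture(scope="session")
def hh_phase_plot(hh_spike):
    win = sp.spike_window(hh_spike.t, hh_spike.v_soma)
    return sp.phase_plot(hh_spike.t, hh_spike.v_soma, window=win)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def passive_single_comp() -> sp.CompartmentGraph:
    """Isopotential passive membrane (no Na/K) for clamp-linearity tests."""
    return sp.CompartmentGraph(
        cap=np.array([100.0]), area=np.array([1000.0]),
        g_na=np.array([0.0]), g_k=np.array([0.0]), g_leak=np.array([10.0]),
        r_axial=np.array([np.inf]),
        e_na=60.0, e_k=-90.0, e_leak=-70.0,
        soma_index=0, sections={"soma": (0, 1)},
        x0=np.array([0.0]), x1=np.array([10.0]), radius=np.array([5.0]),
        kinetics=sp.Kinetics.from_gate_specs(),
    )


def scaled_config(base: sp.ModelConfig, **kw) -> sp.ModelConfig:
    return dataclasses.replace(base, **kw)
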