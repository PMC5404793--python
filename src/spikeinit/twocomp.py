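"""Minimal two-compartment model of the soma-AIS system.

Two isopotential compartments -- a large somatodendritic compartment and a
small axon-initial-segment compartment -- coupled by a single axial
resistance R_a.  Channels are deliberately simple: single-gate Boltzmann
activation/inactivation with voltage-independent time constants, so that any
sharpness of spike onset comes from the resistive coupling and not from
channel kinetics.

The integrator here is an independent, algebraically explicit two-unknown
Crank-Nicolson core (closed-form 2x2 solve, closed-form Boltzmann gate
relaxation); the general cable integrator applied to the equivalent two-node
graph serves as a cross-check in the test suite, not as the implementation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import units
from ._integrator import two_compartment_loop
from .cable import CompartmentGraph, RestingState, SimResult, resting_state
from .channels import (
    GateSpec,
    Kinetics,
    K_ACTIVATION,
    NA_ACTIVATION,
    NA_INACTIVATION,
)

__all__ = [
    "TwoCompartmentParams",
    "two_compartment_graph",
    "simulate_two_compartment",
    "na_influx_charge",
]

#: Nominal membrane areas used only for density bookkeeping (um^2).
SOMA_AREA_UM2 = 2000.0
AIS_AREA_UM2 = 50.0


@dataclass
class TwoCompartmentParams:
    """Parameters of the two-compartment soma-AIS model.

    Capacitances in pF, conductances in nS, coupling resistance in MOhm,
    potentials in mV.  The printed leak conductance (12 nS, giving the soma
    its ~20 ms passive time constant) is applied to each compartment by
    default: scaling the axonal leak down by the capacitance ratio
    (0.24 nS) leaves the subthreshold Na current unopposed and the model
    then has no resting fixed point at all.  Reversal potentials default to
    standard cortical values.
    """

    c_s: float = 250.0
    c_a: float = 5.0
    r_a: float = 4.5                    # MOhm
    g_leak_soma: float = 12.0
    g_leak_axon: float | None = None    # None -> same as the soma
    e_leak: float = -80.0
    g_na_soma: float = 800.0
    g_na_axon: float = 1200.0
    g_k_soma: float = 2200.0
    g_k_axon: float = 1200.0
    e_na: float = 60.0
    e_k: float = -90.0
    na_activation: GateSpec = field(default_factory=lambda: NA_ACTIVATION)
    na_inactivation: GateSpec = field(default_factory=lambda: NA_INACTIVATION)
    k_activation: GateSpec = field(default_factory=lambda: K_ACTIVATION)

    def __post_init__(self) -> None:
        if min(self.c_s, self.c_a, self.r_a, self.g_leak_soma) <= 0:
            raise ValueError("capacitances, coupling resistance and somatic "
                             "leak must be positive")
        for name in ("g_na_soma", "g_na_axon", "g_k_soma", "g_k_axon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def g_leak_axon_ns(self) -> float:
        if self.g_leak_axon is not None:
            return self.g_leak_axon
        return self.g_leak_soma

    @property
    def membrane_time_constant(self) -> float:
        """Somatic passive time constant C_s / g_leak, ms."""
        return self.c_s / self.g_leak_soma

    def kinetics(self) -> Kinetics:
        return Kinetics.from_gate_specs(
            self.na_activation, self.na_inactivation, self.k_activation
        )

    def to_yaml(self, path: str) -> None:
        d = {k: getattr(self, k) for k in (
            "c_s", "c_a", "r_a", "g_leak_soma", "g_leak_axon", "e_leak",
            "g_na_soma", "g_na_axon", "g_k_soma", "g_k_axon", "e_na", "e_k")}
        for label, g in (("na_activation", self.na_activation),
                         ("na_inactivation", self.na_inactivation),
                         ("k_activation", self.k_activation)):
            d[label] = {
                "v_half_mv": g.half_activation_voltage,
                "slope_mv": g.slope_factor,
                "tau_ms": g.time_constant,
                "exponent": g.exponent,
            }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "TwoCompartmentParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        kw = {}
        for k in ("c_s", "c_a", "r_a", "g_leak_soma", "g_leak_axon", "e_leak",
                  "g_na_soma", "g_na_axon", "g_k_soma", "g_k_axon",
                  "e_na", "e_k"):
            if k in d:
                kw[k] = d[k]
        for label in ("na_activation", "na_inactivation", "k_activation"):
            if label in d:
                gd = d[label]
                kw[label] = GateSpec(gd["v_half_mv"], gd["slope_mv"],
                                     gd["tau_ms"], gd.get("exponent", 1))
        return cls(**kw)


def two_compartment_graph(params: TwoCompartmentParams) -> CompartmentGraph:
    """Equivalent two-node :class:`~spikeinit.cable.CompartmentGraph`
    (index 0 = soma, 1 = AIS), used by the clamp protocols and as the
    cross-check route for the dedicated integrator."""
    return CompartmentGraph(
        cap=np.array([params.c_s, params.c_a]),
        area=np.array([SOMA_AREA_UM2, AIS_AREA_UM2]),
        g_na=np.array([params.g_na_soma, params.g_na_axon]),
        g_k=np.array([params.g_k_soma, params.g_k_axon]),
        g_leak=np.array([params.g_leak_soma, params.g_leak_axon_ns]),
        r_axial=np.array([math.inf, units.mohm_to_gohm(params.r_a)]),
        e_na=params.e_na, e_k=params.e_k, e_leak=params.e_leak,
        soma_index=0,
        sections={"soma": (0, 1), "axon": (1, 2)},
        x0=np.array([-30.0, 0.0]), x1=np.array([0.0, 5.0]),
        radius=np.array([10.0, 0.5]),
        kinetics=params.kinetics(),
    )


def simulate_two_compartment(
    params: TwoCompartmentParams,
    stimulus=None,
    duration: float = 50.0,
    dt: float = 1e-3,
    record_stride: int = 10,
    theta: float = 0.5,
    initial: RestingState | None = None,
) -> SimResult:
    """Integrate the two-compartment model; same trace contract as the cable
    simulator (the single axial link is R_a).

    ``dt`` must resolve the fastest gate (activation tau = 100 us), so
    dt <= 0.01 ms is required.
    """
    if dt <= 0 or dt > 0.010001:
        raise ValueError("dt must be positive and at most 10 us")
    nsteps = int(round(duration / dt))
    tgrid = np.arange(nsteps + 1) * dt
    graph = two_compartment_graph(params)

    if stimulus is not None:
        i_stim = np.asarray(stimulus.waveform(tgrid), dtype=float)
        comp = getattr(stimulus, "compartment", "soma")
        stim_idx = graph.compartment_index(comp)
    else:
        i_stim = np.zeros(nsteps + 1)
        stim_idx = 0

    state = initial or resting_state(graph)
    nrec = nsteps // record_stride + 1
    rec = np.empty((nrec, 8))

    ga = params.na_activation
    gi = params.na_inactivation
    gk = params.k_activation
    bad = two_compartment_loop(
        float(state.v[0]), float(state.v[1]),
        float(state.m[0]), float(state.h[0]), float(state.n[0]),
        float(state.m[1]), float(state.h[1]), float(state.n[1]),
        params.c_s, params.c_a, 1.0 / units.mohm_to_gohm(params.r_a),
        params.g_leak_soma, params.g_leak_axon_ns, params.e_leak,
        params.g_na_soma, params.g_na_axon, params.e_na,
        params.g_k_soma, params.g_k_axon, params.e_k,
        ga.half_activation_voltage, ga.slope_factor, ga.time_constant,
        gi.half_activation_voltage, gi.slope_factor, gi.time_constant,
        gk.half_activation_voltage, gk.slope_factor, gk.time_constant,
        i_stim, 1 if stim_idx == 0 else 0,
        dt, nsteps, record_stride, theta,
        rec,
    )
    if bad >= 0:
        from .cable import SolverDivergence

        raise SolverDivergence(
            f"non-finite voltage at step {bad} (t = {bad * dt:.4f} ms)",
            state={"step": bad, "t_ms": bad * dt, "record": rec},
        )

    t_rec = tgrid[: (nrec - 1) * record_stride + 1 : record_stride]
    return SimResult(
        t=t_rec,
        v=rec[:, 0:2].copy(),
        m=rec[:, [2, 5]].copy(),
        h=rec[:, [3, 6]].copy(),
        n=rec[:, [4, 7]].copy(),
        graph=graph, dt=dt, record_stride=record_stride,
        stim_index=stim_idx if stimulus is not None else None,
        i_inj=i_stim[::record_stride][:nrec] if stimulus is not None else None,
        metadata={"theta": theta, "duration_ms": duration,
                  "integrator": "two_compartment"},
    )


def na_influx_charge(result: SimResult, compartment, window=None) -> float:
    """Time integral of the Na current magnitude over ``window`` (ms
    interval), in pC.

    ``window`` defaults to the whole trace; it should cover one spike.  A
    warning is issued when no spike (dV/dt >= 10 mV/ms anywhere) occurs in
    the window.
    """
    idx = result.graph.compartment_index(compartment)
    t = result.t
    if window is None:
        sel = slice(None)
    else:
        t0, t1 = window
        sel = (t >= t0) & (t <= t1)
        if not np.any(sel):
            raise ValueError("window outside the recorded trace")
    i_na = np.abs(result.i_na()[sel, idx])
    tw = t[sel]
    dvdt = np.gradient(result.v[sel], tw, axis=0)
    if np.max(np.abs(dvdt)) < 10.0:
        warnings.warn("no spike detected in the integration window; "
                      "returning near-baseline Na charge")
    # pA * ms = fC; convert to pC
    return float(np.trapezoid(i_na, tw) * 1e-3)
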