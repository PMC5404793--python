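"""In-silico experimental protocols.

Current-clamp stimuli (steps, ramps), somatic voltage clamp through a series
resistance with P/n leak subtraction and optional inactivating prepulse,
spike-threshold detection at a dV/dt criterion, and rheobase search.

Protocols accept either a :class:`~spikeinit.cable.CompartmentGraph` or
:class:`~spikeinit.twocomp.TwoCompartmentParams`; the latter runs on the
equivalent two-node graph for clamp protocols and on the dedicated
two-compartment integrator for current clamp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cable import (
    ClampDrive,
    CompartmentGraph,
    RestingState,
    SimResult,
    resting_state,
    run_simulation,
)
from .twocomp import TwoCompartmentParams, simulate_two_compartment, two_compartment_graph

__all__ = [
    "StimulusProtocol",
    "ClampProtocol",
    "ClampResult",
    "run_voltage_clamp",
    "run_prepulse_inactivation",
    "pn_correction",
    "detect_threshold",
    "find_rheobase",
]


# ---------------------------------------------------------------------------
# Current-clamp stimuli
# ---------------------------------------------------------------------------


@dataclass
class StimulusProtocol:
    """A current-clamp stimulus: 'step', 'ramp' or 'zero'.

    Amplitudes in pA, times in ms.  For a ramp the current rises linearly
    from ``amp_start`` to ``amp_end`` between onset and offset.
    """

    kind: str = "step"
    amplitude: float = 0.0
    onset: float = 1.0
    offset: float = math.inf
    amp_start: float = 0.0
    amp_end: float = 0.0
    compartment: object = "soma"

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp", "zero"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "ramp" and not self.offset > self.onset:
            raise ValueError("ramp duration must be positive")

    @classmethod
    def step(cls, amplitude: float, onset: float = 1.0,
             offset: float = math.inf, compartment="soma") -> "StimulusProtocol":
        return cls("step", amplitude=amplitude, onset=onset, offset=offset,
                   compartment=compartment)

    @classmethod
    def ramp(cls, amp_start: float, amp_end: float, onset: float,
             offset: float, compartment="soma") -> "StimulusProtocol":
        return cls("ramp", onset=onset, offset=offset, amp_start=amp_start,
                   amp_end=amp_end, compartment=compartment)

    def waveform(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if self.kind == "zero":
            return out
        active = (t >= self.onset) & (t < self.offset)
        if self.kind == "step":
            out[active] = self.amplitude
        else:
            frac = (t[active] - self.onset) / (self.offset - self.onset)
            out[active] = self.amp_start + frac * (self.amp_end - self.amp_start)
        return out


def _simulate(model, stimulus, duration, dt, record_stride=10, theta=0.5,
              initial=None) -> SimResult:
    if isinstance(model, TwoCompartmentParams):
        return simulate_two_compartment(
            model, stimulus, duration=duration, dt=dt,
            record_stride=record_stride, theta=theta, initial=initial)
    return run_simulation(model, stimulus, duration=duration, dt=dt,
                          record_stride=record_stride, theta=theta,
                          initial=initial)


def _as_graph(model) -> CompartmentGraph:
    if isinstance(model, TwoCompartmentParams):
        return two_compartment_graph(model)
    return model


# ---------------------------------------------------------------------------
# Voltage clamp
# ---------------------------------------------------------------------------


@dataclass
class ClampProtocol:
    """Somatic voltage clamp through a series (access) resistance.

    ``commands`` are the command potentials (mV) scanned; ``holding``
    defaults to the model's resting potential.  With ``leak_subtraction =
    'pn'``, ``n_subpulses`` hyperpolarizing subpulses of amplitude
    -(command - holding)/n are delivered from holding and their summed
    baseline-subtracted response is used to cancel the linear component of
    the test response.  ``prepulse = (voltage_mv, duration_ms)`` inserts a
    conditioning step immediately before each command (used to inactivate
    axonal Na channels).
    """

    commands: Sequence[float] = field(default_factory=list)
    holding: float | None = None
    onset: float = 20.0
    duration: float = 10.0
    post: float = 2.0
    r_s: float = 0.1                      # MOhm
    leak_subtraction: str | None = "pn"
    n_subpulses: int = 4
    prepulse: tuple | None = None          # (voltage mV, duration ms)
    compartment: object = "soma"

    def __post_init__(self) -> None:
        if self.r_s <= 0:
            raise ValueError("series resistance must be positive")
        if self.leak_subtraction not in (None, "pn"):
            raise ValueError("leak_subtraction must be None or 'pn'")
        if self.leak_subtraction == "pn" and self.n_subpulses < 2:
            raise ValueError("P/n requires n >= 2 subpulses")
        pre = self.prepulse[1] if self.prepulse else 0.0
        if self.onset < pre + 7.0:
            raise ValueError("onset must leave >= 7 ms of baseline before "
                             "any prepulse")

    @classmethod
    def scan(cls, v_from: float, v_to: float, step: float = 0.5,
             **kw) -> "ClampProtocol":
        n = int(round((v_to - v_from) / step))
        return cls(commands=[v_from + i * step for i in range(n + 1)], **kw)

    @property
    def total_duration(self) -> float:
        return self.onset + self.duration + self.post


@dataclass
class ClampResult:
    """Per-command current traces from a voltage-clamp scan.

    ``raw`` holds the clamp current (pA, positive into the cell) including
    the holding baseline; ``corrected`` the baseline- and leak-subtracted
    traces (None when leak subtraction is off).  Distal-compartment voltage
    and Na-gate traces are retained for open-fraction analyses.
    """

    t: np.ndarray
    commands: np.ndarray
    raw: np.ndarray                 # (n_commands, T)
    corrected: np.ndarray | None
    baseline: np.ndarray            # (n_commands,)
    holding: float
    onset: float
    duration: float
    r_s: float
    v_soma: np.ndarray              # (n_commands, T)
    v_distal: np.ndarray
    m_distal: np.ndarray
    h_distal: np.ndarray
    exponents: tuple
    metadata: dict = field(default_factory=dict)

    @property
    def command_window(self) -> np.ndarray:
        return (self.t >= self.onset) & (self.t <= self.onset + self.duration)

    def best_traces(self) -> np.ndarray:
        if self.corrected is not None:
            return self.corrected
        return self.raw - self.baseline[:, None]

    def peak_currents(self) -> np.ndarray:
        """Peak current per command (nA): the maximum of |trace| within the
        command window, signed by its direction at the peak."""
        win = self.command_window
        tr = self.best_traces()[:, win]
        idx = np.argmax(np.abs(tr), axis=1)
        return tr[np.arange(tr.shape[0]), idx] * 1e-3

    def peak_latencies(self) -> np.ndarray:
        """Latency (ms) from command onset to the current peak."""
        win = self.command_window
        tr = self.best_traces()[:, win]
        tw = self.t[win]
        return tw[np.argmax(np.abs(tr), axis=1)] - self.onset

    def peak_open_fractions(self, measure: str = "activation") -> np.ndarray:
        """Peak open Na fraction at the distal axonal end per command:
        m^pm ('activation', as conventionally displayed) or m^pm * h^ph
        ('conductance')."""
        pm, ph, _ = self.exponents
        frac = self.m_distal**pm
        if measure == "conductance":
            frac = frac * self.h_distal**ph
        elif measure != "activation":
            raise ValueError("measure must be 'activation' or 'conductance'")
        return frac[:, self.command_window].max(axis=1)


def pn_correction(test_trace: np.ndarray, subpulse_traces: Sequence[np.ndarray],
                  scale: float = 1.0) -> np.ndarray:
    """P/n leak subtraction: ``corrected = test - scale * sum(subpulses)``.

    With n subpulses of amplitude (command - holding)/n the summed linear
    response equals the linear part of the test response and ``scale = 1``;
    for hyperpolarizing (sign-mirrored) subpulses use ``scale = -1``.
    """
    test_trace = np.asarray(test_trace, dtype=float)
    total = np.zeros_like(test_trace)
    for tr in subpulse_traces:
        tr = np.asarray(tr, dtype=float)
        if tr.shape != test_trace.shape:
            raise ValueError("subpulse traces must match the test trace length")
        total += tr
    return test_trace - scale * total


def _command_waveform(t, holding, command, onset, duration, prepulse):
    out = np.full_like(t, holding, dtype=float)
    if prepulse is not None:
        v_pre, d_pre = prepulse
        out[(t >= onset - d_pre) & (t < onset)] = v_pre
    out[(t >= onset) & (t < onset + duration)] = command
    return out


def run_voltage_clamp(
    model,
    clamp: ClampProtocol,
    dt: float = 1e-3,
    record_stride: int = 5,
) -> ClampResult:
    """Run a voltage-clamp scan at the soma.

    The soma is driven through the access resistance R_s, so the recorded
    current is (V_cmd - V_soma) / R_s.  Integration uses the backward-Euler
    variant of the implicit scheme: the clamp conductance 1/R_s makes the
    somatic equation stiff and Crank-Nicolson would ring at command steps.

    The linear-leak template for P/n correction is obtained from one
    subpulse simulation replicated n times: subpulses are independent,
    deterministic runs from the same holding state, so their responses are
    identical by construction.
    """
    graph = _as_graph(model)
    rest = resting_state(graph)
    holding = clamp.holding if clamp.holding is not None else float(
        rest.v[graph.soma_index])
    distal = (graph.compartment_index("axon_end") if "axon" in graph.sections
              else graph.n - 1)

    pre_end = clamp.onset - (clamp.prepulse[1] if clamp.prepulse else 0.0)
    raws, correcteds, baselines = [], [], []
    v_soma_l, v_dist_l, m_dist_l, h_dist_l = [], [], [], []
    t_rec = None

    for cmd in clamp.commands:
        res = _run_one_clamp(graph, rest, holding, cmd, clamp, dt,
                             record_stride, prepulse=clamp.prepulse)
        t_rec = res.t
        i_raw = res.i_clamp()
        base_win = (t_rec >= pre_end - 6.0) & (t_rec <= pre_end - 1.0)
        baseline = float(i_raw[base_win].mean())
        raws.append(i_raw)
        baselines.append(baseline)
        v_soma_l.append(res.v[:, graph.soma_index])
        v_dist_l.append(res.v[:, distal])
        m_dist_l.append(res.m[:, distal])
        h_dist_l.append(res.h[:, distal])

        if clamp.leak_subtraction == "pn":
            dv = cmd - holding
            sub_cmd = holding - dv / clamp.n_subpulses
            sub = _run_one_clamp(graph, rest, holding, sub_cmd, clamp, dt,
                                 record_stride, prepulse=None)
            i_sub = sub.i_clamp()
            sub_base = float(i_sub[base_win].mean())
            sub_bs = i_sub - sub_base
            corrected = pn_correction(
                i_raw - baseline, [sub_bs] * clamp.n_subpulses, scale=-1.0)
            correcteds.append(corrected)

    return ClampResult(
        t=t_rec,
        commands=np.asarray(clamp.commands, dtype=float),
        raw=np.array(raws),
        corrected=np.array(correcteds) if correcteds else None,
        baseline=np.array(baselines),
        holding=holding,
        onset=clamp.onset,
        duration=clamp.duration,
        r_s=clamp.r_s,
        v_soma=np.array(v_soma_l),
        v_distal=np.array(v_dist_l),
        m_distal=np.array(m_dist_l),
        h_distal=np.array(h_dist_l),
        exponents=graph.kinetics.exponents,
        metadata={"dt": dt, "record_stride": record_stride,
                  "n_subpulses": clamp.n_subpulses,
                  "leak_subtraction": clamp.leak_subtraction,
                  "prepulse": clamp.prepulse},
    )


def _run_one_clamp(graph, rest, holding, command, clamp, dt, record_stride,
                   prepulse) -> SimResult:
    drive = ClampDrive(
        command=lambda t: _command_waveform(
            t, holding, command, clamp.onset, clamp.duration, prepulse),
        r_s_mohm=clamp.r_s,
        compartment=clamp.compartment,
    )
    return run_simulation(
        graph, stimulus=None, duration=clamp.total_duration, dt=dt,
        record_stride=record_stride, theta=1.0, clamp=drive, initial=rest)


def run_prepulse_inactivation(model, clamp: ClampProtocol, dt: float = 1e-3,
                              record_stride: int = 5) -> ClampResult:
    """Voltage-clamp scan with a conditioning prepulse before each command
    (Na inactivation gates relax toward their steady state at the prepulse
    voltage, near zero for a depolarized prepulse)."""
    if clamp.prepulse is None:
        raise ValueError("clamp.prepulse must be set")
    return run_voltage_clamp(model, clamp, dt=dt, record_stride=record_stride)


# ---------------------------------------------------------------------------
# Spike detection
# ---------------------------------------------------------------------------


def detect_threshold(t: np.ndarray, v: np.ndarray, criterion: float = 5.0,
                     return_time: bool = False):
    """Spike threshold: V at the first upward crossing of dV/dt =
    ``criterion`` (mV/ms) before the spike peak, linearly interpolated
    between samples.  Returns None when the trace never reaches the
    criterion (no spike)."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    dvdt = np.gradient(v, t)
    peak = int(np.argmax(v))
    seg = dvdt[: peak + 1]
    above = np.nonzero(seg >= criterion)[0]
    if len(above) == 0:
        return None
    i = int(above[0])
    if i == 0:
        v_thr, t_thr = v[0], t[0]
    else:
        frac = (criterion - dvdt[i - 1]) / (dvdt[i] - dvdt[i - 1])
        v_thr = v[i - 1] + frac * (v[i] - v[i - 1])
        t_thr = t[i - 1] + frac * (t[i] - t[i - 1])
    if return_time:
        return float(v_thr), float(t_thr)
    return float(v_thr)


def find_rheobase(model, duration: float = 30.0, dt: float = 5e-3,
                  lo: float = 0.0, hi: float | None = None,
                  tol: float = 1.0, compartment="soma",
                  spike_voltage: float = -20.0) -> float:
    """Minimal sustained step current (pA) that elicits a spike, by
    bisection to ``tol`` pA.

    A run counts as spiking when any compartment exceeds
    ``spike_voltage``.  The bracket is grown by doubling from 100 pA if
    ``hi`` is not given.
    """
    initial = None
    if isinstance(model, TwoCompartmentParams):
        initial = resting_state(two_compartment_graph(model))
    else:
        initial = resting_state(model)

    def spikes(amp: float) -> bool:
        stim = StimulusProtocol.step(amp, onset=1.0, compartment=compartment)
        res = _simulate(model, stim, duration=duration, dt=dt,
                        record_stride=20, initial=initial)
        return bool(np.max(res.v) > spike_voltage)

    if hi is None:
        hi = 100.0
        while not spikes(hi):
            hi *= 2.0
            if hi > 1e6:
                raise RuntimeError("no spike up to 1 uA; model not excitable")
    if spikes(lo):
        raise ValueError("lower bracket already spikes")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi
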