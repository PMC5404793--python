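"""Synthetic traces with analytically known structure.

These generators produce voltage and clamp-current traces whose phase-plane
structure (or circuit response) is known in closed form, so every estimator
and protocol in the package can be validated without running a biophysical
simulation: exponential upstrokes with constant phase slope 1/tau, biphasic
piecewise-exponential upstrokes with two phase-slope plateaus, and passive
series-RC voltage-clamp responses.

Every trace carries its generating parameters (including the noise seed) in
its metadata, and identical specs produce identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticTrace",
    "make_exponential_upstroke",
    "make_biphasic",
    "make_passive_rc_clamp",
]


@dataclass
class SyntheticTrace:
    """A generated trace: time grid (ms), samples (mV for voltage traces,
    pA for current traces), and the generating parameters."""

    t: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)


def _add_noise(y: np.ndarray, noise_sd: float, seed: int | None) -> np.ndarray:
    if noise_sd <= 0:
        return y
    if seed is None:
        raise ValueError("a seed is required when noise is requested")
    rng = np.random.default_rng(seed)
    return y + rng.normal(0.0, noise_sd, size=y.shape)


def make_exponential_upstroke(
    v0: float = -70.0,
    amplitude: float = 0.5,
    tau: float = 0.2,
    v_cap: float = 0.0,
    dt: float = 0.01,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SyntheticTrace:
    """Exponential upstroke V(t) = v0 + A exp(t / tau), truncated at
    ``v_cap``.

    Its phase plot is the straight line dV/dt = (V - v0)/tau, so the phase
    slope is 1/tau at every point.
    """
    if tau <= 0 or amplitude <= 0 or dt <= 0:
        raise ValueError("tau, amplitude and dt must be positive")
    if v_cap <= v0 + amplitude:
        raise ValueError("v_cap must exceed the initial voltage")
    t_end = tau * math.log((v_cap - v0) / amplitude)
    t = np.arange(math.floor(t_end / dt) + 1) * dt  # last sample <= cap
    v = v0 + amplitude * np.exp(t / tau)
    v = _add_noise(v, noise_sd, seed)
    return SyntheticTrace(t=t, y=v, meta={
        "kind": "exponential_upstroke", "v0": v0, "amplitude": amplitude,
        "tau": tau, "rate": 1.0 / tau, "v_cap": v_cap, "dt": dt,
        "noise_sd": noise_sd, "seed": seed})


def make_biphasic(
    r1: float = 5.0,
    r2: float = 40.0,
    v0: float = -70.0,
    amplitude: float = 0.5,
    v_junction: float = -40.0,
    v_cap: float = 30.0,
    dt: float = 0.01,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SyntheticTrace:
    """Piecewise-exponential upstroke with phase slope r1 below
    ``v_junction`` and r2 above, continuous in V and dV/dt.

    Below the junction, dV/dt = r1 (V - v0); above it,
    dV/dt = r2 (V - v0') with v0' = v_junction - r1 (v_junction - v0) / r2,
    which makes dV/dt continuous at the junction.  The phase-slope function
    has two plateaus at r1 and r2, with no intervening dip -- the degenerate
    biphasic shape that a fixed-dV/dt rapidness measure mis-reads when the
    queried dV/dt falls on the wrong branch.
    """
    if not 0 < r1 < r2:
        raise ValueError("rates must satisfy 0 < r1 < r2")
    if not v0 + amplitude < v_junction < v_cap:
        raise ValueError("need v0 + amplitude < v_junction < v_cap")
    t1 = (1.0 / r1) * math.log((v_junction - v0) / amplitude)
    v0p = v_junction - r1 * (v_junction - v0) / r2
    a2 = v_junction - v0p
    t2 = (1.0 / r2) * math.log((v_cap - v0p) / a2)
    t = np.arange(math.floor((t1 + t2) / dt) + 1) * dt
    v = np.where(
        t <= t1,
        v0 + amplitude * np.exp(r1 * t),
        v0p + a2 * np.exp(r2 * np.clip(t - t1, 0, None)),
    )
    v = _add_noise(v, noise_sd, seed)
    return SyntheticTrace(t=t, y=v, meta={
        "kind": "biphasic", "r1": r1, "r2": r2, "v0": v0,
        "amplitude": amplitude, "v_junction": v_junction,
        "dvdt_junction": r1 * (v_junction - v0), "v_cap": v_cap, "dt": dt,
        "noise_sd": noise_sd, "seed": seed})


def make_passive_rc_clamp(
    capacitance: float = 100.0,      # pF
    g_leak: float = 10.0,            # nS
    r_s: float = 0.1,                # MOhm
    e_leak: float = -70.0,
    holding: float = -70.0,
    command: float = -50.0,
    onset: float = 5.0,
    duration: float = 20.0,
    dt: float = 0.01,
) -> SyntheticTrace:
    """Analytic clamp-current response (pA) of a passive RC membrane driven
    through a series resistance.

    The membrane obeys C dV/dt = (V_cmd - V)/R_s + g_L (E_L - V); the
    recorded current is (V_cmd - V)/R_s.  For a command step the response is
    an exponential transient with time constant C / (1/R_s + g_L) settling
    to the steady leak current g_L (V_inf - E_L) where
    V_inf = (V_cmd / R_s + g_L E_L) / (1/R_s + g_L).
    """
    if min(capacitance, g_leak, r_s, dt, duration) <= 0:
        raise ValueError("parameters must be positive")
    g_s = 1.0 / (r_s * 1e-3)         # nS
    g_tot = g_s + g_leak
    tau = capacitance / g_tot         # ms

    def v_inf(v_cmd: float) -> float:
        return (g_s * v_cmd + g_leak * e_leak) / g_tot

    t = np.arange(0.0, onset + duration + dt / 2, dt)
    v_hold = v_inf(holding)
    v_cmd_inf = v_inf(command)
    v = np.where(
        t < onset,
        v_hold,
        v_cmd_inf + (v_hold - v_cmd_inf) * np.exp(-np.clip(t - onset, 0, None) / tau),
    )
    v_cmd_trace = np.where(t < onset, holding, command)
    i = (v_cmd_trace - v) * g_s       # nS * mV = pA
    i_ss = g_s * (command - v_inf(command))
    return SyntheticTrace(t=t, y=i, meta={
        "kind": "passive_rc_clamp", "capacitance_pf": capacitance,
        "g_leak_ns": g_leak, "r_s_mohm": r_s, "e_leak": e_leak,
        "holding": holding, "command": command, "onset": onset,
        "duration": duration, "dt": dt, "tau_ms": tau,
        "steady_state_pa": float(i_ss),
        "v_trace": v})
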