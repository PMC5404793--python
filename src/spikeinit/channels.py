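"""Voltage-gated channel models.

Two families of kinetics are supported:

* Boltzmann steady states with voltage-independent, first-order relaxation
  (:class:`GateSpec`).  These are the deliberately minimal channels of the
  two-compartment soma-AIS model, and double as the fallback kinetics of the
  cable model.
* Arbitrary voltage-dependent rates supplied either as alpha/beta functions
  or as tabulated ``x_inf(V)`` / ``tau(V)`` curves (:class:`Kinetics`).  The
  canonical squid-axon Hodgkin-Huxley reference uses this path, and the same
  slot accepts user-supplied rate tables for channel models published
  elsewhere.

Sign convention for gates: a positive ``slope_factor`` describes activation
(open fraction increases with depolarization), a negative one inactivation.
A single Boltzmann code path serves both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "Kinetics",
    "HHSquidSpec",
    "boltzmann_inf",
    "gate_step",
    "hh_squid_resting_state",
    "hh_squid_kinetics",
    "NA_ACTIVATION",
    "NA_INACTIVATION",
    "K_ACTIVATION",
    "CABLE_NA_ACTIVATION",
]


@dataclass(frozen=True)
class GateSpec:
    """One first-order gate with a Boltzmann steady state.

    Parameters
    ----------
    half_activation_voltage : float
        Membrane potential of half-maximal steady state, mV.
    slope_factor : float
        Boltzmann slope k, mV.  Positive for activation, negative for
        inactivation; must be nonzero.
    time_constant : float
        Voltage-independent relaxation time constant, ms.
    exponent : int
        Number of identical gates multiplied in the conductance.
    """

    half_activation_voltage: float
    slope_factor: float
    time_constant: float
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.slope_factor == 0:
            raise ValueError("slope_factor must be nonzero")
        if self.time_constant <= 0:
            raise ValueError("time_constant must be positive")
        if self.exponent < 1:
            raise ValueError("exponent must be >= 1")


# The simplified single-gate channels of the two-compartment soma-AIS model.
NA_ACTIVATION = GateSpec(-25.0, 6.0, 0.1, 1)
NA_INACTIVATION = GateSpec(-35.0, -6.0, 0.5, 1)
K_ACTIVATION = GateSpec(-15.0, 4.0, 2.0, 1)

# Cable-model fallback Na activation: same Boltzmann/first-order machinery,
# but three identical gates (m^3, per-gate half-activation -40 mV).  A single
# gate at -25 mV leaves too much open fraction at rest (~5e-4): with the
# axonal density of 8000 pS/um^2 and the weak leak (R_m = 30 kOhm cm^2) the
# subthreshold Na current then exceeds the total leak everywhere and the
# cable has no resting state.  Cubing the gate suppresses the resting open
# fraction to ~3e-7 while keeping activation steep near threshold.
CABLE_NA_ACTIVATION = GateSpec(-40.0, 6.0, 0.1, 3)


def boltzmann_inf(v: float | np.ndarray, gate: GateSpec) -> float | np.ndarray:
    """Steady-state open fraction of a Boltzmann gate at potential ``v`` (mV).

    ``1 / (1 + exp(-(v - v_half) / k))``; strictly increasing in ``v`` for
    activation (k > 0), strictly decreasing for inactivation (k < 0), and
    bounded in (0, 1) for all finite ``v``.
    """
    x = -(np.asarray(v, dtype=float) - gate.half_activation_voltage) / gate.slope_factor
    out = np.where(
        x >= 0, np.exp(-np.clip(x, 0, None)) / (1.0 + np.exp(-np.clip(x, 0, None))),
        1.0 / (1.0 + np.exp(np.clip(x, None, 0))),
    )
    if np.isscalar(v) or np.asarray(v).ndim == 0:
        return float(out)
    return out


def gate_step(x: float, v: float, gate: GateSpec, dt: float) -> float:
    """Advance a gate by ``dt`` (ms) at fixed voltage ``v``.

    Exact exponential relaxation toward the steady state:
    ``x' = x_inf + (x - x_inf) * exp(-dt / tau)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x_inf = boltzmann_inf(v, gate)
    return x_inf + (x - x_inf) * math.exp(-dt / gate.time_constant)


@dataclass
class ChannelSpec:
    """A conductance-based channel: g * prod(gate^exponent) * (E_rev - V).

    ``conductance`` is either a total (nS) or a surface density (pS/um^2),
    distinguished by ``is_density``.
    """

    name: str
    conductance: float
    reversal_potential: float
    gates: list[GateSpec] = field(default_factory=list)
    is_density: bool = False

    def __post_init__(self) -> None:
        if self.conductance < 0:
            raise ValueError("conductance must be >= 0")

    def total_conductance_ns(self, area_um2: float | None = None) -> float:
        if not self.is_density:
            return self.conductance
        if area_um2 is None:
            raise ValueError("area required to convert a density channel")
        return self.conductance * area_um2 * 1e-3

    def open_fraction(self, gate_values: Sequence[float]) -> float:
        p = 1.0
        for g, x in zip(self.gates, gate_values, strict=True):
            p *= x ** g.exponent
        return p

    def current(self, v: float, gate_values: Sequence[float],
                area_um2: float | None = None) -> float:
        """Instantaneous current in pA, depolarizing-positive (E - V form)."""
        return self.total_conductance_ns(area_um2) * self.open_fraction(gate_values) * (
            self.reversal_potential - v
        )


# ---------------------------------------------------------------------------
# Tabulated kinetics shared by the integrators
# ---------------------------------------------------------------------------

_VGRID_MIN = -120.0
_VGRID_MAX = 80.0
_VGRID_STEP = 0.01


@dataclass
class Kinetics:
    """Na (activation m, inactivation h) and K (n) gate kinetics on a uniform
    voltage grid, with per-gate exponents.

    The integrators evaluate ``x_inf`` and ``tau`` by linear interpolation on
    this grid, which accommodates Boltzmann gates, alpha/beta rate functions
    and externally supplied rate tables through one code path.
    """

    v0: float
    dv: float
    inf: np.ndarray   # (3, n): rows m, h, n
    tau: np.ndarray   # (3, n), ms
    exponents: tuple[int, int, int]  # (p_m, p_h, p_n)

    @property
    def vgrid(self) -> np.ndarray:
        return self.v0 + self.dv * np.arange(self.inf.shape[1])

    def x_inf(self, v: float | np.ndarray, gate: int) -> np.ndarray:
        return np.interp(v, self.vgrid, self.inf[gate])

    def x_tau(self, v: float | np.ndarray, gate: int) -> np.ndarray:
        return np.interp(v, self.vgrid, self.tau[gate])

    def steady_open_na(self, v: float | np.ndarray) -> np.ndarray:
        pm, ph, _ = self.exponents
        return self.x_inf(v, 0) ** pm * self.x_inf(v, 1) ** ph

    def steady_open_k(self, v: float | np.ndarray) -> np.ndarray:
        return self.x_inf(v, 2) ** self.exponents[2]

    @classmethod
    def from_gate_specs(
        cls,
        na_activation: GateSpec = NA_ACTIVATION,
        na_inactivation: GateSpec = NA_INACTIVATION,
        k_activation: GateSpec = K_ACTIVATION,
    ) -> "Kinetics":
        v = np.arange(_VGRID_MIN, _VGRID_MAX + _VGRID_STEP / 2, _VGRID_STEP)
        gates = (na_activation, na_inactivation, k_activation)
        inf = np.stack([np.asarray(boltzmann_inf(v, g)) for g in gates])
        tau = np.stack([np.full_like(v, g.time_constant) for g in gates])
        exps = tuple(g.exponent for g in gates)
        return cls(v[0], _VGRID_STEP, inf, tau, exps)  # type: ignore[arg-type]

    @classmethod
    def from_rate_functions(
        cls,
        alpha: Sequence[Callable[[np.ndarray], np.ndarray]],
        beta: Sequence[Callable[[np.ndarray], np.ndarray]],
        exponents: tuple[int, int, int],
    ) -> "Kinetics":
        """Build from alpha/beta rate functions (1/ms) for gates (m, h, n)."""
        v = np.arange(_VGRID_MIN, _VGRID_MAX + _VGRID_STEP / 2, _VGRID_STEP)
        inf_rows, tau_rows = [], []
        for a, b in zip(alpha, beta, strict=True):
            av, bv = a(v), b(v)
            inf_rows.append(av / (av + bv))
            tau_rows.append(1.0 / (av + bv))
        return cls(v[0], _VGRID_STEP, np.stack(inf_rows), np.stack(tau_rows), exponents)

    @classmethod
    def from_tables(
        cls,
        v: np.ndarray,
        inf: np.ndarray,
        tau: np.ndarray,
        exponents: tuple[int, int, int],
    ) -> "Kinetics":
        """Loader slot for user-supplied rate tables (rows m, h, n).

        Tables are re-interpolated onto the internal uniform grid.
        """
        vg = np.arange(_VGRID_MIN, _VGRID_MAX + _VGRID_STEP / 2, _VGRID_STEP)
        inf_u = np.stack([np.interp(vg, v, row) for row in np.atleast_2d(inf)])
        tau_u = np.stack([np.interp(vg, v, row) for row in np.atleast_2d(tau)])
        if np.any(tau_u <= 0):
            raise ValueError("time constants must be positive")
        return cls(vg[0], _VGRID_STEP, inf_u, tau_u, exponents)

    @classmethod
    def from_file(cls, path: str, exponents: tuple[int, int, int]) -> "Kinetics":
        """Read a whitespace-separated table: V, m_inf, m_tau, h_inf, h_tau,
        n_inf, n_tau (header lines starting with '#' are ignored)."""
        data = np.loadtxt(path, comments="#")
        v = data[:, 0]
        inf = data[:, [1, 3, 5]].T
        tau = data[:, [2, 4, 6]].T
        return cls.from_tables(v, inf, tau, exponents)


# ---------------------------------------------------------------------------
# Canonical squid-axon Hodgkin-Huxley reference
# ---------------------------------------------------------------------------


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 handled."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x / y) < 1e-6
    out[small] = y * (1.0 + x[small] / (2.0 * y))
    out[~small] = x[~small] / (1.0 - np.exp(-x[~small] / y))
    return out


def _alpha_m(v):
    return 0.1 * _vtrap(v + 40.0, 10.0)


def _beta_m(v):
    return 4.0 * np.exp(-(np.asarray(v, float) + 65.0) / 18.0)


def _alpha_h(v):
    return 0.07 * np.exp(-(np.asarray(v, float) + 65.0) / 20.0)


def _beta_h(v):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) + 35.0) / 10.0))


def _alpha_n(v):
    return 0.01 * _vtrap(v + 55.0, 10.0)


def _beta_n(v):
    return 0.125 * np.exp(-(np.asarray(v, float) + 65.0) / 80.0)


@dataclass(frozen=True)
class HHSquidSpec:
    """Canonical squid-axon parameter set (6.3 degC) on an absolute voltage
    scale with rest near -65 mV.

    Densities in uF/cm^2 and mS/cm^2, reversals in mV.
    """

    c_m: float = 1.0
    g_na: float = 120.0
    g_k: float = 36.0
    g_leak: float = 0.3
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.387

    alpha = staticmethod(
        lambda gate, v: (_alpha_m, _alpha_h, _alpha_n)[gate](v)
    )
    beta = staticmethod(
        lambda gate, v: (_beta_m, _beta_h, _beta_n)[gate](v)
    )


def hh_squid_kinetics() -> Kinetics:
    """Tabulated m^3 h / n^4 kinetics of the canonical squid membrane."""
    return Kinetics.from_rate_functions(
        alpha=(_alpha_m, _alpha_h, _alpha_n),
        beta=(_beta_m, _beta_h, _beta_n),
        exponents=(3, 1, 4),
    )


def hh_squid_resting_state(
    spec: HHSquidSpec | None = None,
) -> tuple[float, float, float, float]:
    """Resting fixed point (V_rest, m, h, n) of the canonical squid membrane.

    Solves the current balance with gates at steady state; gate values equal
    alpha/(alpha+beta) at the resting potential.  Raises ``RuntimeError`` if
    the bracketing root search fails.
    """
    spec = spec or HHSquidSpec()

    def balance(v: float) -> float:
        m = float(_alpha_m(v) / (_alpha_m(v) + _beta_m(v)))
        h = float(_alpha_h(v) / (_alpha_h(v) + _beta_h(v)))
        n = float(_alpha_n(v) / (_alpha_n(v) + _beta_n(v)))
        return (
            spec.g_leak * (spec.e_leak - v)
            + spec.g_na * m**3 * h * (spec.e_na - v)
            + spec.g_k * n**4 * (spec.e_k - v)
        )

    try:
        v_rest = brentq(balance, -90.0, -40.0, xtol=1e-12)
    except ValueError as exc:  # pragma: no cover - degenerate parameter sets
        raise RuntimeError("resting-point search did not converge") from exc
    m = float(_alpha_m(v_rest) / (_alpha_m(v_rest) + _beta_m(v_rest)))
    h = float(_alpha_h(v_rest) / (_alpha_h(v_rest) + _beta_h(v_rest)))
    n = float(_alpha_n(v_rest) / (_alpha_n(v_rest) + _beta_n(v_rest)))
    return float(v_rest), m, h, n
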