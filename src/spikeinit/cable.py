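"""Compartmental cable model of the soma-axon (optionally soma-dendrite-axon)
system.

The geometry is deliberately simple: an isopotential cylindrical soma joined
to a uniform cylindrical axon, with an optional uniform dendrite on the other
side.  Compartments form a path graph ordered dendrite (distal to proximal),
soma, axon (proximal to distal), so the implicit voltage update is a
tridiagonal solve.  Voltages advance with a Crank-Nicolson scheme and gates
with exact exponential relaxation per step (operator splitting); every
simulation records per-compartment voltages and gating states from which all
per-current-type traces are reconstructed exactly.

Sign conventions: membrane currents are reported as their contribution to
C dV/dt, i.e. depolarizing-positive; the axial current of link i is the
current flowing from compartment i into compartment i-1, so the current at
the soma-axon junction is positive when flowing from axon toward soma.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.optimize import root

from . import units
from ._integrator import cable_loop
from .channels import (
    CABLE_NA_ACTIVATION,
    HHSquidSpec,
    K_ACTIVATION,
    Kinetics,
    NA_INACTIVATION,
    hh_squid_kinetics,
)


def default_cable_kinetics() -> Kinetics:
    """Fallback channel kinetics of the cable model: Boltzmann gates with
    fixed time constants, Na as m^3 h (per-gate half-activation -40 mV) and
    K as a single 2-ms gate."""
    return Kinetics.from_gate_specs(
        CABLE_NA_ACTIVATION, NA_INACTIVATION, K_ACTIVATION)

__all__ = [
    "ModelConfig",
    "CompartmentGraph",
    "SimResult",
    "ClampDrive",
    "SolverDivergence",
    "axial_resistance",
    "build_model",
    "cluster_channels",
    "resting_state",
    "run_simulation",
    "junction_axial_current",
    "initiation_site",
    "hh_squid_graph",
    "default_cable_kinetics",
]


class SolverDivergence(RuntimeError):
    """Raised when the integrator produces a non-finite voltage.

    Carries a diagnostic ``state`` dict (step index, last finite state).
    """

    def __init__(self, message: str, state: dict):
        super().__init__(message)
        self.state = state


def axial_resistance(r_i: float, l1: float, d1: float, l2: float, d2: float) -> float:
    """Center-to-center axial resistance (GOhm) between two adjoining
    half-segments of lengths ``l1``, ``l2`` (um) and diameters ``d1``, ``d2``
    (um), for intracellular resistivity ``r_i`` (Ohm*cm).

    ``R = (4 r_i / pi) * (l1 / (2 d1^2) + l2 / (2 d2^2))``.
    """
    return units.axial_resistance_gohm(r_i, l1, d1, l2, d2)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Full description of the simple compartmental model.

    Geometry in um, resistivity in Ohm*cm, specific capacitance in uF/cm^2,
    specific membrane resistance in Ohm*cm^2, channel densities in pS/um^2,
    potentials in mV -- the units in which such models are conventionally
    published.
    """

    # geometry
    soma_length: float = 30.0
    soma_diameter: float = 20.0
    axon_length: float = 50.0
    axon_diameter: float = 1.0
    axon_segments: int = 50
    include_dendrite: bool = False
    dendrite_length: float = 3000.0
    dendrite_diameter: float = 5.0
    dendrite_segments: int = 60
    # passive properties
    r_i: float = 150.0
    c_m: float = 0.75
    r_m: float = 30000.0
    e_leak: float = -70.0
    # channel densities per section
    na_density_axon: float = 8000.0
    na_density_soma: float = 800.0
    na_density_dendrite: float = 20.0
    k_density_axon: float = 1500.0
    k_density_soma: float = 320.0
    k_density_dendrite: float = 0.0
    # reversal potentials
    e_na: float = 60.0
    e_k: float = -90.0

    @property
    def membrane_time_constant(self) -> float:
        """Passive membrane time constant R_m * C_m, ms."""
        return self.r_m * self.c_m * 1e-3

    def validate(self) -> None:
        if min(self.soma_length, self.soma_diameter, self.axon_length,
               self.axon_diameter) <= 0:
            raise ValueError("geometry must be positive")
        if self.axon_segments < 1:
            raise ValueError("axon_segments must be >= 1")
        if self.include_dendrite and (
            min(self.dendrite_length, self.dendrite_diameter) <= 0
            or self.dendrite_segments < 1
        ):
            raise ValueError("dendrite geometry must be positive")
        if min(self.r_i, self.c_m, self.r_m) <= 0:
            raise ValueError("passive parameters must be positive")
        for name in ("na_density_axon", "na_density_soma", "na_density_dendrite",
                     "k_density_axon", "k_density_soma", "k_density_dendrite"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- structured-text (YAML) round trip ---------------------------------
    def to_dict(self) -> dict:
        return {
            "geometry": {
                "soma_length_um": self.soma_length,
                "soma_diameter_um": self.soma_diameter,
                "axon_length_um": self.axon_length,
                "axon_diameter_um": self.axon_diameter,
                "axon_segments": self.axon_segments,
                "include_dendrite": self.include_dendrite,
                "dendrite_length_um": self.dendrite_length,
                "dendrite_diameter_um": self.dendrite_diameter,
                "dendrite_segments": self.dendrite_segments,
            },
            "passive": {
                "r_i_ohm_cm": self.r_i,
                "c_m_uf_cm2": self.c_m,
                "r_m_ohm_cm2": self.r_m,
                "e_leak_mv": self.e_leak,
            },
            "channels": {
                "na_density_ps_um2": {
                    "axon": self.na_density_axon,
                    "soma": self.na_density_soma,
                    "dendrite": self.na_density_dendrite,
                },
                "k_density_ps_um2": {
                    "axon": self.k_density_axon,
                    "soma": self.k_density_soma,
                    "dendrite": self.k_density_dendrite,
                },
                "e_na_mv": self.e_na,
                "e_k_mv": self.e_k,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        g, p, c = d.get("geometry", {}), d.get("passive", {}), d.get("channels", {})
        na = c.get("na_density_ps_um2", {})
        k = c.get("k_density_ps_um2", {})
        kw = {}
        mapping = [
            ("soma_length", g, "soma_length_um"),
            ("soma_diameter", g, "soma_diameter_um"),
            ("axon_length", g, "axon_length_um"),
            ("axon_diameter", g, "axon_diameter_um"),
            ("axon_segments", g, "axon_segments"),
            ("include_dendrite", g, "include_dendrite"),
            ("dendrite_length", g, "dendrite_length_um"),
            ("dendrite_diameter", g, "dendrite_diameter_um"),
            ("dendrite_segments", g, "dendrite_segments"),
            ("r_i", p, "r_i_ohm_cm"),
            ("c_m", p, "c_m_uf_cm2"),
            ("r_m", p, "r_m_ohm_cm2"),
            ("e_leak", p, "e_leak_mv"),
            ("na_density_axon", na, "axon"),
            ("na_density_soma", na, "soma"),
            ("na_density_dendrite", na, "dendrite"),
            ("k_density_axon", k, "axon"),
            ("k_density_soma", k, "soma"),
            ("k_density_dendrite", k, "dendrite"),
            ("e_na", c, "e_na_mv"),
            ("e_k", c, "e_k_mv"),
        ]
        for attr, section, key in mapping:
            if key in section:
                kw[attr] = section[key]
        return cls(**kw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Compartment graph
# ---------------------------------------------------------------------------


@dataclass
class CompartmentGraph:
    """Discretized model: per-compartment absolute quantities plus the chain
    of axial links.

    Arrays are indexed dendrite (distal..proximal), soma, axon
    (proximal..distal).  ``r_axial[i]`` is the resistance (GOhm) of the link
    between compartments ``i-1`` and ``i``; ``r_axial[0]`` is unused.
    """

    cap: np.ndarray          # pF
    area: np.ndarray         # um^2
    g_na: np.ndarray         # nS (absolute, per compartment)
    g_k: np.ndarray          # nS
    g_leak: np.ndarray       # nS
    r_axial: np.ndarray      # GOhm
    e_na: float
    e_k: float
    e_leak: float
    soma_index: int
    sections: dict           # name -> (start, stop) index range
    x0: np.ndarray           # um, proximal end coordinate along the cell axis
    x1: np.ndarray           # um, distal end coordinate
    radius: np.ndarray       # um
    kinetics: Kinetics
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.n
        for arr in (self.area, self.g_na, self.g_k, self.g_leak,
                    self.r_axial, self.x0, self.x1, self.radius):
            if len(arr) != n:
                raise ValueError("inconsistent array lengths")
        if np.any(self.cap <= 0):
            raise ValueError("capacitances must be positive")
        if n > 1 and np.any(self.r_axial[1:] <= 0):
            raise ValueError("axial resistances must be positive")
        if not self.labels:
            self.labels = [self.label(i) for i in range(n)]

    @property
    def n(self) -> int:
        return len(self.cap)

    @property
    def links(self) -> list:
        """Axial links as (i-1, i, R_GOhm) tuples (the graph is a path,
        hence trivially a tree)."""
        return [(i - 1, i, float(self.r_axial[i])) for i in range(1, self.n)]

    @property
    def junction_link(self) -> int | None:
        """Index i of the soma-axon junction link (between soma and the first
        axonal compartment), or None if the model has no axon."""
        if "axon" not in self.sections:
            return None
        return self.sections["axon"][0]

    def label(self, i: int) -> str:
        for name, (start, stop) in self.sections.items():
            if start <= i < stop:
                return name if stop - start == 1 else f"{name}[{i - start}]"
        return f"comp[{i}]"

    def compartment_index(self, spec) -> int:
        """Resolve 'soma', 'axon_end', ('axon', k), ('dendrite', k) or an
        absolute integer index."""
        if isinstance(spec, (int, np.integer)):
            return int(spec)
        if spec == "soma":
            return self.soma_index
        if spec == "axon_end":
            return self.sections["axon"][1] - 1
        if isinstance(spec, tuple) and len(spec) == 2:
            name, k = spec
            start, stop = self.sections[name]
            idx = start + int(k)
            if not start <= idx < stop:
                raise IndexError(f"segment {k} outside section {name}")
            return idx
        raise ValueError(f"cannot resolve compartment {spec!r}")

    def copy(self) -> "CompartmentGraph":
        return dataclasses.replace(
            self,
            cap=self.cap.copy(), area=self.area.copy(),
            g_na=self.g_na.copy(), g_k=self.g_k.copy(),
            g_leak=self.g_leak.copy(), r_axial=self.r_axial.copy(),
            x0=self.x0.copy(), x1=self.x1.copy(), radius=self.radius.copy(),
            labels=list(self.labels),
        )


def build_model(config: ModelConfig, kinetics: Kinetics | None = None) -> CompartmentGraph:
    """Discretize a :class:`ModelConfig` into a :class:`CompartmentGraph`.

    The soma is a single isopotential node (its internal axial resistance is
    neglected); cylinder side-wall areas are used throughout, end caps
    excluded.  The soma-axon junction resistance is the half-resistance of
    the first axonal segment.
    """
    config.validate()
    kin = kinetics or default_cable_kinetics()
    leak_density = units.leak_density_ps_um2(config.r_m)

    areas, caps, gna, gk, gl = [], [], [], [], []
    x0s, x1s, radii, raxial = [], [], [], []
    sections: dict = {}
    idx = 0

    def add_comp(area, na_d, k_d, x0, x1, radius, r_link):
        areas.append(area)
        caps.append(units.capacitance_pf(area, config.c_m))
        gna.append(units.density_to_total_ns(na_d, area))
        gk.append(units.density_to_total_ns(k_d, area))
        gl.append(units.density_to_total_ns(leak_density, area))
        x0s.append(x0)
        x1s.append(x1)
        radii.append(radius)
        raxial.append(r_link)

    soma_x0 = -config.soma_length
    if config.include_dendrite:
        nd = config.dendrite_segments
        ld = config.dendrite_length / nd
        area_d = units.cylinder_area_um2(ld, config.dendrite_diameter)
        r_dd = axial_resistance(config.r_i, ld, config.dendrite_diameter,
                                ld, config.dendrite_diameter)
        r_ds = axial_resistance(config.r_i, ld, config.dendrite_diameter, 0.0, 1.0)
        dend_x0 = soma_x0 - config.dendrite_length
        for k in range(nd):
            # index 0 = distal dendrite tip; x decreases toward the tip
            x_far = dend_x0 + (nd - k - 1) * ld
            add_comp(area_d, config.na_density_dendrite, config.k_density_dendrite,
                     x_far + ld, x_far, config.dendrite_diameter / 2,
                     math.inf if k == 0 else r_dd)
        sections["dendrite"] = (0, nd)
        idx = nd
        soma_link = r_ds  # soma joined by the half-resistance of the last dendrite seg
    else:
        soma_link = math.inf

    area_s = units.cylinder_area_um2(config.soma_length, config.soma_diameter)
    add_comp(area_s, config.na_density_soma, config.k_density_soma,
             soma_x0, 0.0, config.soma_diameter / 2, soma_link)
    sections["soma"] = (idx, idx + 1)
    soma_index = idx
    idx += 1

    na_ = config.axon_segments
    la = config.axon_length / na_
    area_a = units.cylinder_area_um2(la, config.axon_diameter)
    r_aa = axial_resistance(config.r_i, la, config.axon_diameter,
                            la, config.axon_diameter)
    r_sa = axial_resistance(config.r_i, 0.0, 1.0, la, config.axon_diameter)
    for k in range(na_):
        add_comp(area_a, config.na_density_axon, config.k_density_axon,
                 k * la, (k + 1) * la, config.axon_diameter / 2,
                 r_sa if k == 0 else r_aa)
    sections["axon"] = (idx, idx + na_)

    return CompartmentGraph(
        cap=np.array(caps), area=np.array(areas),
        g_na=np.array(gna), g_k=np.array(gk), g_leak=np.array(gl),
        r_axial=np.array(raxial),
        e_na=config.e_na, e_k=config.e_k, e_leak=config.e_leak,
        soma_index=soma_index, sections=sections,
        x0=np.array(x0s), x1=np.array(x1s), radius=np.array(radii),
        kinetics=kin,
    )


def hh_squid_graph(area_um2: float = 1000.0, spec: HHSquidSpec | None = None
                   ) -> CompartmentGraph:
    """Single isopotential compartment with canonical squid-axon membrane."""
    spec = spec or HHSquidSpec()
    # 1 mS/cm^2 = 10 pS/um^2; 1 uF/cm^2 = 0.01 pF/um^2
    g = np.array([1.0])
    return CompartmentGraph(
        cap=np.array([area_um2 * spec.c_m * 0.01]),
        area=np.array([area_um2]),
        g_na=np.array([spec.g_na * 10 * area_um2 * 1e-3]),
        g_k=np.array([spec.g_k * 10 * area_um2 * 1e-3]),
        g_leak=np.array([spec.g_leak * 10 * area_um2 * 1e-3]),
        r_axial=np.array([math.inf]),
        e_na=spec.e_na, e_k=spec.e_k, e_leak=spec.e_leak,
        soma_index=0, sections={"soma": (0, 1)},
        x0=np.array([0.0]), x1=np.array([math.sqrt(area_um2)]),
        radius=np.array([math.sqrt(area_um2 / math.pi) / 2]),
        kinetics=hh_squid_kinetics(),
    )


def cluster_channels(graph: CompartmentGraph, target_segment: int) -> CompartmentGraph:
    """Concentrate all axonal Na and K conductance on one axonal segment.

    ``target_segment`` is a 0-based index within the axon (proximal to
    distal).  Total conductance over the axon is preserved exactly; with a
    uniform n-segment axon the target's density is multiplied by n.
    """
    if "axon" not in graph.sections:
        raise ValueError("model has no axon")
    start, stop = graph.sections["axon"]
    tgt = start + int(target_segment)
    if not start <= tgt < stop:
        raise IndexError("target segment outside the axon")
    out = graph.copy()
    for arr in (out.g_na, out.g_k):
        total = arr[start:stop].sum()
        arr[start:stop] = 0.0
        arr[tgt] = total
    return out


# ---------------------------------------------------------------------------
# Resting state
# ---------------------------------------------------------------------------


@dataclass
class RestingState:
    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray


def resting_state(graph: CompartmentGraph) -> RestingState:
    """Fixed point of the full system with gates at steady state.

    Solves the coupled current balance over compartments with a root finder;
    raises ``RuntimeError`` on failure.
    """
    kin = graph.kinetics
    g_ax = np.zeros(graph.n)
    if graph.n > 1:
        g_ax[1:] = 1.0 / graph.r_axial[1:]

    def residual(v: np.ndarray) -> np.ndarray:
        gna = graph.g_na * kin.steady_open_na(v)
        gk = graph.g_k * kin.steady_open_k(v)
        f = (graph.g_leak * (graph.e_leak - v)
             + gna * (graph.e_na - v) + gk * (graph.e_k - v))
        if graph.n > 1:
            dv = np.diff(v)
            ax = g_ax[1:] * dv  # current from i into i-1
            f[:-1] += ax
            f[1:] -= ax
        return f

    # residuals are balanced currents; accept when below 1e-3 pA
    atol = 1e-3
    for guess in (np.full(graph.n, graph.e_leak), np.full(graph.n, -65.0)):
        sol = root(residual, guess, method="hybr", tol=1e-13)
        v = sol.x
        if np.max(np.abs(residual(v))) < atol:
            return RestingState(
                v=v,
                m=np.asarray(kin.x_inf(v, 0), dtype=float),
                h=np.asarray(kin.x_inf(v, 1), dtype=float),
                n=np.asarray(kin.x_inf(v, 2), dtype=float),
            )
    raise RuntimeError("resting-state search did not converge")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class ClampDrive:
    """Voltage-clamp drive through a series resistance.

    ``command`` maps a time grid (ms) to the command potential (mV).
    """

    command: Callable[[np.ndarray], np.ndarray]
    r_s_mohm: float = 0.1
    compartment: object = "soma"

    @property
    def g_clamp_ns(self) -> float:
        if self.r_s_mohm <= 0:
            raise ValueError("series resistance must be positive")
        return 1.0 / units.mohm_to_gohm(self.r_s_mohm)


@dataclass
class SimResult:
    """Recorded traces of one run: time grid (ms, uniform at
    ``dt * record_stride``), per-compartment voltages (mV) and gates, plus
    enough bookkeeping to reconstruct every current trace (pA) exactly.

    All arrays are time-major: shape (T, n_compartments).
    """

    t: np.ndarray
    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    graph: CompartmentGraph
    dt: float
    record_stride: int
    stim_index: int | None = None
    i_inj: np.ndarray | None = None          # (T,) at the stimulated compartment
    clamp_index: int | None = None
    clamp_command: np.ndarray | None = None  # (T,)
    clamp_r_s_mohm: float | None = None
    metadata: dict = field(default_factory=dict)

    # -- current bookkeeping (depolarizing-positive) -----------------------
    def open_na(self) -> np.ndarray:
        pm, ph, _ = self.graph.kinetics.exponents
        return self.m**pm * self.h**ph

    def i_na(self) -> np.ndarray:
        return self.graph.g_na * self.open_na() * (self.graph.e_na - self.v)

    def i_k(self) -> np.ndarray:
        pn = self.graph.kinetics.exponents[2]
        return self.graph.g_k * self.n**pn * (self.graph.e_k - self.v)

    def i_leak(self) -> np.ndarray:
        return self.graph.g_leak * (self.graph.e_leak - self.v)

    def i_clamp(self) -> np.ndarray:
        """Clamp current (pA) delivered through the series resistance,
        positive into the cell."""
        if self.clamp_index is None:
            raise ValueError("run had no voltage clamp")
        r_gohm = units.mohm_to_gohm(self.clamp_r_s_mohm)
        return (self.clamp_command - self.v[:, self.clamp_index]) / r_gohm

    def injected_matrix(self) -> np.ndarray:
        """External (electrode) current per compartment and sample, pA."""
        out = np.zeros_like(self.v)
        if self.i_inj is not None and self.stim_index is not None:
            out[:, self.stim_index] += self.i_inj
        if self.clamp_index is not None:
            out[:, self.clamp_index] += self.i_clamp()
        return out

    def axial_link_currents(self) -> np.ndarray:
        """(T, n) array; column i is the current of link i flowing from
        compartment i into compartment i-1 (column 0 is zero)."""
        out = np.zeros_like(self.v)
        if self.graph.n > 1:
            g = 1.0 / self.graph.r_axial[1:]
            out[:, 1:] = (self.v[:, 1:] - self.v[:, :-1]) * g
        return out

    def axial_in(self) -> np.ndarray:
        """Net axial current received by each compartment, pA."""
        j = self.axial_link_currents()
        out = np.zeros_like(self.v)
        out[:, :-1] += j[:, 1:]
        out[:, 1:] -= j[:, 1:]
        return out

    def membrane_source_currents(self) -> np.ndarray:
        """Current each compartment passes to the extracellular space
        (capacitive + ionic, outward-positive), pA.

        By Kirchhoff's law this equals axial-in plus injected current, which
        avoids numerical differentiation of the voltage.
        """
        return self.axial_in() + self.injected_matrix()

    def dvdt(self, compartment=None) -> np.ndarray:
        """Centered-difference dV/dt (mV/ms); one-sided at the ends."""
        v = self.v if compartment is None else self.v[:, self.graph.compartment_index(compartment)]
        return np.gradient(v, self.t, axis=0)

    @property
    def v_soma(self) -> np.ndarray:
        return self.v[:, self.graph.soma_index]

    @property
    def v_axon_end(self) -> np.ndarray:
        return self.v[:, self.graph.compartment_index("axon_end")]

    # -- export ------------------------------------------------------------
    def to_table(self, path: str | None = None, compartments=None):
        """Columnar table (time + named voltage traces); optionally written
        as tab-separated text."""
        import pandas as pd

        if compartments is None:
            idx = list(range(self.graph.n))
        else:
            idx = [self.graph.compartment_index(c) for c in compartments]
        data = {"time_ms": self.t}
        for i in idx:
            data[f"v_{self.graph.labels[i]}_mv"] = self.v[:, i]
        df = pd.DataFrame(data)
        if path is not None:
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return df

    def to_hdf5(self, path: str) -> None:
        """Full per-compartment dump in a hierarchical binary container."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_ms", data=self.t)
            st = fh.create_group("state")
            for name, arr in (("v", self.v), ("m", self.m), ("h", self.h),
                              ("n", self.n)):
                st.create_dataset(name, data=arr)
            fh.attrs["dt_ms"] = self.dt
            fh.attrs["record_stride"] = self.record_stride
            fh.attrs["labels"] = [s.encode() for s in self.graph.labels]


def run_simulation(
    graph: CompartmentGraph,
    stimulus=None,
    duration: float = 50.0,
    dt: float = 1e-3,
    record_stride: int = 10,
    theta: float = 0.5,
    clamp: ClampDrive | None = None,
    initial: RestingState | None = None,
) -> SimResult:
    """Integrate the model for ``duration`` ms with time step ``dt`` ms.

    ``stimulus`` is any object with a ``waveform(t_ms) -> pA`` method and a
    ``compartment`` attribute (see :mod:`spikeinit.protocols`).  ``theta``
    selects the implicit scheme (0.5 Crank-Nicolson, 1.0 backward Euler; the
    latter is preferred for stiff voltage-clamp drives).  Starts from the
    model's resting state unless ``initial`` is given.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    nsteps = int(round(duration / dt))
    if nsteps < 1:
        raise ValueError("duration shorter than one step")
    tgrid = np.arange(nsteps + 1) * dt

    if stimulus is not None:
        i_stim = np.asarray(stimulus.waveform(tgrid), dtype=float)
        stim_idx = graph.compartment_index(getattr(stimulus, "compartment", "soma"))
    else:
        i_stim = np.zeros(nsteps + 1)
        stim_idx = graph.soma_index

    if clamp is not None:
        v_cmd = np.asarray(clamp.command(tgrid), dtype=float)
        g_clamp = clamp.g_clamp_ns
        clamp_idx = graph.compartment_index(clamp.compartment)
    else:
        v_cmd = np.zeros(nsteps + 1)
        g_clamp = 0.0
        clamp_idx = 0

    state = initial or resting_state(graph)
    v = state.v.astype(float).copy()
    m = state.m.astype(float).copy()
    h = state.h.astype(float).copy()
    n = state.n.astype(float).copy()

    kin = graph.kinetics
    g_ax = np.zeros(graph.n)
    if graph.n > 1:
        g_ax[1:] = 1.0 / graph.r_axial[1:]

    nrec = nsteps // record_stride + 1
    rec_v = np.empty((nrec, graph.n))
    rec_m = np.empty((nrec, graph.n))
    rec_h = np.empty((nrec, graph.n))
    rec_n = np.empty((nrec, graph.n))

    pm, ph, pn = kin.exponents
    bad = cable_loop(
        v, m, h, n,
        graph.cap.astype(float), graph.g_na.astype(float),
        graph.g_k.astype(float), graph.g_leak.astype(float),
        float(graph.e_na), float(graph.e_k), float(graph.e_leak),
        pm, ph, pn,
        kin.v0, kin.dv,
        kin.inf[0], kin.tau[0], kin.inf[1], kin.tau[1], kin.inf[2], kin.tau[2],
        g_ax, i_stim, stim_idx,
        g_clamp, v_cmd, clamp_idx,
        dt, nsteps, record_stride, theta,
        rec_v, rec_m, rec_h, rec_n,
    )
    if bad >= 0:
        raise SolverDivergence(
            f"non-finite voltage at step {bad} (t = {bad * dt:.4f} ms)",
            state={"step": bad, "t_ms": bad * dt, "v": v, "m": m, "h": h, "n": n},
        )

    t_rec = tgrid[: (nrec - 1) * record_stride + 1 : record_stride]
    return SimResult(
        t=t_rec, v=rec_v, m=rec_m, h=rec_h, n=rec_n,
        graph=graph, dt=dt, record_stride=record_stride,
        stim_index=stim_idx if stimulus is not None else None,
        i_inj=i_stim[::record_stride][:nrec] if stimulus is not None else None,
        clamp_index=clamp_idx if clamp is not None else None,
        clamp_command=v_cmd[::record_stride][:nrec] if clamp is not None else None,
        clamp_r_s_mohm=clamp.r_s_mohm if clamp is not None else None,
        metadata={"theta": theta, "duration_ms": duration},
    )


def junction_axial_current(result: SimResult) -> np.ndarray:
    """Signed current trace (pA) through the soma-axon junction link;
    positive when flowing from axon toward soma."""
    jl = result.graph.junction_link
    if jl is None:
        raise ValueError("model has no axon")
    return (result.v[:, jl] - result.v[:, jl - 1]) / result.graph.r_axial[jl]


def initiation_site(result: SimResult, criterion: float = 5.0) -> str:
    """Label of the compartment whose voltage first crosses the dV/dt
    criterion (mV/ms); ties broken toward the earlier (first) compartment."""
    dvdt = np.gradient(result.v, result.t, axis=0)
    crossed = dvdt >= criterion
    if not crossed.any():
        raise ValueError("no compartment reaches the dV/dt criterion")
    first_t = np.where(crossed.any(axis=0), crossed.argmax(axis=0), np.iinfo(np.int64).max)
    return result.graph.labels[int(np.argmin(first_t))]
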