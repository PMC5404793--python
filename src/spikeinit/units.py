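"""Unit conventions and conversions.

Internal unit system: mV, ms, pA, pF, nS, GOhm.  These are mutually
consistent: nS * mV = pA, pF * mV / ms = pA, GOhm = mV / pA, and pF / nS = ms.
Configuration files and constructors accept the units conventionally printed
in the electrophysiology literature (um, Ohm*cm, Ohm*cm^2, uF/cm^2, pS/um^2,
MOhm, nA) and convert on load through the helpers below.
"""

from __future__ import annotations

import math

# 1 uF/cm^2 = 1e6 pF / 1e8 um^2 = 0.01 pF/um^2
PF_PER_UM2_PER_UF_CM2 = 0.01

# 1 pS = 1e-3 nS
NS_PER_PS = 1e-3

# 1 MOhm = 1e-3 GOhm
GOHM_PER_MOHM = 1e-3


def capacitance_pf(area_um2: float, c_m_uf_cm2: float) -> float:
    """Membrane capacitance (pF) of a patch of given area (um^2)."""
    return area_um2 * c_m_uf_cm2 * PF_PER_UM2_PER_UF_CM2


def density_to_total_ns(density_ps_um2: float, area_um2: float) -> float:
    """Total conductance (nS) from a surface density (pS/um^2) and area (um^2)."""
    return density_ps_um2 * area_um2 * NS_PER_PS


def total_to_density_ps_um2(g_ns: float, area_um2: float) -> float:
    """Surface density (pS/um^2) equivalent to a total conductance (nS)."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return g_ns / area_um2 / NS_PER_PS


def leak_density_ps_um2(r_m_ohm_cm2: float) -> float:
    """Leak conductance density (pS/um^2) from a specific membrane resistance.

    1/R_m S/cm^2 = (1e12 / 1e8) / R_m pS/um^2 = 1e4 / R_m pS/um^2.
    """
    if r_m_ohm_cm2 <= 0:
        raise ValueError("R_m must be positive")
    return 1e4 / r_m_ohm_cm2


def cylinder_area_um2(length_um: float, diameter_um: float) -> float:
    """Lateral (side-wall) area of a cylinder; end caps are excluded.

    This matches the convention of compartmental simulators, so that
    density-to-total conversions printed alongside model parameters are
    reproducible.
    """
    return math.pi * diameter_um * length_um


def axial_resistance_gohm(
    r_i_ohm_cm: float, l1_um: float, d1_um: float, l2_um: float, d2_um: float
) -> float:
    """Center-to-center axial resistance (GOhm) of two adjoining half-cylinders.

    R = (4 R_i / pi) * (L1 / (2 d1^2) + L2 / (2 d2^2)), i.e. half of each
    segment's end-to-end resistance 4 R_i L / (pi d^2).  A zero-length side
    (L = 0) contributes nothing, which is how a large isopotential soma is
    joined to the first axonal segment.
    """
    if d1_um <= 0 or d2_um <= 0:
        raise ValueError("diameters must be positive")
    if l1_um < 0 or l2_um < 0 or r_i_ohm_cm <= 0:
        raise ValueError("lengths must be >= 0 and resistivity > 0")
    # R_i [Ohm*cm] * L [um] / d^2 [um^2] -> Ohm requires a factor 1e4
    # (1 Ohm*cm = 1e4 Ohm*um^2/um).
    r_ohm = (4.0 * r_i_ohm_cm / math.pi) * (
        l1_um / (2.0 * d1_um**2) + l2_um / (2.0 * d2_um**2)
    ) * 1e4
    return r_ohm * 1e-9


def mohm_to_gohm(r_mohm: float) -> float:
    return r_mohm * GOHM_PER_MOHM
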