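"""Spike-shape and current measurements.

Phase plots (dV/dt versus V), the two onset-rapidness measures (maximum
phase slope of the first phase-plot component, and phase slope at a fixed
dV/dt value), the tangent-based prediction of somatic rapidness from the
axonal phase plot, current-voltage discontinuity detection for clamp scans,
and the current-balance decomposition at the initiation site.

Numerical choices: dV/dt by centered differences on an optionally smoothed
trace (Savitzky-Golay, for noisy input); the phase-slope function s(V) =
d(dV/dt)/dV by moving least squares over a +-0.5 mV voltage window along the
upstroke.  Local maxima of s must exceed their surroundings by more than 1%
to count (guarding floating-point plateaus); ties resolve to the earlier
maximum.  Piecewise-linear phase plots whose slope jumps without an
intervening dip (no strict local maximum) are segmented at the jump, and the
pre-jump plateau is reported as the first component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .cable import SimResult

__all__ = [
    "PhasePlot",
    "IVCurve",
    "BalanceTraces",
    "phase_plot",
    "phase_slope_at",
    "onset_rapidness",
    "predict_onset_rapidness",
    "find_discontinuity",
    "current_balance",
    "open_fraction_vs_command",
    "spike_window",
]


# ---------------------------------------------------------------------------
# Phase plots
# ---------------------------------------------------------------------------


@dataclass
class PhasePlot:
    """The (V, dV/dt) trajectory of one spike.

    ``upstroke`` is the index slice from spike foot to voltage peak; slope
    analyses are restricted to it.  ``phase_slope()`` returns s(V) =
    d(dV/dt)/dV (1/ms) per upstroke sample, estimated by moving least
    squares over ``slope_window_mv``.
    """

    t: np.ndarray
    v: np.ndarray
    dvdt: np.ndarray
    upstroke: slice
    slope_window_mv: float = 0.5
    _slope_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def upstroke_v(self) -> np.ndarray:
        return self.v[self.upstroke]

    @property
    def upstroke_dvdt(self) -> np.ndarray:
        return self.dvdt[self.upstroke]

    def phase_slope(self) -> np.ndarray:
        if self._slope_cache is None:
            self._slope_cache = _moving_ls_slope(
                self.upstroke_v, self.upstroke_dvdt, self.slope_window_mv)
        return self._slope_cache


def _moving_ls_slope(v: np.ndarray, y: np.ndarray, window: float) -> np.ndarray:
    """Least-squares slope dy/dv around every sample, using all samples whose
    v lies within +-window of the center.  NaN where fewer than 2 usable
    samples or degenerate spread."""
    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order]
    n = len(vs)
    lo = np.searchsorted(vs, vs - window, side="left")
    hi = np.searchsorted(vs, vs + window, side="right")
    z = np.zeros(1)
    c1 = np.concatenate([z, np.cumsum(np.ones(n))])
    cx = np.concatenate([z, np.cumsum(vs)])
    cy = np.concatenate([z, np.cumsum(ys)])
    cxx = np.concatenate([z, np.cumsum(vs * vs)])
    cxy = np.concatenate([z, np.cumsum(vs * ys)])
    cnt = c1[hi] - c1[lo]
    sx = cx[hi] - cx[lo]
    sy = cy[hi] - cy[lo]
    sxx = cxx[hi] - cxx[lo]
    sxy = cxy[hi] - cxy[lo]
    denom = cnt * sxx - sx * sx
    scale = np.maximum(sxx, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope_sorted = np.where(
            (cnt >= 3) & (denom > 1e-12 * scale),
            (cnt * sxy - sx * sy) / denom,
            np.nan,
        )
    # where the trajectory is faster than the sampling (fewer than 3 samples
    # per window) fall back to a neighbor difference
    if n >= 3:
        nb = np.full(n, np.nan)
        dv = vs[2:] - vs[:-2]
        with np.errstate(divide="ignore", invalid="ignore"):
            nb[1:-1] = np.where(np.abs(dv) > 1e-12, (ys[2:] - ys[:-2]) / dv,
                                np.nan)
        slope_sorted = np.where(np.isnan(slope_sorted), nb, slope_sorted)
    out = np.empty(n)
    out[order] = slope_sorted
    return out


def phase_plot(t: np.ndarray, v: np.ndarray, window=None,
               smooth_window: int | None = None,
               slope_window_mv: float = 0.5) -> PhasePlot:
    """Build a phase plot from a uniformly sampled voltage trace.

    ``window = (t0, t1)`` restricts to one spike; ``smooth_window`` (odd
    sample count) applies a Savitzky-Golay local-cubic smoother before
    differentiating -- recommended for noisy recordings, unnecessary for
    noise-free simulation.  dV/dt is computed by centered differences; the
    same differentiation feeds the phase-slope estimate.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("t and v must be 1-D arrays of equal length")
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("time grid must be uniform")
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, v = t[sel], v[sel]
    if smooth_window is not None and smooth_window >= 5:
        v = savgol_filter(v, smooth_window, 3)
    dvdt = np.gradient(v, t)
    peak = int(np.argmax(v))
    below = np.nonzero(dvdt[:peak] <= 0)[0]
    start = int(below[-1]) + 1 if len(below) else 0
    start = min(start, peak)
    return PhasePlot(t=t, v=v, dvdt=dvdt, upstroke=slice(start, peak + 1),
                     slope_window_mv=slope_window_mv)


# ---------------------------------------------------------------------------
# Onset rapidness
# ---------------------------------------------------------------------------


def _first_component(s: np.ndarray, v: np.ndarray,
                     prominence_frac: float = 0.01,
                     jump_factor: float = 1.3,
                     window_mv: float = 0.5):
    """Segment the phase-slope profile into components.

    Returns (value, info) where value is the maximum slope of the first
    component.  Components are delimited by strict local maxima of s
    (prominence > ``prominence_frac`` of the global maximum), or -- for
    piecewise-linear plots with no intervening dip -- by an abrupt jump of s
    (factor > ``jump_factor``) that is resolved over no more than a few
    samples / estimator windows of voltage.
    """
    ok = np.isfinite(s)
    s_f, v_f = s[ok], v[ok]
    if len(s_f) < 3:
        raise ValueError("too few phase-slope samples on the upstroke")
    smax = float(np.max(s_f))
    peaks, _ = find_peaks(s_f, prominence=prominence_frac * abs(smax))
    peaks = peaks[s_f[peaks] > 0]  # a maximum of rapidness must be a rise

    info = {"n_components": 1, "monotone": False,
            "peak_slopes": s_f[peaks].tolist(),
            "peak_voltages": v_f[peaks].tolist(), "boundary_v": None}

    if len(peaks) >= 2:
        info["n_components"] = len(peaks)
        seg = s_f[peaks[0]: peaks[1] + 1]
        info["boundary_v"] = float(v_f[peaks[0] + int(np.argmin(seg))])
        return float(s_f[peaks[0]]), info

    # jump (kink) segmentation for plateau-then-rise profiles
    limit = int(peaks[0]) + 1 if len(peaks) == 1 else len(s_f)
    ds = np.diff(s_f[:limit])
    if len(ds) >= 3:
        b = int(np.argmax(ds))
        if 2 <= b < limit - 2:
            # plateau value taken clear of the transition: the moving
            # least-squares window smears the kink over +-window_mv
            clear = np.nonzero(v_f[:b + 1] <= v_f[b] - 2.0 * window_mv)[0]
            s_before = float(np.max(s_f[clear])) if len(clear) else float(s_f[0])
            after = s_f[b + 1: limit]
            s_after = float(np.max(after))
            if s_after > jump_factor * s_before and s_before > 0:
                a = b + 1 + int(np.argmax(after >= 0.9 * s_after))
                # a genuine kink resolves within a few samples or smoothing
                # windows, however coarsely the upstroke is sampled
                dv_local = float(np.median(np.diff(v_f[max(b - 2, 0): a + 3])))
                span_limit = max(2.0 * window_mv, 4.0 * dv_local)
                if v_f[a] - v_f[b] <= span_limit:
                    info["n_components"] = 2
                    info["boundary_v"] = float(v_f[b])
                    return s_before, info

    if len(peaks) == 1:
        return float(s_f[peaks[0]]), info
    info["monotone"] = True
    return smax, info


def onset_rapidness(pp: PhasePlot, min_dvdt: float = 0.5,
                    return_details: bool = False):
    """Onset rapidness (1/ms): the maximum phase slope of the first
    component of the phase plot.

    Monophasic plots yield their single maximum; biphasic plots (somatic
    spike regeneration) the earlier, lower-voltage maximum.  When s(V) is
    monotone (no local maximum) the supremum is returned and flagged in the
    details.  ``min_dvdt`` excludes the subthreshold foot of the upstroke.
    """
    s = pp.phase_slope()
    du = pp.upstroke_dvdt
    mask = du >= min_dvdt
    if not mask.any():
        raise ValueError("upstroke never exceeds min_dvdt")
    value, info = _first_component(s[mask], pp.upstroke_v[mask],
                                   window_mv=pp.slope_window_mv)
    if return_details:
        return value, info
    return value


def phase_slope_at(pp: PhasePlot, dvdt_value: float) -> float:
    """Phase slope (1/ms) at a fixed dV/dt value: the local least-squares
    slope around the first upward crossing of ``dvdt_value`` on the
    upstroke."""
    vu, du = pp.upstroke_v, pp.upstroke_dvdt
    cross = np.nonzero((du[1:] >= dvdt_value) & (du[:-1] < dvdt_value))[0]
    if du[0] >= dvdt_value:
        i = 0
        v_star = vu[0]
    elif len(cross) == 0:
        raise ValueError(f"dV/dt never crosses {dvdt_value} mV/ms upward")
    else:
        i = int(cross[0]) + 1
        frac = (dvdt_value - du[i - 1]) / (du[i] - du[i - 1])
        v_star = vu[i - 1] + frac * (vu[i] - vu[i - 1])
    w = pp.slope_window_mv
    sel = np.abs(vu - v_star) <= w
    if sel.sum() < 2:
        sel = np.zeros_like(sel)
        sel[max(i - 2, 0): i + 3] = True
    x, y = vu[sel], du[sel]
    denom = len(x) * np.sum(x * x) - np.sum(x) ** 2
    return float((len(x) * np.sum(x * y) - np.sum(x) * np.sum(y)) / denom)


def predict_onset_rapidness(pp_axonal: PhasePlot, v_threshold: float) -> float:
    """Predicted somatic onset rapidness (1/ms) from the axonal phase plot.

    If the somatic current at spike initiation is the resistive axonal
    current I = (Va - V) / Ra and V sits at threshold, the somatic phase
    slope equals (dVa/dt) / (Va - V_threshold).  Geometrically, its maximum
    is the slope of the steepest tangent from (V_threshold, 0) to the axonal
    phase plot.

    The ratio diverges spuriously as Va -> V_threshold (low on the upstroke)
    and falls to zero at the voltage peak, so the tangency is identified as
    the largest *interior* local maximum of the ratio along the trajectory;
    when the ratio has no interior maximum (e.g. it is constant, as for an
    exponential trajectory starting at threshold) the final sample is used.
    """
    va, dva = pp_axonal.upstroke_v, pp_axonal.upstroke_dvdt
    sel = (va > v_threshold + 1e-9) & (dva > 0)
    if not sel.any():
        raise ValueError("axonal upstroke never exceeds the threshold")
    ratio = dva[sel] / (va[sel] - v_threshold)
    peaks, _ = find_peaks(ratio)
    if len(peaks):
        return float(np.max(ratio[peaks]))
    return float(ratio[-1])


# ---------------------------------------------------------------------------
# Current-voltage curves
# ---------------------------------------------------------------------------


@dataclass
class IVCurve:
    """Peak clamp current (nA) versus command voltage (mV), optionally
    annotated with the voltage and size of a discontinuous jump."""

    voltages: np.ndarray
    peak_currents: np.ndarray
    discontinuity_voltage: float | None = None
    jump_na: float | None = None

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.peak_currents = np.asarray(self.peak_currents, dtype=float)
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("command voltages must be strictly increasing")

    @classmethod
    def from_clamp(cls, clamp_result) -> "IVCurve":
        return cls(voltages=clamp_result.commands,
                   peak_currents=clamp_result.peak_currents())

    def annotate_discontinuity(self, jump_threshold: float = 1.0) -> "IVCurve":
        v = find_discontinuity(self, jump_threshold=jump_threshold)
        self.discontinuity_voltage = v
        if v is not None:
            i = int(np.searchsorted(self.voltages, v))
            self.jump_na = float(abs(self.peak_currents[i]
                                     - self.peak_currents[i - 1]))
        return self


def find_discontinuity(iv: IVCurve, jump_threshold: float = 1.0) -> float | None:
    """Smallest command voltage at which the peak current jumps by more than
    ``jump_threshold`` (nA) between consecutive commands; the midpoint of the
    bracketing pair is returned, or None when the curve is graded.

    Requires a uniform voltage step (default scans use 0.5 mV).
    """
    if len(iv.voltages) < 2:
        raise ValueError("need at least two commands")
    steps = np.diff(iv.voltages)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("command voltages must be uniformly spaced")
    jumps = np.abs(np.diff(iv.peak_currents))
    idx = np.nonzero(jumps > jump_threshold)[0]
    if len(idx) == 0:
        return None
    i = int(idx[0])
    return float(0.5 * (iv.voltages[i] + iv.voltages[i + 1]))


# ---------------------------------------------------------------------------
# Current balance at the initiation site
# ---------------------------------------------------------------------------


@dataclass
class BalanceTraces:
    """Aligned current traces (pA, depolarizing-positive) at the AIS:
    Na and K summed over the AIS membrane, and the net axial current
    received by the AIS (negative when current drains to the soma)."""

    t: np.ndarray
    i_na: np.ndarray
    i_k: np.ndarray
    i_axial: np.ndarray


def current_balance(result: SimResult, ais_segments=None) -> BalanceTraces:
    """Decompose the currents over an axonal segment range.

    ``ais_segments = (first, last)`` are 0-based axon-relative indices
    (inclusive); default is the whole axon.  The axial trace is the summed
    boundary-link current flowing into the range, so during the spike
    upstroke it is the (negative) resistive current draining to the soma.
    """
    graph = result.graph
    if "axon" not in graph.sections:
        raise ValueError("model has no axon")
    a0, a1 = graph.sections["axon"]
    if ais_segments is None:
        start, stop = a0, a1
    else:
        first, last = ais_segments
        start, stop = a0 + int(first), a0 + int(last) + 1
        if not (a0 <= start < stop <= a1):
            raise ValueError("segment range outside the axon")
    i_na = result.i_na()[:, start:stop].sum(axis=1)
    i_k = result.i_k()[:, start:stop].sum(axis=1)
    j = result.axial_link_currents()
    i_axial = -j[:, start]  # into the range across its proximal boundary
    if stop < graph.n:
        i_axial = i_axial + j[:, stop]
    return BalanceTraces(t=result.t, i_na=i_na, i_k=i_k, i_axial=i_axial)


def open_fraction_vs_command(clamp_result, measure: str = "activation"):
    """Peak open Na fraction at the distal axonal end versus command
    voltage, from a voltage-clamp scan with gate recording."""
    return (clamp_result.commands,
            clamp_result.peak_open_fractions(measure=measure))


def spike_window(t: np.ndarray, v: np.ndarray, criterion: float = 5.0,
                 pre: float = 1.0, post: float = 8.0) -> tuple[float, float]:
    """Convenience window (t0, t1) around the first spike: from ``pre`` ms
    before the first upward dV/dt-criterion crossing to ``post`` ms after."""
    dvdt = np.gradient(np.asarray(v, float), np.asarray(t, float))
    above = np.nonzero(dvdt >= criterion)[0]
    if len(above) == 0:
        raise ValueError("no spike in trace")
    t_on = float(t[above[0]])
    return max(t_on - pre, float(t[0])), min(t_on + post, float(t[-1]))
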