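"""Time-stepping cores.

The cable integrator advances a path-ordered compartment chain with an
implicit theta scheme (theta = 0.5 is Crank-Nicolson, theta = 1 backward
Euler) on the voltage, and exact exponential relaxation of the gating
variables at the start-of-step voltage (operator splitting).  The linear
system per step is tridiagonal and solved with the Thomas algorithm.

A separate, algebraically explicit two-unknown core integrates the
two-compartment soma-AIS model with closed-form Boltzmann gate updates; it
shares no code with the cable core and serves as an independent route for
cross-checks.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def _interp(table: np.ndarray, v: float, v0: float, dv: float) -> float:
    pos = (v - v0) / dv
    n = table.shape[0]
    if pos <= 0.0:
        return table[0]
    if pos >= n - 1:
        return table[n - 1]
    j = int(pos)
    frac = pos - j
    return table[j] + (table[j + 1] - table[j]) * frac


@njit(cache=False)
def _ipow(x: float, p: int) -> float:
    out = 1.0
    for _ in range(p):
        out *= x
    return out


@njit(cache=False)
def cable_loop(
    v: np.ndarray, m: np.ndarray, h: np.ndarray, n: np.ndarray,
    cap: np.ndarray, g_na: np.ndarray, g_k: np.ndarray, g_leak: np.ndarray,
    e_na: float, e_k: float, e_leak: float,
    pm: int, ph: int, pn: int,
    v0g: float, dvg: float,
    minf: np.ndarray, mtau: np.ndarray,
    hinf: np.ndarray, htau: np.ndarray,
    ninf: np.ndarray, ntau: np.ndarray,
    g_ax: np.ndarray,          # (N,); g_ax[i] couples i-1 and i; g_ax[0] unused
    i_stim: np.ndarray,        # (nsteps+1,)
    stim_idx: int,
    g_clamp: float,            # 0.0 disables the clamp branch
    v_cmd: np.ndarray,         # (nsteps+1,) command potential, ignored if g_clamp==0
    clamp_idx: int,
    dt: float, nsteps: int, stride: int, theta: float,
    rec_v: np.ndarray, rec_m: np.ndarray, rec_h: np.ndarray, rec_n: np.ndarray,
) -> int:
    """Advance ``nsteps`` steps, recording every ``stride`` steps.

    Returns the step index at which a non-finite voltage was first produced,
    or -1 on success.  Recording buffers are (nrec, N) with the initial state
    in row 0.
    """
    ncomp = v.shape[0]
    diag = np.empty(ncomp)
    off = np.empty(ncomp)     # off[i] couples i-1 and i (sub == super)
    rhs = np.empty(ncomp)
    cprime = np.empty(ncomp)

    rec_v[0, :] = v
    rec_m[0, :] = m
    rec_h[0, :] = h
    rec_n[0, :] = n
    row = 1

    for k in range(nsteps):
        # 1) exact exponential gate relaxation at V^k
        for i in range(ncomp):
            vi = v[i]
            xm = _interp(minf, vi, v0g, dvg)
            tm = _interp(mtau, vi, v0g, dvg)
            m[i] = xm + (m[i] - xm) * math.exp(-dt / tm)
            xh = _interp(hinf, vi, v0g, dvg)
            th = _interp(htau, vi, v0g, dvg)
            h[i] = xh + (h[i] - xh) * math.exp(-dt / th)
            xn = _interp(ninf, vi, v0g, dvg)
            tn = _interp(ntau, vi, v0g, dvg)
            n[i] = xn + (n[i] - xn) * math.exp(-dt / tn)

        # 2) assemble the tridiagonal theta-scheme system
        for i in range(ncomp):
            gna = g_na[i] * _ipow(m[i], pm) * _ipow(h[i], ph)
            gk = g_k[i] * _ipow(n[i], pn)
            gm = gna + gk + g_leak[i]
            const = gna * e_na + gk * e_k + g_leak[i] * e_leak
            if i == stim_idx:
                const += theta * i_stim[k + 1] + (1.0 - theta) * i_stim[k]
            if g_clamp > 0.0 and i == clamp_idx:
                gm += g_clamp
                const += g_clamp * (theta * v_cmd[k + 1] + (1.0 - theta) * v_cmd[k])
            g_lo = g_ax[i] if i > 0 else 0.0
            g_hi = g_ax[i + 1] if i + 1 < ncomp else 0.0
            diag[i] = cap[i] / dt + theta * (gm + g_lo + g_hi)
            off[i] = -theta * g_lo
            r = (cap[i] / dt - (1.0 - theta) * (gm + g_lo + g_hi)) * v[i] + const
            if i > 0:
                r += (1.0 - theta) * g_lo * v[i - 1]
            if i + 1 < ncomp:
                r += (1.0 - theta) * g_hi * v[i + 1]
            rhs[i] = r

        # 3) Thomas solve (sub- and super-diagonal are both off[i])
        cprime[0] = off[1] / diag[0] if ncomp > 1 else 0.0
        rhs[0] = rhs[0] / diag[0]
        for i in range(1, ncomp):
            denom = diag[i] - off[i] * cprime[i - 1]
            if i + 1 < ncomp:
                cprime[i] = off[i + 1] / denom
            rhs[i] = (rhs[i] - off[i] * rhs[i - 1]) / denom
        v[ncomp - 1] = rhs[ncomp - 1]
        for i in range(ncomp - 2, -1, -1):
            v[i] = rhs[i] - cprime[i] * v[i + 1]

        for i in range(ncomp):
            if not math.isfinite(v[i]):
                return k
        if (k + 1) % stride == 0:
            rec_v[row, :] = v
            rec_m[row, :] = m
            rec_h[row, :] = h
            rec_n[row, :] = n
            row += 1
    return -1


@njit(cache=False)
def _boltz(v: float, vh: float, k: float) -> float:
    x = -(v - vh) / k
    if x >= 0.0:
        e = math.exp(-x)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(x))


@njit(cache=False)
def two_compartment_loop(
    vs0: float, va0: float,
    ms0: float, hs0: float, ns0: float,
    ma0: float, ha0: float, na0: float,
    c_s: float, c_a: float, g_ra: float,
    gl_s: float, gl_a: float, e_leak: float,
    gna_s: float, gna_a: float, e_na: float,
    gk_s: float, gk_a: float, e_k: float,
    m_vh: float, m_k: float, m_tau: float,
    h_vh: float, h_k: float, h_tau: float,
    n_vh: float, n_k: float, n_tau: float,
    i_stim: np.ndarray, stim_on_soma: int,
    dt: float, nsteps: int, stride: int, theta: float,
    rec: np.ndarray,  # (nrec, 8): Vs, Va, ms, hs, ns, ma, ha, na
) -> int:
    vs, va = vs0, va0
    ms, hs, ns_, ma, ha, na_ = ms0, hs0, ns0, ma0, ha0, na0
    fm = math.exp(-dt / m_tau)
    fh = math.exp(-dt / h_tau)
    fn = math.exp(-dt / n_tau)

    rec[0, 0] = vs; rec[0, 1] = va
    rec[0, 2] = ms; rec[0, 3] = hs; rec[0, 4] = ns_
    rec[0, 5] = ma; rec[0, 6] = ha; rec[0, 7] = na_
    row = 1

    for k in range(nsteps):
        ms = _boltz(vs, m_vh, m_k) + (ms - _boltz(vs, m_vh, m_k)) * fm
        hs = _boltz(vs, h_vh, h_k) + (hs - _boltz(vs, h_vh, h_k)) * fh
        ns_ = _boltz(vs, n_vh, n_k) + (ns_ - _boltz(vs, n_vh, n_k)) * fn
        ma = _boltz(va, m_vh, m_k) + (ma - _boltz(va, m_vh, m_k)) * fm
        ha = _boltz(va, h_vh, h_k) + (ha - _boltz(va, h_vh, h_k)) * fh
        na_ = _boltz(va, n_vh, n_k) + (na_ - _boltz(va, n_vh, n_k)) * fn

        gns = gna_s * ms * hs
        gks = gk_s * ns_
        gna = gna_a * ma * ha
        gka = gk_a * na_
        gs = gns + gks + gl_s
        ga = gna + gka + gl_a
        # constant (voltage-independent) parts
        const_s = gns * e_na + gks * e_k + gl_s * e_leak
        const_a = gna * e_na + gka * e_k + gl_a * e_leak
        if stim_on_soma == 1:
            const_s += theta * i_stim[k + 1] + (1.0 - theta) * i_stim[k]
        else:
            const_a += theta * i_stim[k + 1] + (1.0 - theta) * i_stim[k]

        a11 = c_s / dt + theta * (gs + g_ra)
        a22 = c_a / dt + theta * (ga + g_ra)
        a12 = -theta * g_ra
        b1 = (c_s / dt - (1.0 - theta) * (gs + g_ra)) * vs \
            + (1.0 - theta) * g_ra * va + const_s
        b2 = (c_a / dt - (1.0 - theta) * (ga + g_ra)) * va \
            + (1.0 - theta) * g_ra * vs + const_a
        det = a11 * a22 - a12 * a12
        vs = (b1 * a22 - a12 * b2) / det
        va = (a11 * b2 - a12 * b1) / det

        if not (math.isfinite(vs) and math.isfinite(va)):
            return k
        if (k + 1) % stride == 0:
            rec[row, 0] = vs; rec[row, 1] = va
            rec[row, 2] = ms; rec[row, 3] = hs; rec[row, 4] = ns_
            rec[row, 5] = ma; rec[row, 6] = ha; rec[row, 7] = na_
            row += 1
    return -1
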