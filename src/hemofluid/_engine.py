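"""Compiled fixed-step integration kernels.

These kernels exist for throughput: calibration and cohort assessment run
tens of thousands of forward simulations, so the right-hand side and the
fixed-step integrators (RK4 / explicit Euler) are JIT-compiled with numba.
The readable reference implementation of the same equations lives in
:mod:`hemofluid.model`; the two are cross-checked in the test suite.

State layout (index -> variable):
  0 r_U,BV   reference BV change due to infusion (l)
  1 r_V,BV   reference BV change due to loss (l)
  2 BV       blood volume (l)
  3 RBC      red-cell content, HCT-weighted volume (%.l)
  4 r_HV,L   reference long-term HR change (bpm)
  5 H_V,T    transient HR rise from loss (bpm)
  6 H_V,L    long-term HR rise from loss (bpm)
  7 e_int    integral of the HR controller error (bpm.min)
  8 H_U,T    transient HR drop from infusion (bpm)
  9 SV       stroke volume (l)
 10 TPR      total peripheral resistance (mmHg.min/l)

Parameter vector: the 25 values in ``parameters.PARAM_NAMES`` order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_STATES = 11

# status codes
OK = 0
NONFINITE = 1
BV_EXHAUSTED = 2


@njit(cache=True)
def _rhs(y, U, V, th, c_svhr, dy):
    """Time-derivative of the 11 states under constant inputs U, V."""
    rU, rV, bv, rbc = y[0], y[1], y[2], y[3]
    rhvl, hvt, hvl, eint, hut = y[4], y[5], y[6], y[7], y[8]
    sv, tpr = y[9], y[10]

    d_rU = th[0] * rU + U / (1.0 + th[2])
    d_rV = th[1] * rV - V / (1.0 + th[3])
    q = th[4] * (bv - th[21] - (rU + rV))
    d_bv = U - V - q
    hct = rbc / bv
    d_rbc = -V * hct
    # perturbation power terms vanish at rest (0**p := 0, any p >= 0)
    d_rhvl = th[7] * V ** th[9] if V > 0.0 else 0.0
    d_hvt = th[6] * V
    e = rhvl - hvt - hvl
    d_hvl = th[10] * e + th[11] * eint
    d_hut = th[5] * U ** th[8] if U > 0.0 else 0.0
    d_H = d_hvl + d_hvt - d_hut
    d_sv = th[14] * (sv - th[23]) + th[12] * d_bv + th[16] * (th[15] - sv) + c_svhr * th[13] * d_H
    H = th[22] + hvt + hvl - hut
    bp = H * sv * tpr
    d_tpr = th[17] * (tpr - th[24]) + th[18] * (th[19] - bp)

    dy[0] = d_rU
    dy[1] = d_rV
    dy[2] = d_bv
    dy[3] = d_rbc
    dy[4] = d_rhvl
    dy[5] = d_hvt
    dy[6] = d_hvl
    dy[7] = e
    dy[8] = d_hut
    dy[9] = d_sv
    dy[10] = d_tpr


@njit(cache=True)
def _step_segment(y, t0, t1, U, V, th, c_svhr, dt, order, k1, k2, k3, k4, ytmp):
    """Advance y in place from t0 to t1 under constant inputs. Returns status."""
    length = t1 - t0
    n = int(np.ceil(length / dt - 1e-12))
    if n < 1:
        n = 1
    h = length / n
    for _ in range(n):
        if order == 1:
            _rhs(y, U, V, th, c_svhr, k1)
            for j in range(N_STATES):
                y[j] = y[j] + h * k1[j]
        else:
            _rhs(y, U, V, th, c_svhr, k1)
            for j in range(N_STATES):
                ytmp[j] = y[j] + 0.5 * h * k1[j]
            _rhs(ytmp, U, V, th, c_svhr, k2)
            for j in range(N_STATES):
                ytmp[j] = y[j] + 0.5 * h * k2[j]
            _rhs(ytmp, U, V, th, c_svhr, k3)
            for j in range(N_STATES):
                ytmp[j] = y[j] + h * k3[j]
            _rhs(ytmp, U, V, th, c_svhr, k4)
            for j in range(N_STATES):
                y[j] = y[j] + (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        bv = y[2]
        if bv <= 0.0:
            return BV_EXHAUSTED
        if bv != bv:
            return NONFINITE
    for j in range(N_STATES):
        if not np.isfinite(y[j]):
            return NONFINITE
    return OK


@njit(cache=True)
def integrate(th, y0, t_grid, breaks, u_vals, v_vals, dt, order, c_svhr):
    """Fixed-step integration of one subject over ``t_grid``.

    ``breaks``/``u_vals``/``v_vals`` define piecewise-constant inputs on
    ``[breaks[i], breaks[i+1])``; the final entry must extend past the grid.
    Steps never cross an input breakpoint. Returns (states, status, n_valid)
    where states has shape (len(t_grid), 11) and rows >= n_valid are filled
    with NaN when the integration fails early.
    """
    T = t_grid.shape[0]
    out = np.empty((T, N_STATES))
    y = y0.copy()
    k1 = np.empty(N_STATES)
    k2 = np.empty(N_STATES)
    k3 = np.empty(N_STATES)
    k4 = np.empty(N_STATES)
    ytmp = np.empty(N_STATES)
    out[0] = y
    status = OK
    n_valid = T
    for k in range(1, T):
        a = t_grid[k - 1]
        b = t_grid[k]
        t = a
        while t < b - 1e-12:
            i = np.searchsorted(breaks, t, side="right") - 1
            seg_end = b
            if i + 1 < breaks.shape[0] and breaks[i + 1] < seg_end:
                seg_end = breaks[i + 1]
            status = _step_segment(y, t, seg_end, u_vals[i], v_vals[i], th, c_svhr, dt, order, k1, k2, k3, k4, ytmp)
            if status != OK:
                break
            t = seg_end
        if status != OK:
            n_valid = k
            for kk in range(k, T):
                for j in range(N_STATES):
                    out[kk, j] = np.nan
            break
        out[k] = y
    return out, status, n_valid


@njit(cache=True)
def outputs_from_states(states, th):
    """Map state trajectories to (BV, HCT, HR, SV, CO, BP), shape (T, 6)."""
    T = states.shape[0]
    out = np.empty((T, 6))
    for k in range(T):
        bv = states[k, 2]
        hct = states[k, 3] / bv
        hr = th[22] + states[k, 5] + states[k, 6] - states[k, 8]
        sv = states[k, 9]
        co = hr * sv
        bp = co * states[k, 10]
        out[k, 0] = bv
        out[k, 1] = hct
        out[k, 2] = hr
        out[k, 3] = sv
        out[k, 4] = co
        out[k, 5] = bp
    return out


@njit(cache=True)
def integrate_cohort(thetas, t_grid, breaks, u_vals, v_vals, dt, order, c_svhr):
    """Simulate every parameter row; returns outputs (n, T, 6) and status (n,)."""
    n = thetas.shape[0]
    T = t_grid.shape[0]
    outs = np.empty((n, T, 6))
    status = np.empty(n, dtype=np.int64)
    y0 = np.empty(N_STATES)
    for s in range(n):
        th = thetas[s]
        for j in range(N_STATES):
            y0[j] = 0.0
        y0[2] = th[21]            # BV0
        y0[3] = th[20] * th[21]   # RBC(0) = HCT0 * BV0
        y0[9] = th[23]            # SV0
        y0[10] = th[24]           # TPR0
        states, st, _ = integrate(th, y0, t_grid, breaks, u_vals, v_vals, dt, order, c_svhr)
        status[s] = st
        outs[s] = outputs_from_states(states, th)
    return outs, status
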