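"""Integrated cardiovascular response model and its numerical simulation.

The model tracks the response of blood volume (BV), hematocrit (HCT), heart
rate (HR), stroke volume (SV), cardiac output (CO) and blood pressure (BP)
to fluid perturbation, i.e. an infusion rate ``U(t)`` and a loss rate
``V(t)`` (hemorrhage plus urine), both in l/min.

Four coupled sub-models drive eleven states:

* **Blood volume** — a two-compartment fluid-shift description: first-order
  references ``r_U,BV`` and ``r_V,BV`` define the target change in BV under
  infusion and loss (distribution ratios ``alpha_U``, ``alpha_V``); a
  proportional controller with gain ``K_P_BV`` shifts fluid between the
  intravascular and interstitial spaces so that BV tracks ``BV0 + r_BV``.
  Red-cell content is depleted by hemorrhage only, ``dRBC/dt = -V*HCT``, and
  ``HCT = RBC/BV``.
* **Heart rate** — loss raises HR transiently through gain ``G_V_T`` and in
  the long term through a PI controller (gains ``K_P_H``, ``K_I_H``)
  tracking the reference ``r_HV,L = \\int G_V_L V^{P_V_L}``; infusion lowers
  HR through ``G_U_T U^{P_U_T}``. HR itself is the algebraic sum
  ``H0 + H_V,T + H_V,L - H_U,T``.
* **Stroke volume** — SV relaxes at rate ``A_SV``, follows BV through gain
  ``G_BV``, is regulated toward a reference ``r_SV`` with gain ``K_P_SV``,
  and falls when HR rises (Frank-Starling filling-time effect) with gain
  ``G_HR``.
* **Blood pressure** — a control-oriented total-peripheral-resistance (TPR)
  state: TPR relaxes at rate ``A_BP`` and is adjusted with gain ``K_P_BP``
  to drive ``BP = HR*SV*TPR`` toward the reference ``r_BP``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _engine
from .parameters import SubjectParameters
from .protocol import FluidProtocol

__all__ = [
    "OUTPUT_NAMES",
    "StateVector",
    "SolverConfig",
    "SimulationResult",
    "initial_state",
    "derivatives",
    "derived_outputs",
    "simulate",
    "simulate_outputs",
    "simulate_cohort",
    "equilibrium_tpr",
]

#: Output variables, in trajectory-column order.
OUTPUT_NAMES: tuple[str, ...] = ("bv", "hct", "hr", "sv", "co", "bp")

_STATE_FIELDS = (
    "r_U_bv", "r_V_bv", "bv", "rbc", "r_hv_l", "h_v_t",
    "h_v_l", "e_int", "h_u_t", "sv", "tpr",
)


@dataclass(frozen=True)
class StateVector:
    """The 11 model states (see :mod:`hemofluid._engine` for the layout)."""

    r_U_bv: float   # reference BV change due to infusion (l)
    r_V_bv: float   # reference BV change due to loss (l)
    bv: float       # blood volume (l)
    rbc: float      # red-cell content (%.l)
    r_hv_l: float   # reference long-term HR change (bpm)
    h_v_t: float    # transient HR rise from loss (bpm)
    h_v_l: float    # long-term HR rise from loss (bpm)
    e_int: float    # HR-controller error integral (bpm.min)
    h_u_t: float    # transient HR drop from infusion (bpm)
    sv: float       # stroke volume (l)
    tpr: float      # total peripheral resistance (mmHg.min/l)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "StateVector":
        values = list(values)
        if len(values) != len(_STATE_FIELDS):
            raise ValueError(f"expected {len(_STATE_FIELDS)} state values")
        return cls(**dict(zip(_STATE_FIELDS, map(float, values))))


@dataclass(frozen=True)
class SolverConfig:
    """Numerical integration settings.

    ``method`` is one of ``"rk45"`` (adaptive, restarted at protocol
    breakpoints, max step 0.5 min), ``"rk4"`` (compiled fixed-step, default
    step ``dt``) or ``"euler"`` (compiled fixed-step first order).
    ``sv_hr_sign`` is the coefficient of ``G_HR * dH/dt`` in the SV
    equation: -1 (default) makes a rising heart rate depress stroke volume,
    the physiological Frank-Starling direction; +1 gives the literal
    double-negation reading of the printed equations.
    """

    method: str = "rk45"
    dt: float = 0.05            # fixed-step size (min) for rk4/euler
    max_step: float = 0.5       # adaptive max step (min)
    rtol: float = 1e-8
    atol: float = 1e-10
    sv_hr_sign: float = -1.0

    def __post_init__(self) -> None:
        if self.method not in ("rk45", "rk4", "euler"):
            raise ValueError(f"unknown solver method {self.method!r}")
        if self.dt <= 0 or self.max_step <= 0:
            raise ValueError("steps must be positive")
        if self.sv_hr_sign not in (-1.0, 1.0):
            raise ValueError("sv_hr_sign must be -1 or +1")


def initial_state(params: SubjectParameters) -> StateVector:
    """Baseline-consistent initial condition: references and HR offsets are
    zero, BV at BV0, RBC at HCT0*BV0, SV at SV0, TPR at TPR0."""
    return StateVector(
        r_U_bv=0.0, r_V_bv=0.0, bv=params.BV0, rbc=params.HCT0 * params.BV0,
        r_hv_l=0.0, h_v_t=0.0, h_v_l=0.0, e_int=0.0, h_u_t=0.0,
        sv=params.SV0, tpr=params.TPR0,
    )


def _rhs_array(y: np.ndarray, U: float, V: float, th: np.ndarray, c_svhr: float) -> np.ndarray:
    """Reference (pure Python) right-hand side on a state array."""
    rU, rV, bv, rbc, rhvl, hvt, hvl, eint, hut, sv, tpr = y
    if bv <= 0:
        raise FloatingPointError("blood volume exhausted")
    d_rU = th[0] * rU + U / (1.0 + th[2])
    d_rV = th[1] * rV - V / (1.0 + th[3])
    q = th[4] * (bv - th[21] - (rU + rV))
    d_bv = U - V - q
    d_rbc = -V * (rbc / bv)
    d_rhvl = th[7] * V ** th[9] if V > 0 else 0.0
    d_hvt = th[6] * V
    e = rhvl - hvt - hvl
    d_hvl = th[10] * e + th[11] * eint
    d_hut = th[5] * U ** th[8] if U > 0 else 0.0
    d_H = d_hvl + d_hvt - d_hut
    d_sv = th[14] * (sv - th[23]) + th[12] * d_bv + th[16] * (th[15] - sv) + c_svhr * th[13] * d_H
    H = th[22] + hvt + hvl - hut
    d_tpr = th[17] * (tpr - th[24]) + th[18] * (th[19] - H * sv * tpr)
    return np.array([d_rU, d_rV, d_bv, d_rbc, d_rhvl, d_hvt, d_hvl, e, d_hut, d_sv, d_tpr])


def derivatives(
    state: StateVector,
    t: float,
    params: SubjectParameters,
    protocol: FluidProtocol,
    sv_hr_sign: float = -1.0,
) -> StateVector:
    """Time-derivative of the state under the protocol's inputs at time t."""
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("numerical divergence: non-finite state")
    if state.bv <= 0:
        raise ValueError("blood volume exhausted")
    U, V = protocol.rates_at(t)
    return StateVector.from_array(_rhs_array(y, U, V, params.to_array(), sv_hr_sign))


def derived_outputs(state: StateVector, params: SubjectParameters) -> dict[str, float]:
    """Algebraic outputs of a state: HCT, HR, CO, BP plus the reference BV
    change r_BV and the fluid-shift rate q."""
    if state.bv <= 0:
        raise ValueError("blood volume exhausted")
    hct = state.rbc / state.bv
    hr = params.H0 + state.h_v_t + state.h_v_l - state.h_u_t
    co = hr * state.sv
    bp = co * state.tpr
    r_bv = state.r_U_bv + state.r_V_bv
    q = params.K_P_BV * (state.bv - params.BV0 - r_bv)
    return {"hct": hct, "hr": hr, "co": co, "bp": bp, "r_bv": r_bv, "q": q}


@dataclass
class SimulationResult:
    """Trajectories of the six outputs on a regular time grid.

    By construction ``co = hr * sv`` and ``bp = co * tpr`` at every point.
    ``success`` is False when the integrator diverged or blood volume was
    exhausted; in that case trailing grid points are NaN.
    """

    time: np.ndarray
    bv: np.ndarray
    hct: np.ndarray
    hr: np.ndarray
    sv: np.ndarray
    co: np.ndarray
    bp: np.ndarray
    success: bool = True
    message: str = "ok"
    solver: dict = field(default_factory=dict)
    states: np.ndarray | None = None  # (T, 11), optional

    def variable(self, name: str) -> np.ndarray:
        if name not in OUTPUT_NAMES:
            raise KeyError(f"unknown output {name!r}")
        return getattr(self, name)

    def outputs(self) -> np.ndarray:
        """(T, 6) array in ``OUTPUT_NAMES`` order."""
        return np.column_stack([getattr(self, n) for n in OUTPUT_NAMES])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_min": self.time, "BV_l": self.bv, "HCT_pct": self.hct,
            "HR_bpm": self.hr, "SV_l": self.sv, "CO_l_per_min": self.co,
            "BP_mmHg": self.bp,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _output_grid(duration: float, output_interval: float) -> np.ndarray:
    if output_interval <= 0:
        raise ValueError("output_interval must be positive")
    n = int(np.floor(duration / output_interval + 1e-9))
    grid = np.arange(n + 1) * output_interval
    if grid[-1] < duration - 1e-9:
        grid = np.append(grid, duration)
    return grid


def _augmented_inputs(protocol: FluidProtocol) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Breakpoints extended with the protocol end (rates zero afterwards)."""
    if protocol.duration > protocol.times[-1]:
        breaks = np.append(protocol.times, protocol.duration)
        u = np.append(protocol.infusion, 0.0)
        v = np.append(protocol.loss, 0.0)
    else:
        breaks, u, v = protocol.times, protocol.infusion, protocol.loss
    return breaks, u, v


def _result_from_states(t_grid, states, th, success, message, solver_meta, keep_states):
    with np.errstate(invalid="ignore"):
        outs = _engine.outputs_from_states(states, th)
    return SimulationResult(
        time=t_grid, bv=outs[:, 0], hct=outs[:, 1], hr=outs[:, 2],
        sv=outs[:, 3], co=outs[:, 4], bp=outs[:, 5],
        success=success, message=message, solver=solver_meta,
        states=states if keep_states else None,
    )


def simulate(
    params: SubjectParameters,
    protocol: FluidProtocol,
    output_interval: float = 1.0,
    solver: SolverConfig | None = None,
    keep_states: bool = False,
) -> SimulationResult:
    """Integrate the model from its baseline-consistent initial state.

    Integration restarts exactly at protocol breakpoints, so the
    piecewise-constant inputs are never smoothed across a discontinuity.
    """
    cfg = solver or SolverConfig()
    th = params.to_array()
    t_grid = _output_grid(protocol.duration, output_interval)
    breaks, u_vals, v_vals = _augmented_inputs(protocol)
    meta = {"method": cfg.method, "sv_hr_sign": cfg.sv_hr_sign}

    if cfg.method in ("rk4", "euler"):
        order = 4 if cfg.method == "rk4" else 1
        y0 = initial_state(params).to_array()
        states, status, n_valid = _engine.integrate(
            th, y0, t_grid, breaks, u_vals, v_vals, cfg.dt, order, cfg.sv_hr_sign)
        meta["dt"] = cfg.dt
        ok = status == _engine.OK
        msg = {_engine.OK: "ok", _engine.NONFINITE: "numerical divergence",
               _engine.BV_EXHAUSTED: "blood volume exhausted"}[int(status)]
        return _result_from_states(t_grid, states, th, ok, msg, meta, keep_states)

    # adaptive RK45, segment by segment between input breakpoints
    meta.update({"max_step": cfg.max_step, "rtol": cfg.rtol, "atol": cfg.atol})
    seg_bounds = np.unique(np.concatenate([breaks[breaks < protocol.duration], [0.0, protocol.duration]]))
    states = np.full((t_grid.size, _engine.N_STATES), np.nan)
    y = initial_state(params).to_array()
    states[0] = y
    success, message = True, "ok"

    def bv_zero(t, yy):
        return yy[2]
    bv_zero.terminal = True
    bv_zero.direction = -1

    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        i = int(np.searchsorted(breaks, a, side="right")) - 1
        U, V = float(u_vals[i]), float(v_vals[i])
        sol = solve_ivp(
            lambda t, yy: _rhs_array(yy, U, V, th, cfg.sv_hr_sign),
            (a, b), y, method="RK45", max_step=cfg.max_step,
            rtol=cfg.rtol, atol=cfg.atol, dense_output=True, events=bv_zero,
        )
        mask = (t_grid > a + 1e-12) & (t_grid <= (sol.t[-1] if sol.t.size else a) + 1e-12)
        if np.any(mask):
            states[:, :][mask] = sol.sol(t_grid[mask]).T
        if sol.status == 1:  # bv hit zero
            success, message = False, "blood volume exhausted"
            break
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            success, message = False, "numerical divergence"
            break
        y = sol.y[:, -1]
    return _result_from_states(t_grid, states, th, success, message, meta, keep_states)


def simulate_outputs(
    params: SubjectParameters | np.ndarray,
    protocol: FluidProtocol,
    times: Sequence[float],
    dt: float = 0.1,
    sv_hr_sign: float = -1.0,
) -> tuple[np.ndarray, bool]:
    """Fast path: outputs (len(times), 6) at arbitrary times (compiled RK4).

    Returns ``(outputs, success)``; rows after a failure are NaN.
    """
    th = params.to_array() if isinstance(params, SubjectParameters) else np.asarray(params, float)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly increasing and non-negative")
    prepend = times[0] > 0
    t_grid = np.concatenate([[0.0], times]) if prepend else times
    breaks, u_vals, v_vals = _augmented_inputs(protocol)
    y0 = np.zeros(_engine.N_STATES)
    y0[2] = th[21]
    y0[3] = th[20] * th[21]
    y0[9] = th[23]
    y0[10] = th[24]
    states, status, _ = _engine.integrate(th, y0, t_grid, breaks, u_vals, v_vals, dt, 4, sv_hr_sign)
    with np.errstate(invalid="ignore"):
        outs = _engine.outputs_from_states(states, th)
    if prepend:
        outs = outs[1:]
    return outs, status == _engine.OK


def simulate_cohort(
    cohort: Sequence[SubjectParameters] | np.ndarray,
    protocol: FluidProtocol,
    times: Sequence[float],
    dt: float = 0.1,
    sv_hr_sign: float = -1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate many subjects under one protocol (compiled RK4 batch).

    Returns ``(outputs, ok)`` with outputs of shape (n, len(times), 6) in
    ``OUTPUT_NAMES`` order and a boolean success flag per subject.
    """
    if isinstance(cohort, np.ndarray):
        thetas = np.asarray(cohort, dtype=float)
    else:
        thetas = np.array([p.to_array() for p in cohort])
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0:
        raise ValueError("cohort simulation grid must start at 0")
    breaks, u_vals, v_vals = _augmented_inputs(protocol)
    with np.errstate(invalid="ignore"):
        outs, status = _engine.integrate_cohort(thetas, times, breaks, u_vals, v_vals, dt, 4, sv_hr_sign)
    return outs, status == _engine.OK


def equilibrium_tpr(
    params: SubjectParameters, H_const: float, SV_const: float
) -> tuple[float, float]:
    """Closed-form fixed point of the TPR equation at constant CO.

    Returns ``(TPR*, BP*)`` with
    ``TPR* = (A_BP*TPR0 - K_P_BP*r_BP) / (A_BP - K_P_BP*H*SV)``.
    """
    denom = params.A_BP - params.K_P_BP * H_const * SV_const
    if abs(denom) < 1e-12:
        raise ValueError("degenerate equilibrium: A_BP - K_P_BP*H*SV is zero")
    tpr_star = (params.A_BP * params.TPR0 - params.K_P_BP * params.r_BP) / denom
    return tpr_star, H_const * SV_const * tpr_star
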