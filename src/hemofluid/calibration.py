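"""Maximum-likelihood calibration of the model to measured time series.

The measurement model is ``v(t_k) = v_hat(t_k | Theta) + e(t_k)`` with
i.i.d. Gaussian errors per variable. For each calibrated variable
(HCT, HR, SV, BP — CO is excluded, being the product HR*SV) the error SD is
concentrated out analytically, ``sigma_hat^2 = mean(e^2)``, and the fitted
parameters minimize

    -sum_v L*_v(Theta, sigma_hat_v) + 2 * beta * ||Theta_scaled||^2

where ``L* = -(K/2) ln(2 pi) - (K/2) ln sigma^2 - SSE / (2 sigma^2)`` and the
L2 penalty acts on scale-normalized free parameters (the parameters span
five orders of magnitude, so an unscaled norm would regularize only the
largest ones). BV0, HCT0 and SV0 are held at their measured values; the
remaining 22 parameters are estimated by multi-start bounded L-BFGS-B.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .metrics import nmae, nrmse
from .model import simulate_outputs
from .parameters import BASELINE_NAMES, PARAM_NAMES, SubjectParameters, load_reference_parameters
from .protocol import FluidProtocol
from .synthetic import MEASURED_VARIABLES, MeasurementSeries

__all__ = [
    "CALIBRATED_VARIABLES",
    "FIXED_BASELINES",
    "CalibrationConfig",
    "CalibrationResult",
    "default_bounds_and_scales",
    "residuals",
    "sigma_mle",
    "log_likelihood",
    "objective",
    "fit",
]

#: Variables entering the likelihood (CO excluded).
CALIBRATED_VARIABLES: tuple[str, ...] = ("hct", "hr", "sv", "bp")

#: Baselines held at their measured values during calibration.
FIXED_BASELINES: tuple[str, ...] = ("BV0", "HCT0", "SV0")

FREE_PARAMS: tuple[str, ...] = tuple(n for n in PARAM_NAMES if n not in FIXED_BASELINES)

_VAR_COLUMN = {"bv": 0, "hct": 1, "hr": 2, "sv": 3, "co": 4, "bp": 5}

# Parameter-box construction rules. Boxes are the reference-table ranges
# widened 3x, sign-constrained; power exponents are confined to [0, 1];
# distribution ratios are kept above -0.95 so 1/(1+alpha) stays bounded.
_NONPOSITIVE = ("A_U_BV", "A_V_BV", "A_SV", "A_BP")
_RATIOS = ("alpha_U", "alpha_V")
_POWERS = ("P_U_T", "P_V_L")


def default_bounds_and_scales() -> tuple[
    dict[str, tuple[float, float]], dict[str, float], dict[str, tuple[float, float]]
]:
    """Per-parameter search boxes, scale constants and start boxes.

    Bounds are the reference-table ranges widened 3x (sign-constrained);
    multi-start initial values are drawn from the narrower observed range
    (``start_box``), since most of the widened box is dynamically unstable
    and gives the optimizer no usable gradient.
    """
    table = np.array([p.to_array() for p in load_reference_parameters()])
    bounds: dict[str, tuple[float, float]] = {}
    scales: dict[str, float] = {}
    start_box: dict[str, tuple[float, float]] = {}
    for j, name in enumerate(PARAM_NAMES):
        col = table[:, j]
        lo, hi = float(col.min()), float(col.max())
        scales[name] = max(float(np.max(np.abs(col))), 1e-3)
        start_box[name] = (lo, hi)
        if name in _NONPOSITIVE:
            bounds[name] = (3.0 * lo, 0.0)
        elif name in _POWERS:
            bounds[name] = (0.0, 1.0)
        elif name in _RATIOS:
            bounds[name] = (max(3.0 * lo, -0.95), 3.0 * hi)
        elif name in BASELINE_NAMES:
            bounds[name] = (lo / 3.0, 3.0 * hi)
        else:  # non-negative gains and references
            bounds[name] = (0.0, 3.0 * hi)
    return bounds, scales, start_box


@dataclass
class CalibrationConfig:
    """Settings for :func:`fit`.

    ``beta`` is the L2 penalty weight; ``squared_penalty`` selects
    ``2*beta*||x||^2`` (default) versus the literal ``2*beta*||x||``;
    ``sigma_floor`` prevents likelihood divergence on noiseless data.
    ``init`` optionally supplies explicit starting parameter sets used
    before any random starts.
    """

    beta: float = 1e-3
    n_starts: int = 16
    seed: int | None = 0
    bounds: dict[str, tuple[float, float]] | None = None
    scales: dict[str, float] | None = None
    sigma_floor: float = 1e-6
    maxiter: int = 300
    n_explore_per_start: int = 32
    sim_dt: float = 0.1
    squared_penalty: bool = True
    failure_objective: float = 1e12
    init: Sequence[SubjectParameters] | None = None

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.sigma_floor <= 0:
            raise ValueError("sigma_floor must be positive")

    def resolved(self) -> tuple[
        dict[str, tuple[float, float]], dict[str, float], dict[str, tuple[float, float]]
    ]:
        b, s, sb = default_bounds_and_scales()
        if self.bounds:
            b.update(self.bounds)
        if self.scales:
            s.update(self.scales)
        for name in FREE_PARAMS:
            lo, hi = b[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}")
            if s[name] <= 0:
                raise ValueError(f"scale for {name} must be positive")
            slo, shi = sb[name]
            sb[name] = (max(slo, lo), min(shi, hi))
        return b, s, sb


# ---------------------------------------------------------------------------
# Likelihood building blocks
# ---------------------------------------------------------------------------


def residuals(
    params: SubjectParameters,
    measurements: MeasurementSeries,
    protocol: FluidProtocol,
    sim_dt: float = 0.05,
    variables: Sequence[str] = MEASURED_VARIABLES,
) -> dict[str, np.ndarray]:
    """Per-variable residual sequences ``e(t_k) = v(t_k) - v_hat(t_k)``.

    The model is evaluated at the exact sample times; missing observations
    are skipped.
    """
    outs, ok = simulate_outputs(params, protocol, measurements.times, dt=sim_dt)
    if not ok:
        raise RuntimeError("simulation failed over the measurement horizon")
    res: dict[str, np.ndarray] = {}
    for var in variables:
        obs = measurements.values[var]
        mask = ~np.isnan(obs)
        res[var] = obs[mask] - outs[mask, _VAR_COLUMN[var]]
    return res


def sigma_mle(res: np.ndarray, floor: float = 1e-6) -> float:
    """Concentrated error-SD estimate ``sqrt(mean(e^2))``, floored at
    ``floor`` to avoid degeneracy on noiseless data."""
    res = np.asarray(res, dtype=float)
    if res.size < 2:
        raise ValueError("need at least 2 residuals")
    return max(float(np.sqrt(np.mean(res**2))), floor)


def log_likelihood(res: np.ndarray, sigma: float) -> float:
    """Gaussian log-likelihood of one variable's residual sequence."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    res = np.asarray(res, dtype=float)
    K = res.size
    return float(-K / 2 * np.log(2 * np.pi) - K / 2 * np.log(sigma**2)
                 - np.sum(res**2) / (2 * sigma**2))


def neg_log_likelihood(res_by_var: Mapping[str, np.ndarray], sigma_floor: float = 1e-6,
                       variables: Sequence[str] = CALIBRATED_VARIABLES) -> tuple[float, dict[str, float]]:
    """Total -LL over the calibrated variables at the concentrated sigmas."""
    total = 0.0
    sigmas: dict[str, float] = {}
    for var in variables:
        s = sigma_mle(res_by_var[var], sigma_floor)
        sigmas[var] = s
        total -= log_likelihood(res_by_var[var], s)
    return total, sigmas


def objective(
    params: SubjectParameters,
    measurements: MeasurementSeries,
    protocol: FluidProtocol,
    beta: float,
    cfg: CalibrationConfig | None = None,
) -> float:
    """The regularized negative log-likelihood minimized by :func:`fit`.

    Simulation failures map to a large finite value so line searches can
    back off instead of aborting.
    """
    cfg = cfg or CalibrationConfig(beta=beta)
    _, scales, _ = cfg.resolved()
    try:
        res = residuals(params, measurements, protocol, sim_dt=cfg.sim_dt,
                        variables=CALIBRATED_VARIABLES)
    except RuntimeError:
        return cfg.failure_objective
    nll, _ = neg_log_likelihood(res, cfg.sigma_floor)
    x = np.array([getattr(params, n) / scales[n] for n in FREE_PARAMS])
    pen = float(x @ x) if cfg.squared_penalty else float(np.sqrt(x @ x))
    return nll + 2.0 * beta * pen


# ---------------------------------------------------------------------------
# Multi-start fitting
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    params: SubjectParameters
    sigma: dict[str, float]
    neg_ll: float
    objective: float
    nrmse: dict[str, float]
    nmae: dict[str, float]
    start_objectives: list[float]
    converged: list[bool]
    beta: float

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {
            "parameters": self.params.to_dict(),
            "subject_id": self.params.subject_id,
            "sigma": self.sigma,
            "neg_ll": self.neg_ll,
            "objective": self.objective,
            "nrmse": self.nrmse,
            "nmae": self.nmae,
            "start_objectives": self.start_objectives,
            "converged": self.converged,
            "beta": self.beta,
        }
        payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResult":
        d = json.loads(Path(path).read_text())
        return cls(
            params=SubjectParameters(**d["parameters"], subject_id=d.get("subject_id")),
            sigma=d["sigma"], neg_ll=d["neg_ll"], objective=d["objective"],
            nrmse=d["nrmse"], nmae=d["nmae"],
            start_objectives=d["start_objectives"], converged=d["converged"],
            beta=d["beta"],
        )


def fit(
    measurements: MeasurementSeries,
    protocol: FluidProtocol,
    baselines: Mapping[str, float],
    cfg: CalibrationConfig | None = None,
) -> CalibrationResult:
    """Estimate the 22 free parameters by multi-start bounded L-BFGS-B.

    ``baselines`` must supply the fixed values for BV0, HCT0 and SV0.
    Optimization runs in scale-normalized parameter space; starts are drawn
    uniformly within the bounds under ``cfg.seed``, after any explicit
    ``cfg.init`` points. The best start (lowest objective) is returned.
    """
    cfg = cfg or CalibrationConfig()
    for name in FIXED_BASELINES:
        if name not in baselines:
            raise ValueError(f"baselines must include {name}")
    for var in CALIBRATED_VARIABLES:
        if measurements.n_samples(var) < 2:
            raise ValueError(f"need at least 2 samples of {var} to calibrate")

    bounds, scales, start_box = cfg.resolved()
    s = np.array([scales[n] for n in FREE_PARAMS])
    box = np.array([bounds[n] for n in FREE_PARAMS]) / s[:, None]
    sbox = np.array([start_box[n] for n in FREE_PARAMS]) / s[:, None]
    fixed = {n: float(baselines[n]) for n in FIXED_BASELINES}

    def build_theta(x: np.ndarray) -> np.ndarray:
        vals = dict(zip(FREE_PARAMS, x * s))
        vals.update(fixed)
        return np.array([vals[n] for n in PARAM_NAMES])

    t_meas = measurements.times
    obs = {v: measurements.values[v] for v in CALIBRATED_VARIABLES}
    masks = {v: ~np.isnan(obs[v]) for v in CALIBRATED_VARIABLES}

    def fun(x: np.ndarray) -> float:
        th = build_theta(x)
        with np.errstate(over="ignore", invalid="ignore"):
            outs, ok = simulate_outputs(th, protocol, t_meas, dt=cfg.sim_dt)
            if not ok or not np.all(np.isfinite(outs)):
                return cfg.failure_objective
            total = 0.0
            for var in CALIBRATED_VARIABLES:
                m = masks[var]
                e = obs[var][m] - outs[m, _VAR_COLUMN[var]]
                mse = float(np.mean(e**2))
                if not np.isfinite(mse):
                    return cfg.failure_objective
                sig2 = max(mse, cfg.sigma_floor**2)
                K = e.size
                total += K / 2 * (np.log(2 * np.pi) + np.log(sig2) + mse / sig2)
        pen = float(x @ x) if cfg.squared_penalty else float(np.sqrt(x @ x))
        return total + 2.0 * cfg.beta * pen

    rng = np.random.default_rng(cfg.seed)
    starts: list[np.ndarray] = []
    if cfg.init:
        for p in cfg.init:
            starts.append(np.clip(np.array([getattr(p, n) for n in FREE_PARAMS]) / s,
                                  box[:, 0], box[:, 1]))
    n_random = max(cfg.n_starts - len(starts), 0)
    if n_random:
        # exploration stage: screen cheap random candidates, keep the best
        # n_random as initial points for the gradient-based stage
        candidates = rng.uniform(sbox[:, 0], sbox[:, 1],
                                 size=(cfg.n_explore_per_start * n_random, len(FREE_PARAMS)))
        cand_objs = np.array([fun(c) for c in candidates])
        starts.extend(candidates[np.argsort(cand_objs)[:n_random]])

    best = None
    objs: list[float] = []
    flags: list[bool] = []
    for x0 in starts:
        r = minimize(fun, x0, method="L-BFGS-B", bounds=box,
                     options={"maxiter": cfg.maxiter})
        objs.append(float(r.fun))
        flags.append(bool(r.success))
        if best is None or r.fun < best.fun:
            best = r
    if best is None or best.fun >= cfg.failure_objective:
        raise RuntimeError(f"all {len(starts)} optimization starts failed; "
                           f"objectives: {objs}")

    theta = build_theta(best.x)
    params = SubjectParameters.from_array(theta, subject_id=measurements.provenance.get("subject_id"))
    res_all = residuals(params, measurements, protocol, sim_dt=cfg.sim_dt)
    nll, sigmas = neg_log_likelihood(res_all, cfg.sigma_floor)
    outs, _ = simulate_outputs(params, protocol, t_meas, dt=cfg.sim_dt)
    fit_nrmse, fit_nmae = {}, {}
    for var in MEASURED_VARIABLES:
        sim = outs[:, _VAR_COLUMN[var]]
        fit_nrmse[var] = nrmse(measurements.values[var], sim)
        fit_nmae[var] = nmae(measurements.values[var], sim)
    return CalibrationResult(
        params=params, sigma=sigmas, neg_ll=nll, objective=float(best.fun),
        nrmse=fit_nrmse, nmae=fit_nmae, start_objectives=objs, converged=flags,
        beta=cfg.beta,
    )
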