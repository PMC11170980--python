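"""Credibility assessment: filters, prediction envelope, coverage and NIS.

Given a test subject's measurements and a virtual cohort simulated under the
test protocol, the assessment proceeds in three stages:

1. **physiological filter** — discard simulations that leave the ranges
   HCT (0, 50] %, HR (0, 300] bpm, SV (0, 0.100] l, BP (0, 150] mmHg at any
   output time (CO is unconstrained);
2. **relevance filter** — among physiological simulations, keep those with
   NRMSE <= 25% against the test data on *every* one of HCT, HR, SV, CO, BP;
3. **prediction envelope** — the pointwise min/max band over relevant
   simulations at the measurement times, summarized by data coverage and by
   the normalized interval score (NIS), which adds a 2/alpha penalty for
   points outside the band (alpha = 0.05).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CALIBRATED_VARIABLES, neg_log_likelihood
from .metrics import nmae, nrmse
from .model import simulate_cohort
from .parameters import SubjectParameters
from .protocol import FluidProtocol
from .synthetic import MEASURED_VARIABLES, MeasurementSeries

__all__ = [
    "PHYSIOLOGICAL_RANGES",
    "PredictionEnvelope",
    "CredibilityReport",
    "AssessmentConfig",
    "physiological_filter",
    "relevance_filter",
    "build_envelope",
    "coverage",
    "nis",
    "best_virtual_subject",
    "assess",
]

_VAR_COLUMN = {"bv": 0, "hct": 1, "hr": 2, "sv": 3, "co": 4, "bp": 5}

#: Closed upper bounds of the physiological trajectory ranges, per variable.
PHYSIOLOGICAL_RANGES: dict[str, float] = {"hct": 50.0, "hr": 300.0, "sv": 0.100, "bp": 150.0}


@dataclass
class PredictionEnvelope:
    """Pointwise min/max band over relevant simulations at measurement times."""

    times: np.ndarray
    lower: dict[str, np.ndarray]
    upper: dict[str, np.ndarray]
    n_relevant: int

    def __post_init__(self) -> None:
        for var in self.lower:
            if np.any(self.lower[var] > self.upper[var] + 1e-12):
                raise ValueError(f"envelope for {var} has lower > upper")

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for var in MEASURED_VARIABLES:
            for t, lo, hi in zip(self.times, self.lower[var], self.upper[var]):
                rows.append({"variable": var, "time_min": t, "lower": lo,
                             "upper": hi, "n_relevant": self.n_relevant})
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class AssessmentConfig:
    """Settings for :func:`assess`."""

    relevance_threshold: float = 25.0   # NRMSE %, per variable
    alpha: float = 0.05                 # NIS significance level
    output_interval: float = 1.0        # grid (min) for the physiological check
    sim_dt: float = 0.1
    sv_hr_sign: float = -1.0


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def physiological_filter(
    outputs: np.ndarray,
    ok: np.ndarray | None = None,
    ranges: Mapping[str, float] = PHYSIOLOGICAL_RANGES,
) -> tuple[np.ndarray, float]:
    """Boolean mask of physiological simulations and their percentage.

    ``outputs`` has shape (n, T, 6); a simulation is physiological iff it
    succeeded and every constrained variable stays within (0, upper] at all
    output times.
    """
    n = outputs.shape[0]
    keep = np.ones(n, dtype=bool) if ok is None else np.asarray(ok, dtype=bool).copy()
    keep &= np.all(np.isfinite(outputs), axis=(1, 2))
    for var, upper in ranges.items():
        col = outputs[:, :, _VAR_COLUMN[var]]
        with np.errstate(invalid="ignore"):
            keep &= np.all((col > 0.0) & (col <= upper), axis=1)
    return keep, 100.0 * float(keep.sum()) / n


def _nrmse_matrix(sim_at_meas: np.ndarray, measurements: MeasurementSeries) -> np.ndarray:
    """(n, 5) NRMSE of each simulation against the test data."""
    n = sim_at_meas.shape[0]
    out = np.empty((n, len(MEASURED_VARIABLES)))
    for j, var in enumerate(MEASURED_VARIABLES):
        obs = measurements.values[var]
        mask = ~np.isnan(obs)
        err = sim_at_meas[:, mask, _VAR_COLUMN[var]] - obs[mask]
        out[:, j] = 100.0 * np.sqrt(np.mean(err**2, axis=1)) / np.mean(obs[mask])
    return out


def relevance_filter(
    sim_at_meas: np.ndarray,
    measurements: MeasurementSeries,
    threshold: float = 25.0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Relevant-simulation mask among the given simulations.

    A simulation is relevant iff its NRMSE is <= ``threshold`` for every one
    of HCT, HR, SV, CO, BP. Returns (mask, percentage, nrmse_matrix).
    """
    nr = _nrmse_matrix(sim_at_meas, measurements)
    mask = np.all(nr <= threshold, axis=1)
    pct = 100.0 * float(mask.sum()) / sim_at_meas.shape[0] if sim_at_meas.shape[0] else 0.0
    return mask, pct, nr


# ---------------------------------------------------------------------------
# Envelope, coverage, NIS
# ---------------------------------------------------------------------------


def build_envelope(sim_at_meas: np.ndarray, times: np.ndarray) -> PredictionEnvelope:
    """Pointwise min/max across relevant simulations, per variable per time."""
    if sim_at_meas.shape[0] < 1:
        raise ValueError("no relevant simulations: envelope undefined")
    lower, upper = {}, {}
    for var in MEASURED_VARIABLES:
        col = sim_at_meas[:, :, _VAR_COLUMN[var]]
        lower[var] = col.min(axis=0)
        upper[var] = col.max(axis=0)
    return PredictionEnvelope(np.asarray(times, float), lower, upper, sim_at_meas.shape[0])


def coverage(envelope: PredictionEnvelope, measurements: MeasurementSeries) -> float:
    """Mean percentage of data points inside the envelope, averaged over the
    five variables (per-variable fractions first, then unweighted mean)."""
    fracs = []
    for var in MEASURED_VARIABLES:
        obs = measurements.values[var]
        mask = ~np.isnan(obs)
        inside = (obs[mask] >= envelope.lower[var][mask]) & (obs[mask] <= envelope.upper[var][mask])
        fracs.append(np.mean(inside))
    return 100.0 * float(np.mean(fracs))


def nis(envelope: PredictionEnvelope, measurements: MeasurementSeries,
        alpha: float = 0.05) -> dict[str, float]:
    """Normalized interval score per variable (mean over time points).

    Per point: the relative envelope width, plus ``(2/alpha) * distance``
    relative to the observation when it falls outside the band.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    scores: dict[str, float] = {}
    for var in MEASURED_VARIABLES:
        obs = measurements.values[var]
        mask = ~np.isnan(obs)
        v = obs[mask]
        if np.any(v <= 0):
            raise ValueError(f"{var}: observations must be positive for NIS")
        lo = envelope.lower[var][mask]
        hi = envelope.upper[var][mask]
        width = hi - lo
        penalty = (2.0 / alpha) * (np.maximum(lo - v, 0.0) + np.maximum(v - hi, 0.0))
        scores[var] = float(np.mean((width + penalty) / v))
    return scores


# ---------------------------------------------------------------------------
# Best virtual subject and the full assessment
# ---------------------------------------------------------------------------


def best_virtual_subject(
    sim_at_meas: np.ndarray,
    measurements: MeasurementSeries,
    nrmse_matrix: np.ndarray | None = None,
    sigma_floor: float = 1e-6,
) -> dict:
    """Metrics of the most relevant simulation (minimum average NRMSE across
    the five variables; ties broken by maximum NRMSE, then lowest index).

    -LL uses the concentrated per-variable sigma over HCT, HR, SV and BP,
    mirroring the calibration likelihood (CO excluded).
    """
    if sim_at_meas.shape[0] < 1:
        raise ValueError("no candidate simulations")
    nr = nrmse_matrix if nrmse_matrix is not None else _nrmse_matrix(sim_at_meas, measurements)
    avg = nr.mean(axis=1)
    mx = nr.max(axis=1)
    order = np.lexsort((np.arange(len(avg)), mx, avg))
    i = int(order[0])
    res = {}
    for var in CALIBRATED_VARIABLES:
        obs = measurements.values[var]
        mask = ~np.isnan(obs)
        res[var] = obs[mask] - sim_at_meas[i, mask, _VAR_COLUMN[var]]
    nll, _ = neg_log_likelihood(res, sigma_floor)
    nmae_vals = np.array([
        nmae(measurements.values[var], sim_at_meas[i, :, _VAR_COLUMN[var]])
        for var in MEASURED_VARIABLES
    ])
    return {
        "index": i,
        "avg_nrmse": float(avg[i]),
        "max_nrmse": float(mx[i]),
        "avg_nmae": float(nmae_vals.mean()),
        "max_nmae": float(nmae_vals.max()),
        "neg_ll": float(nll),
    }


@dataclass
class CredibilityReport:
    """Assessment summary mirroring the three-fold procedure: best-subject
    similarity, cohort percentages and coverage, and per-variable NIS."""

    best_subject: dict | None
    pct_physiological: float
    pct_relevant: float
    pct_coverage: float | None
    nis: dict[str, float] | None
    n_cohort: int
    n_relevant: int
    flags: list[str] = field(default_factory=list)
    envelope: PredictionEnvelope | None = None

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {
            "best_subject": self.best_subject,
            "cohort": {
                "pct_physiological": self.pct_physiological,
                "pct_relevant": self.pct_relevant,
                "pct_coverage": self.pct_coverage,
                "n_cohort": self.n_cohort,
                "n_relevant": self.n_relevant,
            },
            "nis": self.nis,
            "flags": self.flags,
        }
        payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2))


def assess(
    measurements: MeasurementSeries,
    protocol: FluidProtocol,
    cohort: Sequence,
    cfg: AssessmentConfig | None = None,
) -> CredibilityReport:
    """Run the full three-fold credibility assessment of a cohort against
    one test subject. Deterministic given the cohort."""
    cfg = cfg or AssessmentConfig()
    params = [c.parameters if hasattr(c, "parameters") else c for c in cohort]
    if not params:
        raise ValueError("empty cohort")
    t_meas = measurements.times
    if t_meas[-1] > protocol.duration + 1e-9:
        raise ValueError("measurements extend beyond the protocol duration")
    grid = np.union1d(
        np.arange(0.0, protocol.duration + 1e-9, cfg.output_interval), t_meas)
    if grid[0] != 0.0:
        grid = np.insert(grid, 0, 0.0)
    meas_idx = np.searchsorted(grid, t_meas)

    outs, ok = simulate_cohort(params, protocol, grid, dt=cfg.sim_dt,
                               sv_hr_sign=cfg.sv_hr_sign)
    phys_mask, pct_phys = physiological_filter(outs, ok)
    n = len(params)
    flags: list[str] = []
    if not phys_mask.any():
        return CredibilityReport(None, pct_phys, 0.0, None, None, n, 0,
                                 flags=["no-physiological-subjects", "no-envelope"])

    phys_idx = np.where(phys_mask)[0]
    sim_at_meas = outs[phys_idx][:, meas_idx, :]
    rel_mask, _, nr = relevance_filter(sim_at_meas, measurements, cfg.relevance_threshold)
    n_rel = int(rel_mask.sum())
    pct_rel = 100.0 * n_rel / n

    if n_rel == 0:
        best = best_virtual_subject(sim_at_meas, measurements, nr)
        best["cohort_index"] = int(phys_idx[best.pop("index")])
        flags.append("no-relevant-subjects")
        flags.append("no-envelope")
        return CredibilityReport(best, pct_phys, 0.0, None, None, n, 0, flags=flags)

    rel_sims = sim_at_meas[rel_mask]
    best = best_virtual_subject(rel_sims, measurements, nr[rel_mask])
    best["cohort_index"] = int(phys_idx[np.where(rel_mask)[0][best.pop("index")]])
    env = build_envelope(rel_sims, t_meas)
    cov = coverage(env, measurements)
    scores = nis(env, measurements, cfg.alpha)
    return CredibilityReport(best, pct_phys, pct_rel, cov, scores, n, n_rel,
                             flags=flags, envelope=env)
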