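"""Normalized error metrics shared by calibration and credibility assessment."""

from __future__ import annotations

import numpy as np

__all__ = ["nrmse", "nmae"]


def _prepare(observed, simulated) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError("observed and simulated series must have equal length")
    mask = ~np.isnan(obs)
    obs, sim = obs[mask], sim[mask]
    if obs.size < 1:
        raise ValueError("need at least one observation")
    if np.mean(obs) == 0:
        raise ValueError("observed mean is zero; normalized error undefined")
    return obs, sim


def nrmse(observed, simulated) -> float:
    """Normalized root-mean-square error in percent:
    ``100 * sqrt(mean((v - v_hat)^2)) / mean(v)``. NaN observations are
    skipped; a NaN simulated value (failed simulation) yields NaN."""
    obs, sim = _prepare(observed, simulated)
    return float(100.0 * np.sqrt(np.mean((obs - sim) ** 2)) / np.mean(obs))


def nmae(observed, simulated) -> float:
    """Normalized mean absolute error in percent:
    ``100 * mean(|v - v_hat|) / mean(v)``."""
    obs, sim = _prepare(observed, simulated)
    return float(100.0 * np.mean(np.abs(obs - sim)) / np.mean(obs))
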