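"""Piecewise-constant fluid-perturbation protocols.

A protocol is the pair of input signals driving every simulation: the
infusion rate ``U(t)`` and the loss rate ``V(t)`` (hemorrhage plus urine),
both in l/min, piecewise constant on half-open intervals between breakpoints.
Beyond the protocol duration both rates are zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FluidProtocol"]


@dataclass(frozen=True)
class FluidProtocol:
    """Piecewise-constant infusion/loss schedule.

    ``infusion[i]`` and ``loss[i]`` apply on ``[times[i], times[i+1])``; the
    last interval ends at ``duration``. Rates are zero for ``t >= duration``.
    Negative rates are rejected: hemorrhage and infusion are separate,
    non-negative channels.
    """

    times: np.ndarray       # breakpoint starts (min); times[0] == 0
    infusion: np.ndarray    # U per interval (l/min)
    loss: np.ndarray        # V per interval (l/min)
    duration: float         # total protocol length (min)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        u = np.asarray(self.infusion, dtype=float)
        v = np.asarray(self.loss, dtype=float)
        if t.ndim != 1 or t.size == 0 or t[0] != 0.0:
            raise ValueError("breakpoints must be a 1-d array starting at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if u.shape != t.shape or v.shape != t.shape:
            raise ValueError("infusion/loss must have one rate per breakpoint")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise ValueError("protocol contains non-finite values")
        if np.any(u < 0) or np.any(v < 0):
            raise ValueError("rates must be non-negative")
        if self.duration < t[-1]:
            raise ValueError("duration must be >= last breakpoint")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "infusion", u)
        object.__setattr__(self, "loss", v)
        object.__setattr__(self, "duration", float(self.duration))

    # -- constructors ----------------------------------------------------
    @classmethod
    def zero(cls, duration: float) -> "FluidProtocol":
        """A rest protocol: no infusion, no loss."""
        return cls(np.array([0.0]), np.array([0.0]), np.array([0.0]), duration)

    @classmethod
    def from_events(
        cls,
        duration: float,
        loss_events: Sequence[tuple[float, float, float]] = (),
        infusion_events: Sequence[tuple[float, float, float]] = (),
    ) -> "FluidProtocol":
        """Build a protocol from ``(start, stop, rate)`` events per channel.

        Overlapping events on the same channel add their rates.
        """
        edges = {0.0, float(duration)}
        for start, stop, _ in list(loss_events) + list(infusion_events):
            if not 0 <= start < stop:
                raise ValueError("events need 0 <= start < stop")
            edges.update((float(start), float(stop)))
        times = np.array(sorted(e for e in edges if e < duration))
        u = np.zeros_like(times)
        v = np.zeros_like(times)
        for start, stop, rate in loss_events:
            v[(times >= start) & (times < stop)] += rate
        for start, stop, rate in infusion_events:
            u[(times >= start) & (times < stop)] += rate
        return cls(times, u, v, float(duration))

    # -- evaluation ------------------------------------------------------
    def rates_at(self, t: float) -> tuple[float, float]:
        """(U, V) at time ``t``; zero outside ``[0, duration)``."""
        if t < 0 or t >= self.duration:
            return 0.0, 0.0
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.infusion[i]), float(self.loss[i])

    def total_loss(self) -> float:
        """Integral of V over the protocol (liters)."""
        widths = np.diff(np.append(self.times, self.duration))
        return float(np.sum(widths * self.loss))

    def total_infusion(self) -> float:
        """Integral of U over the protocol (liters)."""
        widths = np.diff(np.append(self.times, self.duration))
        return float(np.sum(widths * self.infusion))

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write `time_min,U_l_per_min,V_l_per_min`, with a terminal zero-rate
        row at ``duration`` marking the protocol end."""
        t = np.append(self.times, self.duration)
        u = np.append(self.infusion, 0.0)
        v = np.append(self.loss, 0.0)
        pd.DataFrame({"time_min": t, "U_l_per_min": u, "V_l_per_min": v}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FluidProtocol":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        for col in ("time_min", "U_l_per_min", "V_l_per_min"):
            if col not in df.columns:
                raise ValueError(f"protocol file {path}: missing column {col!r}")
        t = df["time_min"].to_numpy(float)
        u = df["U_l_per_min"].to_numpy(float)
        v = df["V_l_per_min"].to_numpy(float)
        if t.size >= 2 and u[-1] == 0.0 and v[-1] == 0.0:
            # terminal sentinel row marks the duration
            return cls(t[:-1], u[:-1], v[:-1], float(t[-1]))
        return cls(t, u, v, float(t[-1]) if t.size else 0.0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "duration_min": self.duration,
            "breakpoints": [
                {"time_min": float(t), "U_l_per_min": float(u), "V_l_per_min": float(v)}
                for t, u, v in zip(self.times, self.infusion, self.loss)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FluidProtocol":
        payload = json.loads(Path(path).read_text())
        bps = payload["breakpoints"]
        return cls(
            np.array([b["time_min"] for b in bps], dtype=float),
            np.array([b["U_l_per_min"] for b in bps], dtype=float),
            np.array([b["V_l_per_min"] for b in bps], dtype=float),
            float(payload["duration_min"]),
        )
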