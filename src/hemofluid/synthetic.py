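"""Synthetic study protocols and noisy measurement series.

This module emulates the two animal study designs the model is meant to be
exercised against, so that every downstream component (calibration, cohort
generation, credibility assessment) is testable without animal data:

* **sheep-like** — a conscious-hemorrhage study: 25 ml/kg hemorrhage over
  the first 15 min, two further 5 ml/kg hemorrhages at 50 and 70 min (5 min
  each), and closed-loop fluid infusion over the final 150 min of a 180-min
  experiment. The original study drove the infusion with a proprietary
  closed-loop controller; here a simple discrete proportional-integral law
  (documented stand-in, not a reconstruction) updates the infusion rate
  every 5 min to steer simulated BP back to its baseline.
* **swine-like** — an anesthetized-hemorrhage study: constant-rate
  hemorrhage until simulated BP first reaches a stop target (default
  40 mmHg), then repeated boluses of 500 ml per 70 kg body weight, each
  followed by a 60-min washout.

Measurements are the simulated trajectory sampled every 5 or 10 min with
additive zero-mean i.i.d. Gaussian noise whose SD is a fraction of each
variable's baseline value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import SimulationResult, SolverConfig, simulate, simulate_outputs
from .parameters import SubjectParameters
from .protocol import FluidProtocol

__all__ = [
    "MEASURED_VARIABLES",
    "DEFAULT_NOISE_SD",
    "MeasurementSeries",
    "SheepControllerConfig",
    "ProtocolSpec",
    "make_sheep_protocol",
    "make_swine_protocol",
    "sample_measurements",
    "make_synthetic_subject_data",
]

#: Variables observed every 5-10 min, in canonical order.
MEASURED_VARIABLES: tuple[str, ...] = ("hct", "hr", "sv", "co", "bp")

#: Default measurement-noise SD as a fraction of each variable's baseline.
DEFAULT_NOISE_SD: dict[str, float] = {"hct": 0.02, "hr": 0.05, "sv": 0.05, "co": 0.05, "bp": 0.05}

_CSV_COLS = {"hct": "HCT_pct", "hr": "HR_bpm", "sv": "SV_l", "co": "CO_l_per_min", "bp": "BP_mmHg"}


@dataclass
class MeasurementSeries:
    """Sparse noisy observations of HCT, HR, SV, CO, BP.

    ``values[var]`` aligns with ``times``; missing observations are NaN.
    ``provenance`` records the generating subject, noise SDs and seed when
    the series is synthetic.
    """

    times: np.ndarray
    values: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need at least 2 sample times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        for var in MEASURED_VARIABLES:
            if var not in self.values:
                raise ValueError(f"missing variable {var!r}")
            arr = np.asarray(self.values[var], dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{var}: length mismatch with times")
            present = arr[~np.isnan(arr)]
            if present.size < 2:
                raise ValueError(f"{var}: need at least 2 observations")
            if np.any(~np.isfinite(present)) or np.any(present <= 0):
                raise ValueError(f"{var}: observations must be finite and positive")
            self.values[var] = arr

    def n_samples(self, var: str) -> int:
        return int(np.sum(~np.isnan(self.values[var])))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_min": self.times})
        for var, col in _CSV_COLS.items():
            df[col] = self.values[var]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementSeries":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        for col in ("time_min", *_CSV_COLS.values()):
            if col not in df.columns:
                raise ValueError(f"measurement file {path}: missing column {col!r}")
        values = {var: df[col].to_numpy(float) for var, col in _CSV_COLS.items()}
        return cls(times=df["time_min"].to_numpy(float), values=values)


# ---------------------------------------------------------------------------
# Sheep-like protocol: staged hemorrhage + stand-in closed-loop infusion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SheepControllerConfig:
    """Stand-in discrete PI infusion law for the sheep-like protocol.

    Every ``update_interval`` minutes the infusion rate is set to
    ``kp*e + ki*I`` where ``e`` is the current BP shortfall from baseline
    (mmHg) and ``I`` its running time-integral, clamped to
    ``[0, u_max]`` l/min. The integral only accumulates while the command is
    unsaturated (simple anti-windup). Infusion pauses inside a deadband
    (BP within ``deadband_fraction`` of target) and stops for good once the
    cumulative infused volume reaches ``volume_cap_ml_per_kg``, mimicking a
    finite resuscitation-fluid budget.
    """

    kp: float = 0.004       # l/min per mmHg
    ki: float = 0.0002      # l/min per mmHg.min
    update_interval: float = 5.0
    u_max: float = 0.3
    start_min: float = 30.0
    deadband_fraction: float = 0.05
    volume_cap_ml_per_kg: float = 120.0


def make_sheep_protocol(
    weight_kg: float = 40.0,
    params: SubjectParameters | None = None,
    controller: SheepControllerConfig | None = None,
    duration: float = 180.0,
    urine_rate_l_per_min: float = 0.0,
) -> FluidProtocol:
    """The sheep-like fluid-perturbation protocol for one subject.

    Loss: 25 ml/kg uniformly over [0, 15) min plus 5 ml/kg over [50, 55) and
    [70, 75) min. Infusion: zero before minute 30; afterwards, if ``params``
    is given, the stand-in closed-loop law (run against a forward simulation
    of that subject) produces a piecewise-constant infusion profile updated
    every 5 min. Without ``params`` the protocol is hemorrhage-only.
    """
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    w_l = weight_kg / 1000.0  # ml/kg -> l conversion factor
    loss_events = [
        (0.0, 15.0, 25.0 * w_l / 15.0),
        (50.0, 55.0, 5.0 * w_l / 5.0),
        (70.0, 75.0, 5.0 * w_l / 5.0),
    ]
    if urine_rate_l_per_min > 0:
        loss_events.append((0.0, duration, urine_rate_l_per_min))
    if params is None:
        return FluidProtocol.from_events(duration, loss_events=loss_events)

    ctl = controller or SheepControllerConfig()
    bp_target = params.BP0
    edges = np.arange(ctl.start_min, duration, ctl.update_interval)
    infusion_events: list[tuple[float, float, float]] = []
    integral = 0.0
    infused = 0.0
    budget = ctl.volume_cap_ml_per_kg * w_l
    for t_now in edges:
        # simulate the subject under the inputs committed so far
        trial = FluidProtocol.from_events(duration, loss_events=loss_events,
                                          infusion_events=infusion_events or [])
        outs, ok = simulate_outputs(params, trial, np.array([t_now]), dt=0.05)
        if not ok:
            raise RuntimeError("closed-loop preview simulation failed")
        bp_now = outs[0, 5]
        e = bp_target - bp_now
        if e <= ctl.deadband_fraction * bp_target or infused >= budget:
            continue
        u_cmd = ctl.kp * e + ctl.ki * integral
        u = min(max(u_cmd, 0.0), ctl.u_max)
        if u_cmd == u:  # anti-windup: freeze integral while saturated
            integral += e * ctl.update_interval
        window = float(min(t_now + ctl.update_interval, duration)) - float(t_now)
        u = min(u, (budget - infused) / window)
        if u > 0:
            # commit the window only if the subject tolerates it; a diverging
            # preview (pathological infusion response) skips the window
            candidate = infusion_events + [(float(t_now), float(t_now) + window, u)]
            trial = FluidProtocol.from_events(duration, loss_events=loss_events,
                                              infusion_events=candidate)
            ahead = np.arange(t_now, duration + 1e-9, ctl.update_interval)
            outs_ahead, ok = simulate_outputs(params, trial, ahead, dt=0.05)
            if ok and np.all(outs_ahead > 0.0):
                infusion_events = candidate
                infused += u * window
    return FluidProtocol.from_events(duration, loss_events=loss_events,
                                     infusion_events=infusion_events)


# ---------------------------------------------------------------------------
# Swine-like protocol: hemorrhage to a BP target, then boluses with washouts
# ---------------------------------------------------------------------------


def make_swine_protocol(
    weight_kg: float = 70.0,
    params: SubjectParameters | None = None,
    hemorrhage_rate_ml_per_kg_min: float = 1.0,
    bp_stop_target_mmHg: float = 40.0,
    n_boluses: int = 3,
    bolus_duration_min: float = 5.0,
    washout_min: float = 60.0,
    max_hemorrhage_min: float = 120.0,
    pre_infusion: tuple[float, float, float] | None = None,
) -> FluidProtocol:
    """The swine-like protocol: bleed until BP reaches the stop target, then
    ``n_boluses`` boluses of 500 ml per 70 kg with washouts.

    The hemorrhage stop time is found by forward-simulating ``params`` (the
    original studies stopped on the measured BP). ``pre_infusion`` is an
    optional ``(start, stop, rate_l_per_min)`` infusion before hemorrhage.
    """
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    if hemorrhage_rate_ml_per_kg_min <= 0:
        raise ValueError("hemorrhage rate must be positive")
    if not 0 < bp_stop_target_mmHg < 150:
        raise ValueError("bp_stop_target_mmHg must lie in (0, 150)")
    if params is None:
        raise ValueError("a parameter set is required to locate the BP stop target")

    v_rate = hemorrhage_rate_ml_per_kg_min * weight_kg / 1000.0  # l/min
    pre = [pre_infusion] if pre_infusion is not None else []
    t0 = pre_infusion[1] if pre_infusion is not None else 0.0

    # forward-simulate on a fine grid to find when BP first crosses the target
    probe = FluidProtocol.from_events(
        t0 + max_hemorrhage_min,
        loss_events=[(t0, t0 + max_hemorrhage_min, v_rate)],
        infusion_events=pre,
    )
    t_probe = np.arange(0.0, t0 + max_hemorrhage_min + 1e-9, 0.25)
    outs, _ = simulate_outputs(params, probe, t_probe, dt=0.05)
    bp = outs[:, 5]
    below = np.where((t_probe > t0) & ~np.isnan(bp) & (bp <= bp_stop_target_mmHg))[0]
    if below.size == 0:
        raise ValueError("target unreachable: simulated BP never falls to the stop target")
    t_stop = float(t_probe[below[0]])

    bolus_volume = 0.5 * weight_kg / 70.0  # liters
    bolus_rate = bolus_volume / bolus_duration_min
    infusion_events = list(pre)
    t = t_stop
    for _ in range(n_boluses):
        infusion_events.append((t, t + bolus_duration_min, bolus_rate))
        t += bolus_duration_min + washout_min
    return FluidProtocol.from_events(
        t, loss_events=[(t0, t_stop, v_rate)], infusion_events=infusion_events)


# ---------------------------------------------------------------------------
# ProtocolSpec: declarative description that compiles to a FluidProtocol
# ---------------------------------------------------------------------------


@dataclass
class ProtocolSpec:
    """Declarative protocol description (sheep-like | swine-like | custom).

    ``options`` are forwarded to the matching builder; for ``custom`` they
    must contain ``duration`` plus ``loss_events`` / ``infusion_events``
    lists of ``[start, stop, rate]``. Compilation is deterministic, so
    compiling twice yields identical protocols.
    """

    template: str
    weight_kg: float = 40.0
    options: dict = field(default_factory=dict)

    def compile(self, params: SubjectParameters | None = None) -> FluidProtocol:
        if self.weight_kg <= 0:
            raise ValueError("weight_kg must be positive")
        if self.template == "sheep-like":
            return make_sheep_protocol(self.weight_kg, params=params, **self.options)
        if self.template == "swine-like":
            return make_swine_protocol(self.weight_kg, params=params, **self.options)
        if self.template == "custom":
            opts = dict(self.options)
            return FluidProtocol.from_events(
                opts["duration"],
                loss_events=[tuple(e) for e in opts.get("loss_events", [])],
                infusion_events=[tuple(e) for e in opts.get("infusion_events", [])],
            )
        raise ValueError(f"unknown template {self.template!r}")

    def to_yaml(self, path: str | Path) -> None:
        import yaml
        payload = {"template": self.template, "weight_kg": self.weight_kg,
                   "options": self.options}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolSpec":
        import yaml
        payload = yaml.safe_load(Path(path).read_text())
        return cls(template=payload["template"],
                   weight_kg=float(payload.get("weight_kg", 40.0)),
                   options=payload.get("options", {}) or {})


# ---------------------------------------------------------------------------
# Measurement sampling
# ---------------------------------------------------------------------------


def sample_measurements(
    result: SimulationResult,
    interval_min: float = 5.0,
    noise_sd: Mapping[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
    subject_id: str | None = None,
) -> MeasurementSeries:
    """Sample a simulated trajectory every ``interval_min`` minutes and add
    zero-mean i.i.d. Gaussian noise with SD ``noise_sd[var] * baseline``.

    The trajectory grid must contain the sample times. Deterministic under a
    fixed seed.
    """
    if interval_min <= 0:
        raise ValueError("interval_min must be positive")
    if interval_min > result.time[-1]:
        raise ValueError("sampling interval exceeds the simulation duration")
    sd = dict(DEFAULT_NOISE_SD)
    if noise_sd is not None:
        sd.update(noise_sd)
    for var, frac in sd.items():
        if frac < 0:
            raise ValueError(f"noise SD for {var} must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t_samp = np.arange(0.0, result.time[-1] + 1e-9, interval_min)
    idx = np.searchsorted(result.time, t_samp - 1e-9)
    if np.any(np.abs(result.time[idx] - t_samp) > 1e-6):
        raise ValueError("sample times must lie on the simulation grid")
    values: dict[str, np.ndarray] = {}
    for var in MEASURED_VARIABLES:
        traj = result.variable(var)[idx]
        if np.any(~np.isfinite(traj)) or np.any(traj <= 0):
            raise ValueError(f"{var}: trajectory is not positive at all sample times")
        baseline = result.variable(var)[0]
        if sd[var] > 0:
            obs = traj + rng.normal(0.0, sd[var] * baseline, size=traj.shape)
            # a physical measurement cannot be <= 0: redraw (truncation)
            for _ in range(100):
                neg = obs <= 0
                if not neg.any():
                    break
                obs[neg] = traj[neg] + rng.normal(0.0, sd[var] * baseline, size=int(neg.sum()))
            values[var] = obs
        else:
            values[var] = traj.copy()
    return MeasurementSeries(
        times=t_samp, values=values,
        provenance={"subject_id": subject_id, "noise_sd": sd,
                    "seed": None if isinstance(seed, np.random.Generator) else seed},
    )


def make_synthetic_subject_data(
    params: SubjectParameters,
    weight_kg: float | None = None,
    interval_min: float = 5.0,
    noise_sd: Mapping[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
    blood_volume_ml_per_kg: float = 60.0,
    solver: SolverConfig | None = None,
) -> tuple[FluidProtocol, SimulationResult, MeasurementSeries]:
    """Full synthetic sheep-study data for one subject.

    When ``weight_kg`` is omitted it is inferred from BV0 via the standard
    60 ml/kg blood-volume rule, so the per-kg hemorrhage doses scale
    consistently with the subject's measured blood volume.
    """
    if weight_kg is None:
        weight_kg = params.BV0 * 1000.0 / blood_volume_ml_per_kg
    protocol = make_sheep_protocol(weight_kg, params=params)
    result = simulate(params, protocol, output_interval=1.0,
                      solver=solver or SolverConfig(method="rk4"))
    if not result.success:
        raise RuntimeError(f"synthetic subject simulation failed: {result.message}")
    series = sample_measurements(result, interval_min, noise_sd, seed,
                                 subject_id=params.subject_id)
    return protocol, result, series
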