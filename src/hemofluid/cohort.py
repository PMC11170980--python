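"""Virtual-subject generation by the compartment method.

Virtual subjects are assembled from a calibration set of N subjects by
transplanting whole parameter compartments (BV, HR, SV, BP — 5+7+5+3 = 20
dynamical parameters), which preserves within-compartment plausibility:

* a **mixing** subject takes each of its four compartments whole from one
  of four distinct donors (N^4 ordered assignments in the enumeration);
* an **average** subject takes every compartment as the arithmetic mean of
  three distinct donors (N^3 ordered assignments).

The five baselines (HCT0, BV0, H0, SV0, TPR0) are not donated: they are
resampled per virtual subject from normal distributions centered on the
test subject's measured baselines with a 10% SD, so that credibility
assessment probes dynamic patterns rather than initial conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import BASELINE_NAMES, COMPARTMENTS, PARAM_NAMES, SubjectParameters

__all__ = [
    "VirtualSubject",
    "CohortConfig",
    "compartments",
    "sample_baselines",
    "make_mixing_subject",
    "make_average_subject",
    "count_mixing",
    "count_average",
    "count_total",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "baselines_from_measurements",
]

_COMP_ORDER = ("bv", "hr", "sv", "bp")


def compartments(params: SubjectParameters) -> dict[str, dict[str, float]]:
    """The four dynamical parameter blocks of a subject (baselines excluded)."""
    return {name: params.compartment(name) for name in _COMP_ORDER}


@dataclass(frozen=True)
class VirtualSubject:
    """A generated subject with full construction provenance.

    ``donors`` maps each compartment to the donor subject id(s): one id for
    a mixing subject, a tuple of three for an average subject.
    """

    parameters: SubjectParameters
    kind: str  # "mixing" | "average"
    donors: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.kind not in ("mixing", "average"):
            raise ValueError(f"unknown construction kind {self.kind!r}")


@dataclass
class CohortConfig:
    """Cohort sampling settings: size, baseline SD fraction (default the
    study's 10%), and seed."""

    size: int = 10_000
    baseline_sd_fraction: float = 0.10
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if self.baseline_sd_fraction < 0:
            raise ValueError("baseline SD fraction must be >= 0")


# ---------------------------------------------------------------------------
# Enumeration counts (ordered donor assignment, one donor index per slot)
# ---------------------------------------------------------------------------


def _check_n(n: int) -> int:
    if int(n) != n or n < 1:
        raise ValueError("calibration-set size must be a positive integer")
    return int(n)


def count_mixing(n: int) -> int:
    """Number of mixing constructions from n calibration subjects: n**4."""
    return _check_n(n) ** 4


def count_average(n: int) -> int:
    """Number of average constructions from n calibration subjects: n**3."""
    return _check_n(n) ** 3


def count_total(n: int) -> int:
    """Total virtual-subject pool size: n**4 + n**3."""
    return count_mixing(n) + count_average(n)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def sample_baselines(
    measured: Mapping[str, float],
    sd_fraction: float = 0.10,
    rng: np.random.Generator | int | None = None,
) -> dict[str, float]:
    """Draw the five baselines ~ Normal(measured, sd_fraction * measured),
    independently, redrawing any non-positive value (truncation at 0)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out: dict[str, float] = {}
    for name in BASELINE_NAMES:
        mu = float(measured[name])
        if mu <= 0:
            raise ValueError(f"measured baseline {name} must be positive")
        if sd_fraction == 0:
            out[name] = mu
            continue
        draw = rng.normal(mu, sd_fraction * mu)
        while draw <= 0:
            draw = rng.normal(mu, sd_fraction * mu)
        out[name] = float(draw)
    return out


def _donor_ids(donors: Sequence[SubjectParameters]) -> list[str]:
    ids = [d.subject_id or f"@{i}" for i, d in enumerate(donors)]
    if len(set(ids)) != len(ids):
        raise ValueError("donor subjects must be distinct")
    return ids


def _assemble(values: dict[str, float], baselines: Mapping[str, float]) -> SubjectParameters:
    vals = dict(values)
    for name in BASELINE_NAMES:
        vals[name] = float(baselines[name])
    return SubjectParameters(**{n: vals[n] for n in PARAM_NAMES})


def make_mixing_subject(
    donors: Sequence[SubjectParameters],
    baselines: Mapping[str, float],
    rng: np.random.Generator | int | None = None,
    permute: bool = True,
) -> VirtualSubject:
    """A mixing virtual subject: four distinct donors, one whole compartment
    from each. The compartment-to-donor assignment is randomly permuted
    under ``rng`` (set ``permute=False`` for the positional order BV, HR,
    SV, BP)."""
    if len(donors) != 4:
        raise ValueError("mixing requires exactly 4 donors")
    ids = _donor_ids(donors)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    order = rng.permutation(4) if permute else np.arange(4)
    values: dict[str, float] = {}
    provenance: dict[str, tuple[str, ...]] = {}
    for slot, comp in enumerate(_COMP_ORDER):
        donor = donors[order[slot]]
        values.update(donor.compartment(comp))
        provenance[comp] = (ids[order[slot]],)
    return VirtualSubject(_assemble(values, baselines), "mixing", provenance)


def make_average_subject(
    donors: Sequence[SubjectParameters],
    baselines: Mapping[str, float],
    rng: np.random.Generator | int | None = None,
) -> VirtualSubject:
    """An average virtual subject: every dynamical parameter is the
    arithmetic mean over three distinct donors."""
    if len(donors) != 3:
        raise ValueError("averaging requires exactly 3 donors")
    ids = tuple(_donor_ids(donors))
    values: dict[str, float] = {}
    for comp in _COMP_ORDER:
        for name in COMPARTMENTS[comp]:
            values[name] = float(np.mean([getattr(d, name) for d in donors]))
    provenance = {comp: ids for comp in _COMP_ORDER}
    return VirtualSubject(_assemble(values, baselines), "average", provenance)


def generate_cohort(
    calibration_set: Sequence[SubjectParameters],
    test_baselines: Mapping[str, float],
    cfg: CohortConfig | None = None,
) -> list[VirtualSubject]:
    """Draw a cohort of virtual subjects against one test subject.

    Each draw is a mixing subject with probability N^4/(N^4+N^3) = N/(N+1)
    (matching the relative pool sizes), otherwise an average subject; donor
    tuples are drawn uniformly without repetition. Fully reproducible under
    ``cfg.seed``.
    """
    cfg = cfg or CohortConfig()
    n = len(calibration_set)
    if n < 4:
        raise ValueError("calibration set must contain at least 4 subjects")
    rng = np.random.default_rng(cfg.seed)
    p_mixing = n / (n + 1)
    cohort: list[VirtualSubject] = []
    for _ in range(cfg.size):
        baselines = sample_baselines(test_baselines, cfg.baseline_sd_fraction, rng)
        if rng.random() < p_mixing:
            idx = rng.choice(n, size=4, replace=False)
            vs = make_mixing_subject([calibration_set[i] for i in idx], baselines, rng)
        else:
            idx = rng.choice(n, size=3, replace=False)
            vs = make_average_subject([calibration_set[i] for i in idx], baselines, rng)
        cohort.append(vs)
    return cohort


def baselines_from_measurements(series, bv0: float) -> dict[str, float]:
    """Measured baselines of a test subject from its first measurement:
    HCT0, H0, SV0 read directly, TPR0 derived as BP0/(H0*SV0); BV0 is
    supplied separately (a dye-dilution measurement in the studies)."""
    hct0 = float(series.values["hct"][0])
    h0 = float(series.values["hr"][0])
    sv0 = float(series.values["sv"][0])
    bp0 = float(series.values["bp"][0])
    for name, v in (("HCT0", hct0), ("H0", h0), ("SV0", sv0), ("BP0", bp0)):
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"baseline measurement {name} must be positive")
    return {"HCT0": hct0, "BV0": float(bv0), "H0": h0, "SV0": sv0,
            "TPR0": bp0 / (h0 * sv0)}


# ---------------------------------------------------------------------------
# Cohort I/O: parameter table plus provenance columns
# ---------------------------------------------------------------------------

_PROV_COLS = ("kind", "donor_bv", "donor_hr", "donor_sv", "donor_bp")


def write_cohort(cohort: Sequence[VirtualSubject], path: str | Path,
                 seed: int | None = None) -> None:
    rows = []
    for i, vs in enumerate(cohort):
        row: dict[str, object] = {"subject_id": f"V{i + 1}"}
        row.update(vs.parameters.to_dict())
        row["kind"] = vs.kind
        for comp in _COMP_ORDER:
            row[f"donor_{comp}"] = "|".join(vs.donors[comp])
        row["seed"] = seed
        rows.append(row)
    cols = ["subject_id", *PARAM_NAMES, *_PROV_COLS, "seed"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[VirtualSubject]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("subject_id", *PARAM_NAMES, *_PROV_COLS) if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path}: missing column {missing[0]!r}")
    out = []
    for _, row in df.iterrows():
        params = SubjectParameters(**{n: float(row[n]) for n in PARAM_NAMES},
                                   subject_id=str(row["subject_id"]))
        donors = {comp: tuple(str(row[f"donor_{comp}"]).split("|")) for comp in _COMP_ORDER}
        out.append(VirtualSubject(params, str(row["kind"]), donors))
    return out
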