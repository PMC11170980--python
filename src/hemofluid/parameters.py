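"""Subject parameter sets for the cardiovascular fluid-response model.

The model has 25 parameters per subject: 20 dynamical parameters grouped into
four physiological compartments (blood volume, heart rate, stroke volume,
blood pressure) plus 5 baseline values (HCT0, BV0, H0, SV0, TPR0). A packaged
reference table ships 27 calibrated sheep subjects (LR1-LR22, HEX1-HEX5).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PARAM_NAMES",
    "BASELINE_NAMES",
    "DYNAMIC_NAMES",
    "COMPARTMENTS",
    "SubjectParameters",
    "load_parameter_table",
    "write_parameter_table",
    "load_reference_parameters",
]

#: Canonical column order of the reference table (compartment-blocked).
PARAM_NAMES: tuple[str, ...] = (
    # blood-volume compartment
    "A_U_BV", "A_V_BV", "alpha_U", "alpha_V", "K_P_BV",
    # heart-rate compartment
    "G_U_T", "G_V_T", "G_V_L", "P_U_T", "P_V_L", "K_P_H", "K_I_H",
    # stroke-volume compartment
    "G_BV", "G_HR", "A_SV", "r_SV", "K_P_SV",
    # blood-pressure compartment
    "A_BP", "K_P_BP", "r_BP",
    # baselines
    "HCT0", "BV0", "H0", "SV0", "TPR0",
)

BASELINE_NAMES: tuple[str, ...] = ("HCT0", "BV0", "H0", "SV0", "TPR0")
DYNAMIC_NAMES: tuple[str, ...] = tuple(n for n in PARAM_NAMES if n not in BASELINE_NAMES)

#: The four parameter compartments used by the virtual-cohort generator.
COMPARTMENTS: dict[str, tuple[str, ...]] = {
    "bv": ("A_U_BV", "A_V_BV", "alpha_U", "alpha_V", "K_P_BV"),
    "hr": ("G_U_T", "G_V_T", "G_V_L", "P_U_T", "P_V_L", "K_P_H", "K_I_H"),
    "sv": ("G_BV", "G_HR", "A_SV", "r_SV", "K_P_SV"),
    "bp": ("A_BP", "K_P_BP", "r_BP"),
}

# Stability (relaxation-rate) parameters must be non-positive.
_STABILITY = ("A_U_BV", "A_V_BV", "A_SV", "A_BP")


@dataclass(frozen=True)
class SubjectParameters:
    """The 25 model parameters of one subject.

    Units: A_* in 1/min; alpha_* dimensionless distribution ratios; K_P_BV,
    K_P_H, K_P_SV in 1/min; K_I_H in 1/min^2; G_V_T in bpm/l; G_U_T, G_V_L
    are perturbation gains with power-law rate dependence; G_BV dimensionless;
    G_HR in l/bpm; r_SV in l; K_P_BP in (mmHg.min/l)/mmHg/min; r_BP in mmHg;
    HCT0 in %, BV0 in l, H0 in bpm, SV0 in l, TPR0 in mmHg.min/l.
    """

    A_U_BV: float
    A_V_BV: float
    alpha_U: float
    alpha_V: float
    K_P_BV: float
    G_U_T: float
    G_V_T: float
    G_V_L: float
    P_U_T: float
    P_V_L: float
    K_P_H: float
    K_I_H: float
    G_BV: float
    G_HR: float
    A_SV: float
    r_SV: float
    K_P_SV: float
    A_BP: float
    K_P_BP: float
    r_BP: float
    HCT0: float
    BV0: float
    H0: float
    SV0: float
    TPR0: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} is not finite: {v!r}")
        for name in _STABILITY:
            if getattr(self, name) > 0:
                raise ValueError(f"stability parameter {name} must be <= 0")
        if self.BV0 <= 0:
            raise ValueError("BV0 must be positive")
        if not 0 < self.HCT0 < 50:
            raise ValueError("HCT0 must lie in (0, 50) %")
        if self.H0 <= 0 or self.SV0 <= 0 or self.TPR0 <= 0:
            raise ValueError("H0, SV0 and TPR0 must be positive")

    # -- conversions -----------------------------------------------------
    def to_array(self) -> np.ndarray:
        """The 25 parameters as a float array in canonical order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float], subject_id: str | None = None) -> "SubjectParameters":
        values = list(values)
        if len(values) != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {len(values)}")
        return cls(**dict(zip(PARAM_NAMES, map(float, values))), subject_id=subject_id)

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    def replace(self, **changes: float) -> "SubjectParameters":
        return dataclasses.replace(self, **changes)

    # -- views -----------------------------------------------------------
    def compartment(self, name: str) -> dict[str, float]:
        """One of the four dynamical parameter blocks ('bv','hr','sv','bp')."""
        return {n: getattr(self, n) for n in COMPARTMENTS[name]}

    def baselines(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in BASELINE_NAMES}

    @property
    def BP0(self) -> float:
        """Baseline blood pressure H0*SV0*TPR0 (mmHg)."""
        return self.H0 * self.SV0 * self.TPR0


# ---------------------------------------------------------------------------
# Table I/O (CSV, one row per subject: subject_id + 25 parameter columns)
# ---------------------------------------------------------------------------

_SCHEMA = ("subject_id",) + PARAM_NAMES


def load_parameter_table(path: str | Path) -> list[SubjectParameters]:
    """Read a subject parameter table (CSV, canonical 26-column schema)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in _SCHEMA:
        if col not in df.columns:
            raise ValueError(f"parameter table {path}: missing column {col!r}")
    extra = [c for c in df.columns if c not in _SCHEMA and not c.startswith(("kind", "donor", "seed"))]
    if extra:
        raise ValueError(f"parameter table {path}: unexpected column {extra[0]!r}")
    return [
        SubjectParameters(**{n: float(row[n]) for n in PARAM_NAMES}, subject_id=str(row["subject_id"]))
        for _, row in df.iterrows()
    ]


def write_parameter_table(subjects: Iterable[SubjectParameters], path: str | Path) -> None:
    rows = []
    for i, s in enumerate(subjects):
        row = {"subject_id": s.subject_id or f"S{i + 1}"}
        row.update(s.to_dict())
        rows.append(row)
    pd.DataFrame(rows, columns=list(_SCHEMA)).to_csv(path, index=False)


def load_reference_parameters() -> list[SubjectParameters]:
    """The packaged reference table: 27 sheep subjects (LR1-LR22, HEX1-HEX5)."""
    with resources.as_file(resources.files("hemofluid") / "data" / "calibrated_sheep_parameters.csv") as p:
        subjects = load_parameter_table(p)
    if len(subjects) != 27:
        raise RuntimeError(f"reference table corrupted: expected 27 subjects, found {len(subjects)}")
    return subjects
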