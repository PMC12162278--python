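"""Tracheal reference regressions and demographic normalization.

Published multiple-linear-regression equations predict reference tracheal
diameter (pD, mm), luminal area (pLA, mm^2) and wall thickness (pWT, mm)
from age (years), height (meters) and sex (0 = male, 1 = female):

    pD  = 12.79  - 0.13 log(age) -   5.82 log(height) * sex +  3.01 log(age) log(height)
    pLA = 122.23 - 5.45 log(age) - 148.13 log(height) * sex + 77.75 log(age) log(height)
    pWT = log(9.11) - 1.02 log(age) - 0.98 height^2 * sex + 1.01 height^2 log(age)

The published source does not state the log base; it is a mandatory explicit
parameter (default natural log) and the base used is stamped into every
output. The pWT equation is evaluated exactly as printed, including the
logged leading constant and the height^2 terms. Subject airway metrics are
normalized by dividing by the matching reference value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd

__all__ = ["Demographics", "TracheaReference", "predict_trachea", "normalize",
           "predict_trachea_table"]

LogBase = Literal["natural", "base10"]


@dataclass
class Demographics:
    """Per-subject covariates; weight and BMI are carried but unused by the
    reference equations."""

    age: float  # years
    height: float  # meters
    sex: int  # 0 = male, 1 = female
    weight: float | None = None  # kg
    bmi: float | None = None  # kg/m^2

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.height > 3:
            raise ValueError(
                f"height {self.height} looks like centimeters; the reference "
                "equations require meters (e.g. 1.63, not 163) — convert explicitly"
            )
        if self.sex not in (0, 1):
            raise ValueError("sex must be 0 (male) or 1 (female)")


@dataclass
class TracheaReference:
    """Predicted tracheal reference values and the log base they used."""

    pD: float  # mm
    pLA: float  # mm^2
    pWT: float  # mm
    log_base: LogBase

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.pD, self.pLA, self.pWT))):
            raise ValueError("non-finite reference value")
        if self.pD <= 0 or self.pLA <= 0:
            raise ValueError("pD and pLA must be positive")


def _log(base: LogBase):
    if base == "natural":
        return math.log
    if base == "base10":
        return math.log10
    raise ValueError(f"log_base must be 'natural' or 'base10', got {base!r}")


def predict_trachea(demo: Demographics, log_base: LogBase = "natural") -> TracheaReference:
    """Evaluate the three reference equations verbatim with the chosen log
    base. For sex = 0 the sex-interaction terms contribute exactly 0."""
    log = _log(log_base)
    la, lh = log(demo.age), log(demo.height)
    s, h2 = demo.sex, demo.height**2
    pD = 12.79 - 0.13 * la - 5.82 * lh * s + 3.01 * la * lh
    pLA = 122.23 - 5.45 * la - 148.13 * lh * s + 77.75 * la * lh
    pWT = log(9.11) - 1.02 * la - 0.98 * h2 * s + 1.01 * h2 * la
    return TracheaReference(pD=pD, pLA=pLA, pWT=pWT, log_base=log_base)


def normalize(value: float, reference: float) -> float:
    """Dimensionless ratio value / reference."""
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference}")
    return value / reference


def predict_trachea_table(df: pd.DataFrame, log_base: LogBase = "natural") -> pd.DataFrame:
    """Batch evaluation of a (subject_id, age_years, height_m, sex01) table;
    returns (subject_id, pD_mm, pLA_mm2, pWT_mm, log_base)."""
    rows = []
    for _, r in df.iterrows():
        ref = predict_trachea(
            Demographics(age=float(r["age_years"]), height=float(r["height_m"]),
                         sex=int(r["sex01"])),
            log_base,
        )
        rows.append(
            {
                "subject_id": r["subject_id"],
                "pD_mm": ref.pD,
                "pLA_mm2": ref.pLA,
                "pWT_mm": ref.pWT,
                "log_base": ref.log_base,
            }
        )
    return pd.DataFrame(rows)
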