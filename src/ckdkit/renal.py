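"""GFR estimation and elementary renal classifications.

The creatinine clearance ``C`` (mL/min) is estimated with the Cockcroft-Gault
equation

    C = (140 - I) * K / (72 * P)        (x 0.85 for women)

where ``I`` is age in years, ``K`` weight in kg and ``P`` plasmatic creatinine
in mg/dL.  Cockcroft-Gault is preferred here over MDRD-family equations
because it does not require a race coefficient, which is problematic to
assign in admixed Latin American populations.

Displayed clearances are truncated (not rounded) to one decimal; the
full-precision value is always kept alongside.
"""

from __future__ import annotations

import enum
import functools
import math
from dataclasses import dataclass
from typing import Any, Mapping

from .config import DEFAULTS
from .records import Gender

__all__ = [
    "GfrResult",
    "ProteinuriaCategory",
    "CkdStage",
    "BiomarkerFlag",
    "estimate_gfr",
    "classify_proteinuria",
    "classify_stage",
    "classify_biomarker",
    "truncate_one_decimal",
]

FEMALE_FACTOR = 0.85


@functools.total_ordering
class ProteinuriaCategory(enum.Enum):
    """Albuminuria categories at the 30 / 300 mg/g cut-offs, ordered by severity."""

    NORMAL = "normal"
    MICROALBUMINURIA = "microalbuminuria"
    ALBUMINURIA = "albuminuria"

    @property
    def severity(self) -> int:
        return _PROT_ORDER.index(self)

    def __lt__(self, other: "ProteinuriaCategory") -> bool:
        return self.severity < other.severity


_PROT_ORDER = [
    ProteinuriaCategory.NORMAL,
    ProteinuriaCategory.MICROALBUMINURIA,
    ProteinuriaCategory.ALBUMINURIA,
]


@functools.total_ordering
class CkdStage(enum.Enum):
    """CKD stages 1, 2, 3a, 3b, 4, 5 by GFR band, ordered by severity."""

    S1 = "1"
    S2 = "2"
    S3A = "3a"
    S3B = "3b"
    S4 = "4"
    S5 = "5"

    @property
    def severity(self) -> int:
        return _STAGE_ORDER.index(self)

    def __lt__(self, other: "CkdStage") -> bool:
        return self.severity < other.severity


_STAGE_ORDER = [CkdStage.S1, CkdStage.S2, CkdStage.S3A, CkdStage.S3B, CkdStage.S4, CkdStage.S5]


@dataclass(frozen=True)
class GfrResult:
    """Estimated creatinine clearance, full precision plus display rendering."""

    value: float          # mL/min, full precision
    displayed: float      # one-decimal truncation of value

    def __str__(self) -> str:
        return f"{self.displayed:.1f}"


@dataclass(frozen=True)
class BiomarkerFlag:
    biomarker: str
    status: str  # "low" | "normal" | "high"
    interval: tuple[float, float]
    unit: str
    value: float


def truncate_one_decimal(value: float) -> float:
    """Truncate toward zero at one decimal (155.774 -> 155.7, never 155.8)."""
    return math.trunc(value * 10.0) / 10.0


def estimate_gfr(age: float, weight: float, creatinine: float, gender: Gender) -> GfrResult:
    """Cockcroft-Gault creatinine clearance.

    Parameters
    ----------
    age : years (must be < 140 for a positive estimate)
    weight : kg, > 0
    creatinine : plasmatic creatinine in mg/dL, > 0
    gender : FEMALE applies the 0.85 factor, MALE a factor of 1

    Raises
    ------
    ValueError on inputs outside the equation's domain.
    """
    if age >= 140:
        raise ValueError("age must be below 140 years for a positive clearance")
    if weight <= 0:
        raise ValueError("weight must be positive")
    if creatinine <= 0:
        raise ValueError("creatinine must be positive")
    value = (140.0 - age) * weight / (creatinine * 72.0)
    if gender is Gender.FEMALE:
        value *= FEMALE_FACTOR
    return GfrResult(value=value, displayed=truncate_one_decimal(value))


def classify_proteinuria(
    value: float, config: Mapping[str, Any] | None = None
) -> ProteinuriaCategory:
    """Classify an albumin-to-creatinine ratio (mg/g).

    ``< 30`` normal, ``[30, 300)`` microalbuminuria, ``>= 300`` albuminuria
    under the default cut-offs; both cut-offs configurable.
    """
    if value < 0:
        raise ValueError("proteinuria value must be non-negative")
    cfg = (config or DEFAULTS)["proteinuria"]
    micro, albu = float(cfg["microalbuminuria"]), float(cfg["albuminuria"])
    if value < micro:
        return ProteinuriaCategory.NORMAL
    if value < albu:
        return ProteinuriaCategory.MICROALBUMINURIA
    return ProteinuriaCategory.ALBUMINURIA


def classify_stage(gfr: float, config: Mapping[str, Any] | None = None) -> CkdStage:
    """Map a GFR (mL/min) to its CKD stage.

    Half-open bands, each boundary owned by the less-severe stage:
    >=90 stage 1, [60,90) stage 2, [45,60) 3a, [30,45) 3b, [15,30) 4, <15 stage 5.
    """
    if not (gfr > 0):
        raise ValueError("GFR must be positive")
    bands = (config or DEFAULTS)["stages"]["bands"]
    for stage in _STAGE_ORDER[:-1]:
        if gfr >= float(bands[stage.value]):
            return stage
    return CkdStage.S5


def classify_biomarker(
    name: str, value: float, config: Mapping[str, Any] | None = None
) -> BiomarkerFlag:
    """Flag a serum biomarker against its closed reference interval.

    Endpoints count as normal (a urea of exactly 20.0 is in range).
    """
    if value < 0:
        raise ValueError(f"{name} value must be non-negative")
    biomarkers = (config or DEFAULTS)["biomarkers"]
    if name not in biomarkers:
        raise KeyError(
            f"unknown biomarker {name!r}; known: {sorted(biomarkers)}"
        )
    ref = biomarkers[name]
    low, high = float(ref["low"]), float(ref["high"])
    if value < low:
        status = "low"
    elif value > high:
        status = "high"
    else:
        status = "normal"
    return BiomarkerFlag(
        biomarker=name, status=status, interval=(low, high),
        unit=str(ref.get("unit", "")), value=value,
    )
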