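"""Executable CKD risk-identification workflow.

The decision pipeline mirrors the screening procedure nephrologists apply by
hand: verify proteinuria, estimate/stage the GFR, then read the KDIGO-style
stage x albuminuria risk grid.  The pipeline is deliberately a chain of the
elementary classifications so each run produces exactly one of the four risk
levels, and the terminal-state enumerator drives the same chain over every
category x stage combination (18 reachable outcomes).

The 18-cell risk grid ships as data (``config.DEFAULTS['risk_matrix']``) and
is validated for totality and monotonicity when loaded: worsening the stage at
fixed albuminuria, or the albuminuria at fixed stage, never lowers the risk.
"""

from __future__ import annotations

import datetime as dt
import enum
import functools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping

from .config import DEFAULTS
from .records import PatientRecord
from .renal import (
    BiomarkerFlag,
    CkdStage,
    GfrResult,
    ProteinuriaCategory,
    _STAGE_ORDER,
    _PROT_ORDER,
    classify_biomarker,
    classify_proteinuria,
    classify_stage,
    estimate_gfr,
)

__all__ = [
    "RiskLevel",
    "RiskMatrix",
    "RiskEvaluation",
    "TerminalState",
    "IncompletePanelError",
    "run_workflow",
    "evaluate_risk",
    "enumerate_terminal_states",
    "next_screening_due",
    "append_history",
    "read_history",
]


@functools.total_ordering
class RiskLevel(enum.Enum):
    """Four-level CKD development risk, ordered."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    VERY_HIGH = "very_high"

    @property
    def severity(self) -> int:
        return _RISK_ORDER.index(self)

    @property
    def label(self) -> str:
        return _RISK_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "RiskLevel":
        key = label.strip().lower().replace("_", " ")
        for level, text in _RISK_LABELS.items():
            if key in (text.lower(), level.value.replace("_", " ")):
                return level
        raise ValueError(f"unknown risk label {label!r}")

    def __lt__(self, other: "RiskLevel") -> bool:
        return self.severity < other.severity


_RISK_ORDER = [RiskLevel.LOW, RiskLevel.MODERATE, RiskLevel.HIGH, RiskLevel.VERY_HIGH]
_RISK_LABELS = {
    RiskLevel.LOW: "Low risk",
    RiskLevel.MODERATE: "Moderate risk",
    RiskLevel.HIGH: "High risk",
    RiskLevel.VERY_HIGH: "Very high risk",
}


class IncompletePanelError(ValueError):
    """The record lacks data required for an evaluation; never partial output."""

    def __init__(self, missing: list[str]):
        super().__init__("incomplete panel: missing " + ", ".join(missing))
        self.missing = missing


@dataclass(frozen=True)
class RiskMatrix:
    """Total, monotone mapping (stage, albuminuria category) -> risk level."""

    cells: Mapping[tuple[CkdStage, ProteinuriaCategory], RiskLevel]

    @classmethod
    def from_config(
        cls, config: Mapping[str, Any] | None = None, allow_non_monotone: bool = False
    ) -> "RiskMatrix":
        """Build and validate the grid from configuration.

        A grid missing any of the 18 cells is always rejected; one that breaks
        monotonicity is rejected unless ``allow_non_monotone`` is set, in
        which case a warning is emitted instead.
        """
        raw = (config or DEFAULTS)["risk_matrix"]
        cells: dict[tuple[CkdStage, ProteinuriaCategory], RiskLevel] = {}
        for stage in _STAGE_ORDER:
            for category in _PROT_ORDER:
                try:
                    level_name = raw[stage.value][category.value]
                except KeyError:
                    raise ValueError(
                        f"risk matrix incomplete: missing cell ({stage.value}, {category.value})"
                    ) from None
                cells[(stage, category)] = RiskLevel(level_name)
        matrix = cls(cells=dict(cells))
        problems = matrix._monotonicity_violations()
        if problems:
            message = "risk matrix not monotone: " + "; ".join(problems)
            if allow_non_monotone:
                warnings.warn(message, stacklevel=2)
            else:
                raise ValueError(message)
        return matrix

    def _monotonicity_violations(self) -> list[str]:
        problems = []
        for category in _PROT_ORDER:
            for a, b in zip(_STAGE_ORDER, _STAGE_ORDER[1:]):
                if self.cells[(b, category)] < self.cells[(a, category)]:
                    problems.append(f"stage {b.value} < stage {a.value} at {category.value}")
        for stage in _STAGE_ORDER:
            for a, b in zip(_PROT_ORDER, _PROT_ORDER[1:]):
                if self.cells[(stage, b)] < self.cells[(stage, a)]:
                    problems.append(f"{b.value} < {a.value} at stage {stage.value}")
        return problems

    def lookup(self, stage: CkdStage, category: ProteinuriaCategory) -> RiskLevel:
        return self.cells[(stage, category)]

    def __iter__(self) -> Iterator[tuple[CkdStage, ProteinuriaCategory, RiskLevel]]:
        for (stage, category), level in self.cells.items():
            yield stage, category, level


@dataclass(frozen=True)
class TerminalState:
    """One reachable final classification of the workflow."""

    category: ProteinuriaCategory
    stage: CkdStage
    risk: RiskLevel


@dataclass
class RiskEvaluation:
    """Complete outcome of one risk evaluation."""

    record_id: str
    category: ProteinuriaCategory
    stage: CkdStage
    risk: RiskLevel
    gfr: GfrResult
    biomarker_flags: dict[str, BiomarkerFlag] = field(default_factory=dict)
    has_dm: bool = False
    has_sah: bool = False
    advice: str = ""
    timestamp: dt.datetime = field(default_factory=dt.datetime.now)

    def to_dict(self) -> dict[str, Any]:
        return {
            "record_id": self.record_id,
            "category": self.category.value,
            "stage": self.stage.value,
            "risk": self.risk.value,
            "gfr": self.gfr.value,
            "gfr_displayed": self.gfr.displayed,
            "biomarker_flags": {
                name: {"status": f.status, "value": f.value, "unit": f.unit}
                for name, f in self.biomarker_flags.items()
            },
            "has_dm": self.has_dm,
            "has_sah": self.has_sah,
            "advice": self.advice,
            "timestamp": self.timestamp.isoformat(),
        }


def run_workflow(
    proteinuria: float,
    gfr: float,
    config: Mapping[str, Any] | None = None,
    matrix: RiskMatrix | None = None,
) -> TerminalState:
    """Drive the three-step decision chain for one (proteinuria, GFR) pair.

    This is the core workflow: albuminuria-category verification, stage
    classification, then the risk-grid lookup.  Exactly one terminal state is
    produced for any valid input pair.
    """
    config = config or DEFAULTS
    matrix = matrix or RiskMatrix.from_config(config)
    category = classify_proteinuria(proteinuria, config)
    stage = classify_stage(gfr, config)
    return TerminalState(category=category, stage=stage, risk=matrix.lookup(stage, category))


_REQUIRED_FOR_EVALUATION = ("creatinine", "proteinuria", "age", "weight", "gender")


def evaluate_risk(
    record: PatientRecord,
    config: Mapping[str, Any] | None = None,
    matrix: RiskMatrix | None = None,
    timestamp: dt.datetime | None = None,
) -> RiskEvaluation:
    """Full per-record evaluation: workflow outcome plus biomarker and
    comorbidity annotations and referral advice.

    Raises :class:`IncompletePanelError` when creatinine, proteinuria, age,
    weight or gender is missing — an explicit refusal, never a partial result.
    The comorbidity and biomarker flags annotate the narrative; they do not
    alter the grid risk level.
    """
    config = config or DEFAULTS
    missing = [
        name for name in _REQUIRED_FOR_EVALUATION
        if (getattr(record.labs, name, None) is None
            if name in ("creatinine", "proteinuria")
            else getattr(record, name, None) is None)
    ]
    if missing:
        raise IncompletePanelError(missing)

    gfr = estimate_gfr(record.age, record.weight, record.labs.creatinine, record.gender)
    outcome = run_workflow(record.labs.proteinuria, gfr.value, config, matrix)

    flags: dict[str, BiomarkerFlag] = {}
    for name in ("creatinine", "urea", "potassium"):
        value = getattr(record.labs, name)
        if value is not None:
            flags[name] = classify_biomarker(name, value, config)

    return RiskEvaluation(
        record_id=record.id,
        category=outcome.category,
        stage=outcome.stage,
        risk=outcome.risk,
        gfr=gfr,
        biomarker_flags=flags,
        has_dm=record.has_dm,
        has_sah=record.has_sah,
        advice=_advice(outcome.risk),
        timestamp=timestamp or dt.datetime.now(),
    )


def _advice(risk: RiskLevel) -> str:
    if risk is RiskLevel.LOW:
        return "Low risk of CKD development. Keep up periodic screening."
    if risk is RiskLevel.MODERATE:
        return ("Moderate risk of CKD development. A face-to-face consultation "
                "with a physician is recommended.")
    if risk is RiskLevel.HIGH:
        return ("Alert: high risk of CKD development. Referral to a nephrologist "
                "for confirmation is recommended.")
    return ("Alert: very high risk of CKD development. Seek a nephrologist "
            "as soon as possible.")


def enumerate_terminal_states(
    config: Mapping[str, Any] | None = None,
) -> list[TerminalState]:
    """Exhaustively drive the workflow over every category x stage cell.

    Representative proteinuria and GFR inputs are derived from the configured
    band edges, so the enumeration exercises the real decision chain rather
    than reading the grid directly.  Returns each reachable terminal exactly
    once (18 under the default six-stage, three-category configuration).
    """
    config = config or DEFAULTS
    matrix = RiskMatrix.from_config(config)
    prot_cfg = config["proteinuria"]
    micro, albu = float(prot_cfg["microalbuminuria"]), float(prot_cfg["albuminuria"])
    prot_values = {
        ProteinuriaCategory.NORMAL: micro / 2.0,
        ProteinuriaCategory.MICROALBUMINURIA: (micro + albu) / 2.0,
        ProteinuriaCategory.ALBUMINURIA: albu * 2.0,
    }
    bands = config["stages"]["bands"]
    edges = [float(bands[s.value]) for s in _STAGE_ORDER[:-1]]  # descending
    gfr_values: dict[CkdStage, float] = {}
    for i, stage in enumerate(_STAGE_ORDER[:-1]):
        upper = edges[i - 1] if i > 0 else edges[0] + 30.0
        gfr_values[stage] = (edges[i] + upper) / 2.0
    gfr_values[CkdStage.S5] = edges[-1] / 2.0

    seen: dict[tuple[ProteinuriaCategory, CkdStage], TerminalState] = {}
    for category in _PROT_ORDER:
        for stage in _STAGE_ORDER:
            state = run_workflow(prot_values[category], gfr_values[stage], config, matrix)
            assert state.category is category and state.stage is stage
            seen[(category, stage)] = state
    return list(seen.values())


def next_screening_due(
    evaluation: RiskEvaluation,
    today: dt.date | None = None,
    config: Mapping[str, Any] | None = None,
) -> dt.date:
    """Date the next screening test is due, from the risk-dependent interval.

    The interval table (months per risk level) comes from configuration and is
    checked to be monotone: a higher risk never yields a longer interval.
    ``today`` is only used when the configured interval is zero or negative,
    in which case the screening is due immediately.
    """
    config = config or DEFAULTS
    intervals = config["screening_intervals_months"]
    months = [int(intervals[level.value]) for level in _RISK_ORDER]
    if any(b > a for a, b in zip(months, months[1:])):
        raise ValueError(f"screening intervals not monotone in risk: {months}")
    interval = int(intervals[evaluation.risk.value])
    if interval <= 0:
        return today or dt.date.today()
    return _add_months(evaluation.timestamp.date(), interval)


def _add_months(day: dt.date, months: int) -> dt.date:
    month_index = day.month - 1 + months
    year = day.year + month_index // 12
    month = month_index % 12 + 1
    # clamp to the target month's length (Jan 31 + 1 month -> Feb 28/29)
    last = [31, 29 if _leap(year) else 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31][month - 1]
    return dt.date(year, month, min(day.day, last))


def _leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


# ---------------------------------------------------------------------------
# evaluation history (append-only JSON lines)

def append_history(path: str | Path, evaluation: RiskEvaluation) -> None:
    """Append one evaluation to the JSON-lines history file."""
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(evaluation.to_dict()) + "\n")


def read_history(path: str | Path) -> list[dict[str, Any]]:
    """Read the evaluation history back as a list of dictionaries."""
    entries = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                entries.append(json.loads(line))
    return entries
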