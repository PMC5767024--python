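"""Personal health record data model, validation, persistence, and alerting.

Records carry the demographics, comorbidity flags (systemic arterial
hypertension, diabetes mellitus) and the lab panel needed to screen for
chronic kidney disease.  The CSV dialect mirrors the cohort-table layout used
in the screening study this toolkit supports: header
``ID,SAH,DM,Creatinine,Urea,Microalbuminuria,Potassium,Weight,Age,Gender,GFR``,
an ``X`` marking a comorbidity as present, a blank cell marking a lab value as
absent, and ``F``/``M`` gender codes.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

__all__ = [
    "Gender",
    "BiomarkerPanel",
    "Medication",
    "Allergy",
    "PatientRecord",
    "ValidationFinding",
    "Alert",
    "RecordParseError",
    "validate_record",
    "load_records",
    "save_records",
    "check_medication_alerts",
    "CSV_HEADER",
]

CSV_HEADER = [
    "ID", "SAH", "DM", "Creatinine", "Urea", "Microalbuminuria",
    "Potassium", "Weight", "Age", "Gender", "GFR",
]

ADULT_AGE = 18


class Gender(enum.Enum):
    """Biological sex as used by the Cockcroft-Gault equation."""

    FEMALE = "F"
    MALE = "M"

    @classmethod
    def from_code(cls, code: str) -> "Gender":
        try:
            return cls(code.strip().upper())
        except ValueError:
            raise ValueError(f"unknown gender code {code!r} (expected F or M)") from None


@dataclass
class BiomarkerPanel:
    """Lab panel for one subject; every value is optional (labs go missing).

    Units: creatinine and urea in mg/dL, potassium in mEq/L, proteinuria as an
    albumin-to-creatinine ratio in mg/g.
    """

    creatinine: float | None = None
    urea: float | None = None
    potassium: float | None = None
    proteinuria: float | None = None
    collected_on: str | None = None  # ISO date, optional

    def as_dict(self) -> dict[str, Any]:
        return {
            "creatinine": self.creatinine,
            "urea": self.urea,
            "potassium": self.potassium,
            "proteinuria": self.proteinuria,
            "collected_on": self.collected_on,
        }


@dataclass
class Medication:
    substance: str
    dose: str = ""
    schedule: str = ""


@dataclass
class Allergy:
    substance: str
    reaction: str | None = None


@dataclass
class PatientRecord:
    id: str
    gender: Gender
    age: int
    weight: float
    has_sah: bool = False
    has_dm: bool = False
    labs: BiomarkerPanel = field(default_factory=BiomarkerPanel)
    medications: list[Medication] = field(default_factory=list)
    allergies: list[Allergy] = field(default_factory=list)
    monitoring_log: list[dict[str, Any]] = field(default_factory=list)
    #: GFR as recorded in the source table, kept as data (never recomputed here)
    gfr_reported: float | None = None


@dataclass(frozen=True)
class ValidationFinding:
    """One violated invariant: which field, which rule."""

    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


class RecordParseError(ValueError):
    """Malformed row or document; names the offending row and column."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


def validate_record(record: PatientRecord) -> list[ValidationFinding]:
    """Check every record invariant; return findings (empty iff all hold).

    Findings, not exceptions: screening workflows want to report all problems
    of a record at once rather than fail on the first.
    """
    findings: list[ValidationFinding] = []
    if not record.id:
        findings.append(ValidationFinding("id", "identifier empty"))
    if not isinstance(record.gender, Gender):
        findings.append(ValidationFinding("gender", "not a recognized gender"))
    if record.age < ADULT_AGE:
        findings.append(ValidationFinding("age", "age below adult scope (>= 18 required)"))
    if not (record.weight > 0):
        findings.append(ValidationFinding("weight", "weight non-positive"))
    for name in ("creatinine", "urea", "potassium", "proteinuria"):
        value = getattr(record.labs, name)
        if value is None:
            continue
        if not math.isfinite(value) or value < 0:
            findings.append(ValidationFinding(f"labs.{name}", "lab value must be a non-negative finite number"))
    for i, med in enumerate(record.medications):
        if not med.substance:
            findings.append(ValidationFinding(f"medications[{i}].substance", "substance empty"))
    for i, allergy in enumerate(record.allergies):
        if not allergy.substance:
            findings.append(ValidationFinding(f"allergies[{i}].substance", "substance empty"))
    return findings


# ---------------------------------------------------------------------------
# persistence

def _parse_optional_float(cell: str, row: int, column: str) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise RecordParseError(
            f"row {row}: column {column!r} has non-numeric value {cell!r}",
            row=row, column=column,
        ) from None


def _record_from_csv_row(cells: Sequence[str], row_number: int) -> PatientRecord:
    values = dict(zip(CSV_HEADER, cells))
    if len(cells) != len(CSV_HEADER):
        raise RecordParseError(
            f"row {row_number}: expected {len(CSV_HEADER)} cells, got {len(cells)}",
            row=row_number,
        )
    try:
        gender = Gender.from_code(values["Gender"])
    except ValueError as exc:
        raise RecordParseError(f"row {row_number}: {exc}", row=row_number, column="Gender") from None
    age = _parse_optional_float(values["Age"], row_number, "Age")
    weight = _parse_optional_float(values["Weight"], row_number, "Weight")
    if age is None or weight is None:
        raise RecordParseError(
            f"row {row_number}: Age and Weight are mandatory", row=row_number,
            column="Age" if age is None else "Weight",
        )
    labs = BiomarkerPanel(
        creatinine=_parse_optional_float(values["Creatinine"], row_number, "Creatinine"),
        urea=_parse_optional_float(values["Urea"], row_number, "Urea"),
        potassium=_parse_optional_float(values["Potassium"], row_number, "Potassium"),
        proteinuria=_parse_optional_float(values["Microalbuminuria"], row_number, "Microalbuminuria"),
    )
    return PatientRecord(
        id=values["ID"].strip(),
        gender=gender,
        age=int(age),
        weight=weight,
        has_sah=values["SAH"].strip().upper() == "X",
        has_dm=values["DM"].strip().upper() == "X",
        labs=labs,
        gfr_reported=_parse_optional_float(values["GFR"], row_number, "GFR"),
    )


def record_to_dict(record: PatientRecord) -> dict[str, Any]:
    return {
        "id": record.id,
        "gender": record.gender.value,
        "age": record.age,
        "weight": record.weight,
        "has_sah": record.has_sah,
        "has_dm": record.has_dm,
        "labs": record.labs.as_dict(),
        "medications": [vars(m) for m in record.medications],
        "allergies": [vars(a) for a in record.allergies],
        "monitoring_log": record.monitoring_log,
        "gfr_reported": record.gfr_reported,
    }


def record_from_dict(data: dict[str, Any]) -> PatientRecord:
    labs = data.get("labs") or {}
    return PatientRecord(
        id=str(data["id"]),
        gender=Gender.from_code(data["gender"]),
        age=int(data["age"]),
        weight=float(data["weight"]),
        has_sah=bool(data.get("has_sah", False)),
        has_dm=bool(data.get("has_dm", False)),
        labs=BiomarkerPanel(
            creatinine=labs.get("creatinine"),
            urea=labs.get("urea"),
            potassium=labs.get("potassium"),
            proteinuria=labs.get("proteinuria"),
            collected_on=labs.get("collected_on"),
        ),
        medications=[Medication(**m) for m in data.get("medications", [])],
        allergies=[Allergy(**a) for a in data.get("allergies", [])],
        monitoring_log=list(data.get("monitoring_log", [])),
        gfr_reported=data.get("gfr_reported"),
    )


def load_records(path: str | Path) -> list[PatientRecord]:
    """Load patient records from a cohort-table CSV or a JSON array.

    The format is chosen by file suffix.  Blank CSV cells become absent
    optional labs (real charts frequently lack proteinuria, for example).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        return [record_from_dict(item) for item in data]
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RecordParseError("empty file: missing header row") from None
        if [h.strip() for h in header] != CSV_HEADER:
            raise RecordParseError(
                f"unexpected header {header!r}; expected {CSV_HEADER!r}"
            )
        records = []
        for row_number, cells in enumerate(reader, start=2):
            if not any(cell.strip() for cell in cells):
                continue
            records.append(_record_from_csv_row(cells, row_number))
    return records


def save_records(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records back out in the same dialect ``load_records`` reads."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([record_to_dict(r) for r in records], fh, indent=2)
        return
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in records:
            writer.writerow([
                r.id,
                "X" if r.has_sah else "",
                "X" if r.has_dm else "",
                _fmt(r.labs.creatinine),
                _fmt(r.labs.urea),
                _fmt(r.labs.proteinuria),
                _fmt(r.labs.potassium),
                _fmt(r.weight),
                r.age,
                r.gender.value,
                _fmt(r.gfr_reported),
            ])


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


# ---------------------------------------------------------------------------
# medication / allergy alerting

@dataclass(frozen=True)
class Alert:
    """A medication safety alert: an allergy hit or a drug-drug interaction."""

    kind: str  # "allergy" | "interaction"
    substances: tuple[str, ...]
    message: str


def check_medication_alerts(
    medications: Sequence[Medication],
    allergies: Sequence[Allergy],
    interactions: Iterable[tuple[str, str]] = (),
) -> list[Alert]:
    """Flag allergy conflicts and drug-drug interactions.

    Substance matching is case-insensitive and exact.  The interaction table
    is an unordered pair list supplied by the caller (no interaction knowledge
    is bundled).  Alerts are deduplicated, so repeated medications or mirrored
    interaction pairs produce a single alert each.
    """
    allergy_substances = {a.substance.strip().lower(): a for a in allergies if a.substance}
    interaction_pairs = {
        frozenset((a.strip().lower(), b.strip().lower())) for a, b in interactions
    }
    alerts: dict[tuple[str, frozenset[str]], Alert] = {}

    for med in medications:
        key = med.substance.strip().lower()
        if key in allergy_substances:
            alerts[("allergy", frozenset((key,)))] = Alert(
                kind="allergy",
                substances=(med.substance,),
                message=f"patient is allergic to {med.substance}",
            )

    substances = [m.substance for m in medications if m.substance]
    for i, first in enumerate(substances):
        for second in substances[i + 1:]:
            pair = frozenset((first.strip().lower(), second.strip().lower()))
            if len(pair) == 2 and pair in interaction_pairs:
                if ("interaction", pair) not in alerts:
                    alerts[("interaction", pair)] = Alert(
                        kind="interaction",
                        substances=tuple(sorted((first, second), key=str.lower)),
                        message=f"interaction between {first} and {second}",
                    )
    return list(alerts.values())
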