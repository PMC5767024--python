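"""Simplified CDA-style clinical document exchange.

Risk evaluations and the personal health record behind them are shared as
structured XML documents so a physician (or another installation of the
toolkit) can reuse an initial screening result during later evaluations.  The
document layout is a deliberately small, fully documented template in the
spirit of HL7 CDA R2 — a header with patient demographics, author and
effective time, followed by medications, allergies, lab-results and
risk-evaluation sections — not a conformant CDA implementation; terminology
codes are out of scope.  Every built document validates against the schema
shipped at ``data/cda_lite.xsd``; unknown sections in a foreign namespace are
preserved through a parse as opaque blocks.

Timestamps are injected by the caller, which makes output byte-deterministic
for fixed inputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from lxml import etree

from .records import Allergy, BiomarkerPanel, Gender, Medication, PatientRecord, validate_record
from .renal import CkdStage, GfrResult, ProteinuriaCategory, truncate_one_decimal
from .risk import RiskEvaluation, RiskLevel

__all__ = [
    "NAMESPACE",
    "AUTHOR_ID",
    "ParsedDocument",
    "CdaError",
    "build_document",
    "parse_document",
    "validate_against_schema",
]

NAMESPACE = "urn:ckdkit:cda-lite:1"
AUTHOR_ID = "ckdkit"
_NS = {"c": NAMESPACE}

_LAB_UNITS = {
    "creatinine": "mg/dL",
    "urea": "mg/dL",
    "potassium": "mEq/L",
    "proteinuria": "mg/g",
}


class CdaError(ValueError):
    """Malformed or incomplete clinical document; names the element at fault."""


@dataclass
class ParsedDocument:
    """Fragments recovered from a clinical document."""

    record: PatientRecord
    evaluation: RiskEvaluation | None
    effective_time: dt.datetime
    #: unknown foreign-namespace sections, preserved verbatim
    extensions: list[etree._Element] = field(default_factory=list)


def _qn(tag: str) -> str:
    return f"{{{NAMESPACE}}}{tag}"


def build_document(
    record: PatientRecord,
    evaluation: RiskEvaluation | None = None,
    effective_time: dt.datetime | None = None,
    extensions: list[etree._Element] | None = None,
) -> bytes:
    """Serialize a record (and optionally its evaluation) to document bytes.

    The record must pass :func:`ckdkit.records.validate_record`; an invalid
    record is refused.  ``effective_time`` defaults to now — pass it
    explicitly for deterministic output.
    """
    findings = validate_record(record)
    if findings:
        raise CdaError(
            "refusing to export invalid record: " + "; ".join(map(str, findings))
        )
    effective_time = effective_time or dt.datetime.now()

    root = etree.Element(_qn("ClinicalDocument"), nsmap={None: NAMESPACE})
    header = etree.SubElement(root, _qn("header"))
    etree.SubElement(
        header, _qn("patient"),
        id=record.id, gender=record.gender.value, age=str(record.age),
        weight=_num(record.weight),
        sah=_bool(record.has_sah), dm=_bool(record.has_dm),
    )
    etree.SubElement(header, _qn("author"), id=AUTHOR_ID)
    etree.SubElement(header, _qn("effectiveTime")).text = effective_time.isoformat()

    meds = etree.SubElement(root, _qn("medications"))
    for m in record.medications:
        etree.SubElement(meds, _qn("medication"), substance=m.substance,
                         dose=m.dose, schedule=m.schedule)
    allergies = etree.SubElement(root, _qn("allergies"))
    for a in record.allergies:
        attrs = {"substance": a.substance}
        if a.reaction is not None:
            attrs["reaction"] = a.reaction
        etree.SubElement(allergies, _qn("allergy"), **attrs)

    labs = etree.SubElement(root, _qn("labResults"))
    for name in ("creatinine", "urea", "potassium", "proteinuria"):
        value = getattr(record.labs, name)
        if value is not None:
            attrs = {"name": name, "value": _num(value), "unit": _LAB_UNITS[name]}
            if record.labs.collected_on:
                attrs["date"] = record.labs.collected_on
            etree.SubElement(labs, _qn("lab"), **attrs)

    evaluation_el = etree.SubElement(
        root, _qn("riskEvaluation"), present=_bool(evaluation is not None)
    )
    if evaluation is not None:
        etree.SubElement(evaluation_el, _qn("proteinuriaCategory")).text = evaluation.category.value
        etree.SubElement(evaluation_el, _qn("stage")).text = evaluation.stage.value
        etree.SubElement(evaluation_el, _qn("riskLevel")).text = evaluation.risk.value
        etree.SubElement(evaluation_el, _qn("gfr")).text = _num(evaluation.gfr.value)
        etree.SubElement(evaluation_el, _qn("narrative")).text = evaluation.advice
        etree.SubElement(evaluation_el, _qn("timestamp")).text = evaluation.timestamp.isoformat()

    for extra in extensions or []:
        root.append(extra)

    document = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    validate_against_schema(document)
    return document


def parse_document(data: bytes) -> ParsedDocument:
    """Recover the record and evaluation fragments from document bytes.

    Raises :class:`CdaError` naming the missing element when the header is
    incomplete, and preserves unknown foreign-namespace sections untouched.
    """
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise CdaError(f"malformed XML: {exc}") from None
    if root.tag != _qn("ClinicalDocument"):
        raise CdaError(f"unexpected root element {root.tag!r}")

    patient = root.find("c:header/c:patient", _NS)
    if patient is None:
        raise CdaError("header incomplete: missing patient element")
    for attr in ("id", "gender", "age", "weight"):
        if patient.get(attr) in (None, ""):
            raise CdaError(f"header incomplete: patient element missing {attr!r}")
    time_el = root.find("c:header/c:effectiveTime", _NS)
    if time_el is None or not time_el.text:
        raise CdaError("header incomplete: missing effectiveTime element")

    labs = BiomarkerPanel()
    for lab in root.findall("c:labResults/c:lab", _NS):
        name = lab.get("name")
        if name in _LAB_UNITS:
            setattr(labs, name, float(lab.get("value")))
            if lab.get("date"):
                labs.collected_on = lab.get("date")

    record = PatientRecord(
        id=patient.get("id"),
        gender=Gender.from_code(patient.get("gender")),
        age=int(patient.get("age")),
        weight=float(patient.get("weight")),
        has_sah=patient.get("sah") == "true",
        has_dm=patient.get("dm") == "true",
        labs=labs,
        medications=[
            Medication(substance=m.get("substance"), dose=m.get("dose") or "",
                       schedule=m.get("schedule") or "")
            for m in root.findall("c:medications/c:medication", _NS)
        ],
        allergies=[
            Allergy(substance=a.get("substance"), reaction=a.get("reaction"))
            for a in root.findall("c:allergies/c:allergy", _NS)
        ],
    )

    evaluation = None
    evaluation_el = root.find("c:riskEvaluation", _NS)
    if evaluation_el is not None and evaluation_el.get("present") == "true":
        gfr_value = float(evaluation_el.findtext("c:gfr", namespaces=_NS))
        evaluation = RiskEvaluation(
            record_id=record.id,
            category=ProteinuriaCategory(evaluation_el.findtext("c:proteinuriaCategory", namespaces=_NS)),
            stage=CkdStage(evaluation_el.findtext("c:stage", namespaces=_NS)),
            risk=RiskLevel(evaluation_el.findtext("c:riskLevel", namespaces=_NS)),
            gfr=GfrResult(value=gfr_value, displayed=truncate_one_decimal(gfr_value)),
            has_dm=record.has_dm,
            has_sah=record.has_sah,
            advice=evaluation_el.findtext("c:narrative", namespaces=_NS) or "",
            timestamp=dt.datetime.fromisoformat(
                evaluation_el.findtext("c:timestamp", namespaces=_NS)
            ),
        )

    known = {_qn(t) for t in ("header", "medications", "allergies", "labResults", "riskEvaluation")}
    extensions = [child for child in root if child.tag not in known]

    return ParsedDocument(
        record=record,
        evaluation=evaluation,
        effective_time=dt.datetime.fromisoformat(time_el.text),
        extensions=extensions,
    )


_schema_cache: etree.XMLSchema | None = None


def _schema() -> etree.XMLSchema:
    global _schema_cache
    if _schema_cache is None:
        source = resources.files("ckdkit").joinpath("data/cda_lite.xsd")
        with resources.as_file(source) as path:
            _schema_cache = etree.XMLSchema(etree.parse(str(path)))
    return _schema_cache


def validate_against_schema(data: bytes) -> None:
    """Raise :class:`CdaError` unless ``data`` validates against the schema."""
    document = etree.fromstring(data)
    schema = _schema()
    if not schema.validate(document):
        raise CdaError(f"document does not validate: {schema.error_log.last_error}")


def _num(value: float) -> str:
    text = repr(float(value))
    if "e" in text or "E" in text:  # xs:decimal forbids exponent notation
        text = format(float(value), ".12f").rstrip("0").rstrip(".") or "0"
    return text


def _bool(value: bool) -> str:
    return "true" if value else "false"
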