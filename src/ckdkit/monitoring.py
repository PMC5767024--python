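"""Self-monitoring of the two main CKD risk factors.

Blood-pressure readings (systemic arterial hypertension) and blood-glucose
readings (diabetes mellitus) are classified against configurable guideline
targets and answered with a one-line feedback message, whether they were typed
in manually or ingested from a sensor stream.  Sensor transport is mocked
behind :func:`ingest_sensor_value`; a tagged item yields a reading whose
downstream behaviour is identical to manual entry.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from .config import DEFAULTS

__all__ = [
    "Source",
    "GlucoseContext",
    "BloodPressureReading",
    "GlucoseReading",
    "BpStatus",
    "GlucoseStatus",
    "Assessment",
    "classify_blood_pressure",
    "classify_glucose",
    "ingest_sensor_value",
    "append_reading",
]

logger = logging.getLogger(__name__)


class Source(enum.Enum):
    MANUAL = "manual"
    SENSOR = "sensor"


class GlucoseContext(enum.Enum):
    PREPRANDIAL = "preprandial"
    POSTPRANDIAL = "postprandial"
    FASTING = "fasting"


class BpStatus(enum.Enum):
    CONTROLLED = "controlled"
    ABOVE_TARGET = "above_target"


class GlucoseStatus(enum.Enum):
    IN_RANGE = "in_range"
    OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class BloodPressureReading:
    systolic: float  # mmHg
    diastolic: float  # mmHg
    timestamp: dt.datetime = field(default_factory=dt.datetime.now)
    source: Source = Source.MANUAL


@dataclass(frozen=True)
class GlucoseReading:
    value: float  # mg/dL
    context: GlucoseContext
    timestamp: dt.datetime = field(default_factory=dt.datetime.now)
    source: Source = Source.MANUAL


@dataclass(frozen=True)
class Assessment:
    """Classification plus the one-line feedback shown to the user."""

    status: BpStatus | GlucoseStatus
    message: str


def classify_blood_pressure(
    reading: BloodPressureReading, config: Mapping[str, Any] | None = None
) -> Assessment:
    """Flag a reading at or above either configured threshold (default 140/90).

    Both thresholds are inclusive: 140/89 is already above target.
    """
    if not (reading.systolic > reading.diastolic > 0):
        raise ValueError("require systolic > diastolic > 0")
    cfg = (config or DEFAULTS)["blood_pressure"]
    above = reading.systolic >= float(cfg["systolic"]) or reading.diastolic >= float(cfg["diastolic"])
    if above:
        return Assessment(
            BpStatus.ABOVE_TARGET,
            f"Blood pressure {reading.systolic:g}/{reading.diastolic:g} mmHg is above "
            f"target ({cfg['systolic']:g}/{cfg['diastolic']:g}); consider contacting your physician.",
        )
    return Assessment(
        BpStatus.CONTROLLED,
        f"Blood pressure {reading.systolic:g}/{reading.diastolic:g} mmHg is under control.",
    )


def classify_glucose(
    reading: GlucoseReading, config: Mapping[str, Any] | None = None
) -> Assessment:
    """Compare a glucose value against its context-specific target range.

    Defaults: preprandial 70-130 (inclusive), fasting 70-99 (inclusive),
    postprandial < 180 (strict upper bound, no lower bound).
    """
    if not (reading.value > 0):
        raise ValueError("glucose value must be positive")
    glucose_cfg = (config or DEFAULTS)["glucose"]
    key = reading.context.value
    if key not in glucose_cfg:
        raise KeyError(f"no glucose configuration for context {key!r}")
    cfg = glucose_cfg[key]
    low, high = cfg.get("min"), float(cfg["max"])
    inclusive = bool(cfg.get("max_inclusive", True))
    in_range = (low is None or reading.value >= float(low)) and (
        reading.value <= high if inclusive else reading.value < high
    )
    bound = f"{'<=' if inclusive else '<'} {high:g}"
    window = f"{low:g}-{high:g}" if low is not None else bound
    if in_range:
        return Assessment(
            GlucoseStatus.IN_RANGE,
            f"{key.capitalize()} glucose {reading.value:g} mg/dL is within the target range ({window}).",
        )
    return Assessment(
        GlucoseStatus.OUT_OF_RANGE,
        f"{key.capitalize()} glucose {reading.value:g} mg/dL is outside the target range ({window}).",
    )


def ingest_sensor_value(
    raw: Mapping[str, Any], timestamp: dt.datetime | None = None
) -> BloodPressureReading | GlucoseReading:
    """Turn one tagged stream item into a reading with ``source=sensor``.

    Expected shapes: ``{"type": "bp", "systolic": s, "diastolic": d}`` or
    ``{"type": "glucose", "value": v, "context": "fasting"}``.  Malformed
    items are rejected with a log entry and a ``ValueError``.
    """
    timestamp = timestamp or dt.datetime.now()
    try:
        tag = raw["type"]
    except (KeyError, TypeError):
        logger.warning("sensor item rejected: missing type tag (%r)", raw)
        raise ValueError("sensor item missing type tag") from None
    try:
        if tag == "bp":
            return BloodPressureReading(
                systolic=float(raw["systolic"]),
                diastolic=float(raw["diastolic"]),
                timestamp=timestamp,
                source=Source.SENSOR,
            )
        if tag == "glucose":
            return GlucoseReading(
                value=float(raw["value"]),
                context=GlucoseContext(raw["context"]),
                timestamp=timestamp,
                source=Source.SENSOR,
            )
    except (KeyError, TypeError, ValueError) as exc:
        logger.warning("sensor item rejected: %s (%r)", exc, raw)
        raise ValueError(f"malformed sensor item: {exc}") from None
    logger.warning("sensor item rejected: unknown type tag %r", tag)
    raise ValueError(f"unknown sensor item type {tag!r}")


def append_reading(
    path: str | Path, reading: BloodPressureReading | GlucoseReading
) -> None:
    """Append a reading to the JSON-lines monitoring log."""
    if isinstance(reading, BloodPressureReading):
        entry: dict[str, Any] = {
            "type": "bp",
            "systolic": reading.systolic,
            "diastolic": reading.diastolic,
        }
    else:
        entry = {"type": "glucose", "value": reading.value, "context": reading.context.value}
    entry["timestamp"] = reading.timestamp.isoformat()
    entry["source"] = reading.source.value
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(entry) + "\n")
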