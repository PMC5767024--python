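"""Threshold configuration.

Every clinical cut-off used by the toolkit lives in one nested mapping so that a
deployment can override any of them from a YAML file without touching code.

Documented keys (defaults shown in :data:`DEFAULTS`):

``biomarkers.<name>.{low,high,unit}``
    Closed reference interval for a serum biomarker; values inside (endpoints
    included) are flagged ``normal``, below ``low`` / above ``high``.
``proteinuria.{microalbuminuria,albuminuria,unit}``
    Lower cut-offs of the two pathological albumin-to-creatinine categories
    (mg/g): ``< micro`` is normal, ``[micro, albu)`` microalbuminuria,
    ``>= albu`` albuminuria.
``stages.bands``
    Lower GFR edge (mL/min, inclusive) of each stage except stage 5, which
    owns everything below the stage-4 edge.  Bands are half-open and owned by
    the less-severe stage.
``risk_matrix.<stage>.<category>``
    KDIGO-style risk level (``low``/``moderate``/``high``/``very_high``) for
    every stage x albuminuria-category cell; 18 cells in total.
``screening_intervals_months.<risk level>``
    Recommended months until the next screening test.
``blood_pressure.{systolic,diastolic}``
    Above-target thresholds in mmHg (a reading at or above either is flagged).
``glucose.<context>.{min,max,max_inclusive}``
    Per-context target range in mg/dL. ``min`` may be null (no lower bound);
    ``max_inclusive`` selects a closed or open upper bound.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: dict[str, Any] = {
    "biomarkers": {
        "creatinine": {"low": 0.6, "high": 1.4, "unit": "mg/dL"},
        "urea": {"low": 20.0, "high": 40.0, "unit": "mg/dL"},
        "potassium": {"low": 3.5, "high": 5.5, "unit": "mEq/L"},
    },
    "proteinuria": {
        "microalbuminuria": 30.0,
        "albuminuria": 300.0,
        "unit": "mg/g",
    },
    "stages": {
        # lower GFR edge of each stage; stage 5 is everything below 15
        "bands": {"1": 90.0, "2": 60.0, "3a": 45.0, "3b": 30.0, "4": 15.0},
    },
    "risk_matrix": {
        "1": {"normal": "low", "microalbuminuria": "moderate", "albuminuria": "high"},
        "2": {"normal": "low", "microalbuminuria": "moderate", "albuminuria": "high"},
        "3a": {"normal": "moderate", "microalbuminuria": "high", "albuminuria": "very_high"},
        "3b": {"normal": "high", "microalbuminuria": "very_high", "albuminuria": "very_high"},
        "4": {"normal": "very_high", "microalbuminuria": "very_high", "albuminuria": "very_high"},
        "5": {"normal": "very_high", "microalbuminuria": "very_high", "albuminuria": "very_high"},
    },
    "screening_intervals_months": {
        "low": 12,
        "moderate": 12,
        "high": 6,
        "very_high": 3,
    },
    "blood_pressure": {"systolic": 140.0, "diastolic": 90.0},
    "glucose": {
        "preprandial": {"min": 70.0, "max": 130.0, "max_inclusive": True},
        "postprandial": {"min": None, "max": 180.0, "max_inclusive": False},
        "fasting": {"min": 70.0, "max": 99.0, "max_inclusive": True},
    },
}


def merge_config(overrides: Mapping[str, Any] | None) -> dict[str, Any]:
    """Deep-merge ``overrides`` on top of :data:`DEFAULTS` and return a copy."""
    merged = copy.deepcopy(DEFAULTS)
    if overrides:
        _deep_update(merged, overrides)
    return merged


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML override file (or return defaults when ``path`` is None)."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path, "r", encoding="utf-8") as fh:
        overrides = yaml.safe_load(fh) or {}
    if not isinstance(overrides, Mapping):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return merge_config(overrides)


def _deep_update(base: dict[str, Any], overrides: Mapping[str, Any]) -> None:
    for key, value in overrides.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = copy.deepcopy(value)
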