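"""Synthetic cohorts and rater panels with known ground truth.

Two generators make the whole toolkit testable without any external data:

* :func:`generate_cohort` draws patient records shaped like the screening
  cohort this toolkit targets — comorbidity prevalences (94.5% hypertensive,
  58.82% of those also diabetic), ages uniform on 31-79 years, and lab values
  from truncated parametric families.  The lab distributions are synthetic
  conveniences chosen so every CKD stage and albuminuria category is
  reachable; they are not epidemiological estimates.  An optional target mix
  over risk levels inverts the decision workflow instead (pick a risk cell,
  then solve the Cockcroft-Gault equation for a creatinine that lands the GFR
  in the required band), which guarantees the requested outcome mix exactly.

* :func:`simulate_raters` draws a subjects x raters grid around known true
  risk labels using an adjacent-category confusion model: with probability
  ``1 - error`` a rater reports the true (ordered) category, otherwise an
  adjacent one.  :func:`calibrate_adjacent_error` solves the analytic
  expected-kappa equation so panels can be simulated at a designed agreement
  level.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import RatingMatrix
from .config import DEFAULTS
from .records import BiomarkerPanel, Gender, PatientRecord
from .renal import CkdStage, ProteinuriaCategory, _PROT_ORDER, _STAGE_ORDER
from .risk import RiskEvaluation, RiskLevel, RiskMatrix, _RISK_ORDER, evaluate_risk

__all__ = [
    "CohortSpec",
    "RaterModel",
    "RaterSpec",
    "generate_cohort",
    "simulate_raters",
    "adjacent_confusion_matrix",
    "expected_pairwise_kappa",
    "calibrate_adjacent_error",
    "design_rater_panel",
]


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class CohortSpec:
    """Parameters of a synthetic screening cohort.

    Defaults reproduce the documented cohort conditions: 94.5% with systemic
    arterial hypertension, 58.82% of hypertensives also diabetic, everyone
    with at least one of the two comorbidities, ages uniform on [31, 79].
    ``distributions`` holds the (stated-family) lab parameters; override any
    entry to move the cohort.  ``risk_mix`` switches to workflow inversion
    with the given proportions over the four risk levels.
    """

    n: int
    seed: int
    sah_prevalence: float = 0.945
    dm_given_sah: float = 0.5882
    dm_given_no_sah: float = 1.0
    age_range: tuple[int, int] = (31, 79)
    distributions: dict[str, dict[str, float]] = field(default_factory=lambda: {
        # truncated normal for weight and potassium/urea; lognormal for
        # creatinine and proteinuria (right-skewed, all stages reachable)
        "weight": {"mean": 75.0, "sd": 15.0, "low": 40.0, "high": 140.0},
        "creatinine": {"median": 1.1, "sigma": 0.6, "low": 0.3, "high": 9.0},
        "urea": {"mean": 38.0, "sd": 14.0, "low": 10.0, "high": 150.0},
        "potassium": {"mean": 4.5, "sd": 0.55, "low": 2.5, "high": 7.5},
        "proteinuria": {"median": 35.0, "sigma": 1.4, "low": 0.0, "high": 3000.0},
    })
    female_fraction: float = 0.5
    missing_proteinuria_rate: float = 0.0
    risk_mix: Mapping[RiskLevel, float] | None = None

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, p in (
            ("sah_prevalence", self.sah_prevalence),
            ("dm_given_sah", self.dm_given_sah),
            ("dm_given_no_sah", self.dm_given_no_sah),
            ("female_fraction", self.female_fraction),
            ("missing_proteinuria_rate", self.missing_proteinuria_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.risk_mix is not None:
            weights = [self.risk_mix.get(level, 0.0) for level in _RISK_ORDER]
            if any(w < 0 for w in weights) or not np.isclose(sum(weights), 1.0):
                raise ValueError(
                    f"risk_mix proportions must be non-negative and sum to 1, got {weights}"
                )


@dataclass
class CohortSample:
    records: list[PatientRecord]
    #: ground-truth evaluation per record (None where proteinuria was dropped)
    evaluations: list[RiskEvaluation | None]


def _truncated(draw, low: float, high: float, rng: np.random.Generator) -> float:
    for _ in range(1000):
        value = draw(rng)
        if low <= value <= high:
            return float(value)
    return float(min(max(draw(rng), low), high))


def generate_cohort(
    spec: CohortSpec, config: Mapping[str, Any] | None = None
) -> CohortSample:
    """Draw a reproducible cohort and its ground-truth evaluations."""
    spec.validate()
    config = config or DEFAULTS
    matrix = RiskMatrix.from_config(config)
    rng = np.random.default_rng(spec.seed)
    dists = spec.distributions

    records: list[PatientRecord] = []
    evaluations: list[RiskEvaluation | None] = []
    targets = None
    if spec.risk_mix is not None:
        weights = np.array([spec.risk_mix.get(level, 0.0) for level in _RISK_ORDER])
        targets = rng.choice(len(_RISK_ORDER), size=spec.n, p=weights / weights.sum())

    for i in range(spec.n):
        gender = Gender.FEMALE if rng.random() < spec.female_fraction else Gender.MALE
        age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
        has_sah = bool(rng.random() < spec.sah_prevalence)
        dm_p = spec.dm_given_sah if has_sah else spec.dm_given_no_sah
        has_dm = bool(rng.random() < dm_p)
        w = dists["weight"]
        weight = _truncated(lambda r: r.normal(w["mean"], w["sd"]), w["low"], w["high"], rng)

        if targets is None:
            c = dists["creatinine"]
            creatinine = _truncated(
                lambda r: np.exp(r.normal(np.log(c["median"]), c["sigma"])),
                c["low"], c["high"], rng,
            )
            p = dists["proteinuria"]
            proteinuria = _truncated(
                lambda r: np.exp(r.normal(np.log(p["median"]), p["sigma"])),
                p["low"], p["high"], rng,
            )
        else:
            creatinine, proteinuria = _invert_cell(
                _RISK_ORDER[targets[i]], matrix, age, weight, gender, rng, config
            )

        u = dists["urea"]
        urea = _truncated(lambda r: r.normal(u["mean"], u["sd"]), u["low"], u["high"], rng)
        k = dists["potassium"]
        potassium = _truncated(lambda r: r.normal(k["mean"], k["sd"]), k["low"], k["high"], rng)

        drop_proteinuria = rng.random() < spec.missing_proteinuria_rate
        record = PatientRecord(
            id=f"S{i + 1:04d}",
            gender=gender,
            age=age,
            weight=round(weight, 1),
            has_sah=has_sah,
            has_dm=has_dm,
            labs=BiomarkerPanel(
                # inverted cohorts keep extra creatinine digits so rounding
                # cannot push the implied GFR across a stage edge
                creatinine=round(creatinine, 2 if targets is None else 4),
                urea=round(urea, 1),
                potassium=round(potassium, 1),
                proteinuria=None if drop_proteinuria else round(proteinuria, 1),
            ),
        )
        records.append(record)
        evaluations.append(
            None if drop_proteinuria else evaluate_risk(record, config, matrix)
        )
    return CohortSample(records=records, evaluations=evaluations)


def _invert_cell(
    level: RiskLevel,
    matrix: RiskMatrix,
    age: int,
    weight: float,
    gender: Gender,
    rng: np.random.Generator,
    config: Mapping[str, Any],
) -> tuple[float, float]:
    """Pick a (stage, category) cell with the requested risk, then solve the
    clearance equation for a creatinine that lands the GFR in the stage band
    and draw a proteinuria inside the category range."""
    cells = [(s, c) for s, c, r in matrix if r is level]
    stage, category = cells[rng.integers(len(cells))]

    bands = config["stages"]["bands"]
    edges = [float(bands[s.value]) for s in _STAGE_ORDER[:-1]]
    i = _STAGE_ORDER.index(stage)
    if stage is CkdStage.S5:
        gfr_low, gfr_high = 3.0, edges[-1]
    elif i == 0:
        gfr_low, gfr_high = edges[0], edges[0] + 40.0
    else:
        gfr_low, gfr_high = edges[i], edges[i - 1]
    # rounding creatinine to 2 decimals nudges the GFR; stay inside the band
    margin = 0.02 * (gfr_high - gfr_low)
    gfr = float(rng.uniform(gfr_low + margin, gfr_high - margin))
    factor = 0.85 if gender is Gender.FEMALE else 1.0
    creatinine = (140.0 - age) * weight * factor / (72.0 * gfr)

    prot_cfg = config["proteinuria"]
    micro, albu = float(prot_cfg["microalbuminuria"]), float(prot_cfg["albuminuria"])
    ranges = {
        ProteinuriaCategory.NORMAL: (0.0, micro - 0.5),
        ProteinuriaCategory.MICROALBUMINURIA: (micro, albu - 0.5),
        ProteinuriaCategory.ALBUMINURIA: (albu, albu * 5.0),
    }
    low, high = ranges[category]
    proteinuria = float(rng.uniform(low, high))
    return creatinine, proteinuria


# ---------------------------------------------------------------------------
# rater simulation

@dataclass
class RaterModel:
    """Error model for one rater.

    kinds: ``adjacent`` (report an adjacent ordered category with probability
    ``error``), ``resample`` (with probability ``error`` report a draw from
    the truth marginal instead of the truth), ``uniform`` (ignore the truth).
    """

    name: str
    kind: str = "adjacent"
    error: float = 0.0

    def validate(self) -> None:
        if self.kind not in ("adjacent", "resample", "uniform"):
            raise ValueError(f"unknown rater model kind {self.kind!r}")
        if not 0.0 <= self.error <= 1.0:
            raise ValueError(f"error must be in [0, 1], got {self.error}")


@dataclass
class RaterSpec:
    """True labels plus one confusion model per rater."""

    truth: Sequence[RiskLevel]
    raters: Sequence[RaterModel]
    seed: int

    def validate(self) -> None:
        if len(self.truth) < 1:
            raise ValueError("need at least one subject")
        if len(self.raters) < 2:
            raise ValueError("need at least two raters")
        for model in self.raters:
            model.validate()


def adjacent_confusion_matrix(error: float, k: int = 4) -> np.ndarray:
    """Row-stochastic emission matrix of the adjacent-category model.

    Interior categories split the error mass evenly between their two
    neighbours; the end categories send it all to their single neighbour.
    """
    if not 0.0 <= error <= 1.0:
        raise ValueError("error must be in [0, 1]")
    matrix = np.zeros((k, k))
    for t in range(k):
        matrix[t, t] = 1.0 - error
        neighbours = [d for d in (t - 1, t + 1) if 0 <= d < k]
        for d in neighbours:
            matrix[t, d] += error / len(neighbours)
    return matrix


def expected_pairwise_kappa(truth_mix: np.ndarray, error: float) -> float:
    """Asymptotic Cohen's kappa between two raters sharing the adjacent model.

    ``po = sum_t pi_t sum_d E[t,d]^2`` and ``pe = sum_d (pi^T E)_d^2``.
    """
    pi = np.asarray(truth_mix, dtype=float)
    pi = pi / pi.sum()
    emission = adjacent_confusion_matrix(error, pi.size)
    po = float(pi @ (emission ** 2).sum(axis=1))
    marginal = pi @ emission
    pe = float(marginal @ marginal)
    return (po - pe) / (1.0 - pe)


def calibrate_adjacent_error(target_kappa: float, truth_mix: Sequence[float]) -> float:
    """Solve for the adjacent-model error rate achieving a design kappa.

    Expected kappa decreases from 1 as the error rate grows on [0, 0.5] (it is
    not monotone beyond that: near-deterministic flips agree with each other
    again), so the solution is found by bisection on that interval.
    """
    pi = np.asarray(truth_mix, dtype=float)
    lo, hi = 0.0, 0.5
    k_lo, k_hi = expected_pairwise_kappa(pi, lo), expected_pairwise_kappa(pi, hi)
    if not (k_hi <= target_kappa <= k_lo):
        raise ValueError(
            f"design kappa {target_kappa} outside the achievable range "
            f"[{k_hi:.4f}, {k_lo:.4f}] of the adjacent model for this truth mix"
        )
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if expected_pairwise_kappa(pi, mid) >= target_kappa:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def design_rater_panel(
    n_raters: int, target_kappa: float, truth_mix: Sequence[float]
) -> list[RaterModel]:
    """A panel of identical adjacent-model raters calibrated to a design kappa."""
    error = calibrate_adjacent_error(target_kappa, truth_mix)
    return [RaterModel(name=f"Rater {i + 1}", error=error) for i in range(n_raters)]


def simulate_raters(spec: RaterSpec) -> RatingMatrix:
    """Draw a ratings grid around the true labels, one column per rater."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    k = len(_RISK_ORDER)
    truth_codes = np.array([level.severity for level in spec.truth])
    pi = np.bincount(truth_codes, minlength=k) / truth_codes.size

    columns: dict[str, list[str]] = {}
    for model in spec.raters:
        if model.kind == "uniform":
            emission = np.full((k, k), 1.0 / k)
        elif model.kind == "resample":
            emission = (1.0 - model.error) * np.eye(k) + model.error * np.tile(pi, (k, 1))
        else:
            emission = adjacent_confusion_matrix(model.error, k)
        cumulative = emission.cumsum(axis=1)
        draws = rng.random(truth_codes.size)
        codes = (draws[:, None] > cumulative[truth_codes]).sum(axis=1)
        columns[model.name] = [_RISK_ORDER[c].label for c in codes]

    frame = pd.DataFrame(columns, index=[str(i + 1) for i in range(truth_codes.size)])
    return RatingMatrix(frame, categories=[level.label for level in _RISK_ORDER])
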