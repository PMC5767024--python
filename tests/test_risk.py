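"""Risk-identification workflow: grid, evaluation, enumeration, screening."""

import datetime as dt
import itertools

import pytest

from ckdkit.config import merge_config
from ckdkit.records import BiomarkerPanel, Gender, PatientRecord, load_records
from ckdkit.renal import CkdStage, ProteinuriaCategory, classify_proteinuria, classify_stage
from ckdkit.risk import (
    IncompletePanelError,
    RiskEvaluation,
    RiskLevel,
    RiskMatrix,
    append_history,
    enumerate_terminal_states,
    evaluate_risk,
    next_screening_due,
    read_history,
    run_workflow,
)
from ckdkit.synthetic import CohortSpec, generate_cohort


class TestWorkflow:
    def test_worked_example_microalbuminuria_stage3a_high(self):
        state = run_workflow(200.0, 50.0)
        assert state.category is ProteinuriaCategory.MICROALBUMINURIA
        assert state.stage is CkdStage.S3A
        assert state.risk is RiskLevel.HIGH

    @pytest.mark.parametrize(
        "proteinuria, gfr, risk",
        [
            (5, 120, RiskLevel.LOW),        # best-case cell
            (400, 10, RiskLevel.VERY_HIGH),  # worst-case cell
        ],
    )
    def test_extreme_cells(self, proteinuria, gfr, risk):
        assert run_workflow(proteinuria, gfr).risk is risk

    def test_exactly_one_outcome_for_any_valid_input(self):
        """Each run yields one terminal state with one of the four levels."""
        for proteinuria in (0, 29.9, 30, 150, 299.9, 300, 900):
            for gfr in (5, 14.9, 15, 29, 44, 59, 89, 90, 140):
                state = run_workflow(proteinuria, gfr)
                assert state.risk in set(RiskLevel)

    def test_workflow_equals_classification_composition(self):
        """Oracle equivalence: the pipeline must equal the composition of the
        elementary classifications plus a grid lookup, on 10^3 random panels."""
        import numpy as np

        matrix = RiskMatrix.from_config()
        rng = np.random.default_rng(11)
        for _ in range(1000):
            proteinuria = float(rng.uniform(0, 600))
            gfr = float(rng.uniform(1, 150))
            state = run_workflow(proteinuria, gfr)
            category = classify_proteinuria(proteinuria)
            stage = classify_stage(gfr)
            assert (state.category, state.stage) == (category, stage)
            assert state.risk is matrix.lookup(stage, category)


class TestRiskMatrix:
    def test_default_grid_is_total_and_monotone(self):
        matrix = RiskMatrix.from_config()
        assert len(matrix.cells) == 18
        assert matrix._monotonicity_violations() == []

    def test_missing_cell_rejected(self):
        config = merge_config({})
        del config["risk_matrix"]["3a"]["normal"]
        with pytest.raises(ValueError, match="incomplete"):
            RiskMatrix.from_config(config)

    def test_non_monotone_grid_rejected_unless_overridden(self):
        config = merge_config({"risk_matrix": {"5": {"normal": "low"}}})
        with pytest.raises(ValueError, match="monotone"):
            RiskMatrix.from_config(config)
        with pytest.warns(UserWarning, match="monotone"):
            RiskMatrix.from_config(config, allow_non_monotone=True)

    def test_per_level_cell_counts(self):
        """Brute force over the default grid: 2 low, 3 moderate, 4 high,
        9 very-high cells."""
        matrix = RiskMatrix.from_config()
        counts = {level: 0 for level in RiskLevel}
        for _, _, level in matrix:
            counts[level] += 1
        assert counts == {
            RiskLevel.LOW: 2, RiskLevel.MODERATE: 3,
            RiskLevel.HIGH: 4, RiskLevel.VERY_HIGH: 9,
        }


class TestEnumerate:
    def test_eighteen_terminal_states_bijective_on_grid(self):
        states = enumerate_terminal_states()
        assert len(states) == 18
        cells = {(s.category, s.stage) for s in states}
        assert cells == set(itertools.product(ProteinuriaCategory, CkdStage))
        assert {s.risk for s in states} == set(RiskLevel)

    def test_enumeration_agrees_with_grid(self):
        matrix = RiskMatrix.from_config()
        for state in enumerate_terminal_states():
            assert state.risk is matrix.lookup(state.stage, state.category)


class TestEvaluateRisk:
    def test_cohort_row_moderate_risk(self, cohort_csv):
        # proteinuria 77.5 with an estimated clearance of 63.8 lands in the
        # stage-2 microalbuminuria cell: moderate risk
        record = [r for r in load_records(cohort_csv) if r.id == "3"][0]
        evaluation = evaluate_risk(record)
        assert evaluation.gfr.displayed == 63.8
        assert evaluation.category is ProteinuriaCategory.MICROALBUMINURIA
        assert evaluation.stage is CkdStage.S2
        assert evaluation.risk is RiskLevel.MODERATE
        assert evaluation.advice  # non-empty at moderate and above

    def test_incomplete_panel_is_refused(self, cohort_csv):
        record = [r for r in load_records(cohort_csv) if r.id == "6"][0]
        with pytest.raises(IncompletePanelError, match="incomplete panel") as excinfo:
            evaluate_risk(record)
        assert excinfo.value.missing == ["proteinuria"]

    def test_flags_annotate_without_altering_risk(self):
        record = PatientRecord(
            id="X", gender=Gender.MALE, age=50, weight=70, has_dm=True, has_sah=True,
            labs=BiomarkerPanel(creatinine=1.0, urea=90.0, potassium=6.5, proteinuria=10.0),
        )
        evaluation = evaluate_risk(record)
        assert evaluation.biomarker_flags["urea"].status == "high"
        assert evaluation.biomarker_flags["potassium"].status == "high"
        # grid outcome driven solely by proteinuria and clearance
        assert evaluation.risk is run_workflow(10.0, evaluation.gfr.value).risk

    def test_evaluation_matches_workflow_on_synthetic_cohort(self):
        sample = generate_cohort(CohortSpec(n=100, seed=21))
        for record, evaluation in zip(sample.records, sample.evaluations):
            state = run_workflow(
                record.labs.proteinuria,
                evaluation.gfr.value,
            )
            assert evaluation.risk is state.risk


class TestScreening:
    def _evaluation(self, risk, when="2016-05-01T00:00:00"):
        base = evaluate_risk(
            PatientRecord(
                id="X", gender=Gender.MALE, age=50, weight=70,
                labs=BiomarkerPanel(creatinine=1.0, proteinuria=10.0),
            ),
            timestamp=dt.datetime.fromisoformat(when),
        )
        base.risk = risk
        return base

    def test_default_intervals(self):
        assert next_screening_due(self._evaluation(RiskLevel.LOW)) == dt.date(2017, 5, 1)
        assert next_screening_due(self._evaluation(RiskLevel.VERY_HIGH)) == dt.date(2016, 8, 1)

    def test_zero_interval_is_due_today(self):
        config = merge_config({"screening_intervals_months": {
            "low": 0, "moderate": 0, "high": 0, "very_high": 0}})
        today = dt.date(2020, 2, 2)
        assert next_screening_due(self._evaluation(RiskLevel.LOW), today, config) == today

    def test_higher_risk_never_waits_longer(self):
        dues = [next_screening_due(self._evaluation(level)) for level in RiskLevel]
        assert all(b <= a for a, b in zip(dues, dues[1:]))

    def test_non_monotone_intervals_rejected(self):
        config = merge_config({"screening_intervals_months": {"very_high": 24}})
        with pytest.raises(ValueError, match="monotone"):
            next_screening_due(self._evaluation(RiskLevel.LOW), config=config)

    def test_month_end_clamping(self):
        evaluation = self._evaluation(RiskLevel.HIGH, when="2015-08-31T12:00:00")
        assert next_screening_due(evaluation) == dt.date(2016, 2, 29)


class TestHistory:
    def test_append_and_read_round_trip(self, tmp_path):
        path = tmp_path / "history.jsonl"
        record = PatientRecord(
            id="H1", gender=Gender.FEMALE, age=60, weight=80,
            labs=BiomarkerPanel(creatinine=0.54, proteinuria=0.6),
        )
        for _ in range(3):
            append_history(path, evaluate_risk(record))
        entries = read_history(path)
        assert len(entries) == 3
        assert all(e["record_id"] == "H1" and e["risk"] == "low" for e in entries)
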