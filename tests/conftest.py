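import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ckdkit.agreement import RatingMatrix
from ckdkit.records import CSV_HEADER

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# Six-row cohort fixture in the cohort-table CSV dialect.  Rows 2-4 carry the
# clearances that serve as exact oracles for the Cockcroft-Gault path; rows
# 5-6 are plain data (their recorded GFR column is loaded, never recomputed);
# row 7 has no proteinuria, the most commonly missing lab in practice.
COHORT_ROWS = [
    ["2", "X", "X", "0.54", "25.2", "0.6", "4.1", "80", "60", "F", "139.9"],
    ["3", "X", "", "0.81", "33", "77.5", "3.9", "61", "79", "M", "63.8"],
    ["4", "X", "X", "0.6", "33.4", "5", "4.2", "87", "49", "F", "155.7"],
    ["5", "X", "X", "2.06", "65.1", "26.9", "4.4", "101", "74", "M", "36.6"],
    ["6", "X", "", "2.34", "128", "", "4.4", "67.4", "50", "M", "36.6"],
    ["7", "", "X", "1.1", "30.5", "", "4.8", "70", "45", "F", ""],
]

# Six published control-group risk ratings: three nephrologists plus the app.
CONTROL_RATINGS = {
    "Nephro 1": ["Low risk", "High risk", "High risk", "Low risk", "Low risk", "Very high risk"],
    "Nephro 2": ["Low risk", "Moderate risk", "Moderate risk", "Moderate risk", "Low risk", "Very high risk"],
    "Nephro 3": ["Low risk", "High risk", "High risk", "High risk", "Low risk", "High risk"],
    "App": ["Low risk", "Moderate risk", "Moderate risk", "Low risk", "Low risk", "Very high risk"],
}
RISK_CATEGORIES = ["Low risk", "Moderate risk", "High risk", "Very high risk"]


@pytest.fixture
def cohort_csv(tmp_path):
    path = tmp_path / "cohort.csv"
    lines = [",".join(CSV_HEADER)] + [",".join(row) for row in COHORT_ROWS]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def control_matrix():
    frame = pd.DataFrame(CONTROL_RATINGS, index=[str(i) for i in range(1, 7)])
    return RatingMatrix(frame, categories=RISK_CATEGORIES)
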