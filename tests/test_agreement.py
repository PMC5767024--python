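"""Kappa agreement machinery against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from ckdkit.agreement import (
    RatingMatrix,
    UndefinedKappaError,
    agreement_report,
    cohen_kappa,
    fleiss_kappa,
    global_kappa,
    interpret_kappa,
    kappa_confidence_interval,
    per_category_kappa,
)


def contingency_oracle(a, b, categories):
    """Independent brute-force kappa from the full contingency table."""
    n = len(a)
    table = np.zeros((len(categories), len(categories)))
    for x, y in zip(a, b):
        table[categories.index(x), categories.index(y)] += 1
    table /= n
    po = np.trace(table)
    pe = float(np.sum(table.sum(axis=1) * table.sum(axis=0)))
    return (po - pe) / (1 - pe)


def random_matrix(rng, n=20, k=4, raters=2):
    labels = [f"c{i}" for i in range(k)]
    data = rng.integers(0, k, size=(n, raters))
    frame = pd.DataFrame(
        {f"R{j}": [labels[c] for c in data[:, j]] for j in range(raters)}
    )
    return RatingMatrix(frame, categories=labels)


class TestCohenKappa:
    def test_identical_columns_give_kappa_one(self):
        frame = pd.DataFrame({"A": ["x", "y", "z", "x"], "B": ["x", "y", "z", "x"]})
        result = cohen_kappa(RatingMatrix(frame))
        assert result.kappa == 1.0 and result.po == 1.0

    def test_control_sample_nephro1_vs_app(self, control_matrix):
        """po = 4/6, pe = 10/36 on the six printed rows: kappa = 7/13."""
        result = cohen_kappa(control_matrix, raters=("Nephro 1", "App"))
        assert result.kappa == pytest.approx(7 / 13, abs=1e-12)
        assert result.po == pytest.approx(4 / 6)
        assert result.pe == pytest.approx(10 / 36)

    def test_control_sample_nephro2_vs_app(self, control_matrix):
        result = cohen_kappa(control_matrix, raters=("Nephro 2", "App"))
        assert result.kappa == pytest.approx(17 / 23, abs=1e-12)

    def test_matches_contingency_oracle_and_sklearn(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            matrix = random_matrix(rng, n=int(rng.integers(5, 40)))
            a = list(matrix.ratings.iloc[:, 0])
            b = list(matrix.ratings.iloc[:, 1])
            try:
                result = cohen_kappa(matrix)
            except UndefinedKappaError:
                continue
            assert result.kappa == pytest.approx(
                contingency_oracle(a, b, matrix.categories), abs=1e-12
            )
            assert result.kappa == pytest.approx(
                cohen_kappa_score(a, b, labels=matrix.categories), abs=1e-10
            )

    def test_symmetric_under_rater_exchange(self, control_matrix):
        forward = cohen_kappa(control_matrix, raters=("Nephro 1", "App"))
        backward = cohen_kappa(control_matrix, raters=("App", "Nephro 1"))
        assert forward.kappa == pytest.approx(backward.kappa, abs=1e-15)

    def test_invariant_under_category_relabeling(self, control_matrix):
        mapping = {"Low risk": "d", "Moderate risk": "c", "High risk": "b", "Very high risk": "a"}
        relabeled = control_matrix.relabel(mapping)
        before = cohen_kappa(control_matrix, raters=("Nephro 1", "App")).kappa
        after = cohen_kappa(relabeled, raters=("Nephro 1", "App")).kappa
        assert after == pytest.approx(before, abs=1e-15)

    def test_undefined_when_both_raters_constant_same(self):
        frame = pd.DataFrame({"A": ["x", "x", "x"], "B": ["x", "x", "x"]})
        with pytest.raises(UndefinedKappaError):
            cohen_kappa(RatingMatrix(frame, categories=["x", "y"]))

    def test_kappa_bounded_above_by_one_and_one_iff_po_one(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            matrix = random_matrix(rng, n=12, k=3)
            try:
                result = cohen_kappa(matrix)
            except UndefinedKappaError:
                continue
            assert result.kappa <= 1.0 + 1e-12
            assert (result.kappa == 1.0) == (result.po == 1.0)


class TestPerCategoryKappa:
    def test_total_agreement_category_gives_one(self):
        # all raters mark exactly the same subjects with the category
        column = ["Stage 4", "Stage 1", "Stage 4", "Stage 2", "Stage 1"]
        frame = pd.DataFrame({c: column for c in ("A", "B", "C")})
        matrix = RatingMatrix(frame, categories=["Stage 1", "Stage 2", "Stage 4"])
        assert per_category_kappa(matrix, "Stage 4").kappa == 1.0

    def test_low_risk_binary_collapse_nephro1_vs_app(self, control_matrix):
        frame = control_matrix.ratings[["Nephro 1", "App"]]
        matrix = RatingMatrix(frame, categories=control_matrix.categories)
        assert per_category_kappa(matrix, "Low risk").kappa == pytest.approx(1.0)

    def test_category_used_by_only_one_rater_gives_non_positive(self):
        frame = pd.DataFrame({"A": ["z", "x", "y", "y"], "B": ["x", "y", "y", "x"]})
        matrix = RatingMatrix(frame, categories=["x", "y", "z"])
        assert per_category_kappa(matrix, "z").kappa <= 0

    def test_absent_category_raises_undefined(self, control_matrix):
        frame = control_matrix.ratings
        matrix = RatingMatrix(frame, categories=control_matrix.categories + ["Unused"])
        with pytest.raises(UndefinedKappaError):
            per_category_kappa(matrix, "Unused")

    def test_matches_collapse_then_pairwise_oracle(self, control_matrix):
        for category in control_matrix.categories:
            result = per_category_kappa(control_matrix, category)
            oracle = []
            for pair in itertools.combinations(control_matrix.raters, 2):
                a = [1 if v == category else 0 for v in control_matrix.ratings[pair[0]]]
                b = [1 if v == category else 0 for v in control_matrix.ratings[pair[1]]]
                if len(set(a)) == 1 and a == b:
                    continue  # degenerate pair carries no information
                oracle.append(contingency_oracle(a, b, [0, 1]))
            assert result.kappa == pytest.approx(np.mean(oracle), abs=1e-12)


class TestGlobalKappa:
    def test_all_raters_identical_gives_one(self):
        frame = pd.DataFrame({c: ["x", "y", "z"] for c in "ABCD"})
        assert global_kappa(RatingMatrix(frame)).kappa == 1.0

    def test_two_raters_degenerates_to_cohen(self, control_matrix):
        frame = control_matrix.ratings[["Nephro 1", "App"]]
        matrix = RatingMatrix(frame, categories=control_matrix.categories)
        assert global_kappa(matrix).kappa == cohen_kappa(matrix).kappa

    def test_mean_of_all_pairwise_kappas(self, control_matrix):
        oracle = np.mean([
            contingency_oracle(
                list(control_matrix.ratings[a]),
                list(control_matrix.ratings[b]),
                control_matrix.categories,
            )
            for a, b in itertools.combinations(control_matrix.raters, 2)
        ])
        assert global_kappa(control_matrix).kappa == pytest.approx(oracle, abs=1e-12)

    def test_undefined_pair_propagates_with_names(self):
        frame = pd.DataFrame({"A": ["x", "x"], "B": ["x", "x"], "C": ["x", "y"]})
        with pytest.raises(UndefinedKappaError, match="A vs B"):
            global_kappa(RatingMatrix(frame, categories=["x", "y"]))

    def test_fleiss_alternative_is_flagged(self, control_matrix):
        result = global_kappa(control_matrix, method="fleiss")
        assert result.method == "fleiss"
        assert result.kappa == pytest.approx(fleiss_kappa(control_matrix).kappa)
        # same-definition cross-check of the Fleiss ingredients
        assert result.kappa == pytest.approx((result.po - result.pe) / (1 - result.pe), abs=1e-12)


class TestConfidenceInterval:
    def test_wald_interval_and_unclipped_upper_bound(self, control_matrix):
        result = cohen_kappa(control_matrix, raters=("Nephro 2", "App"))
        se = np.sqrt(result.po * (1 - result.po) / (result.n * (1 - result.pe) ** 2))
        assert result.ci_low == pytest.approx(result.kappa - 1.96 * se)
        assert result.ci_high == pytest.approx(result.kappa + 1.96 * se)
        assert result.ci_high > 1.0  # bounds deliberately not clipped

    def test_degenerate_po_collapses_to_point(self):
        low, high = kappa_confidence_interval(1.0, po=1.0, pe=0.5, n=10)
        assert low == high == 1.0

    def test_half_width_matches_bootstrap_oracle(self):
        """1.96 * SE vs a nonparametric bootstrap of subjects, within
        Monte-Carlo error."""
        rng = np.random.default_rng(17)
        n = 200
        truth = rng.integers(0, 3, size=n)
        noisy = np.where(rng.random(n) < 0.75, truth, rng.integers(0, 3, size=n))
        frame = pd.DataFrame({"A": truth.astype(str), "B": noisy.astype(str)})
        matrix = RatingMatrix(frame, categories=["0", "1", "2"])
        result = cohen_kappa(matrix)
        se = (result.ci_high - result.ci_low) / (2 * 1.96)
        boot = []
        for _ in range(4000):
            idx = rng.integers(0, n, size=n)
            boot.append(contingency_oracle(
                list(frame["A"].values[idx]), list(frame["B"].values[idx]), ["0", "1", "2"]
            ))
        assert se == pytest.approx(np.std(boot), rel=0.25)


class TestInterpretation:
    @pytest.mark.parametrize(
        "kappa, label",
        [
            (0.7119, "substantial"),
            (0.8375, "almost perfect"),
            (0.2920, "fair"),
            (1.0, "almost perfect"),
            (-0.2, "absence"),
            (0.0, "absence"),
            (0.20, "slight"),
            (0.21, "fair"),
            (0.40, "fair"),
            (0.41, "moderate"),
            (0.60, "moderate"),
            (0.61, "substantial"),
            (0.80, "substantial"),
            (0.81, "almost perfect"),
        ],
    )
    def test_scale_labels(self, kappa, label):
        assert interpret_kappa(kappa) == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(float("nan"))


class TestReport:
    def test_one_row_per_category_plus_global(self, control_matrix):
        report = agreement_report(control_matrix)
        assert list(report["Category"]) == control_matrix.categories + ["Global Kappa"]
        assert len(report) == 5

    def test_total_agreement_matrix_reports_all_ones(self):
        frame = pd.DataFrame({c: ["x", "y", "z", "x"] for c in "ABC"})
        report = agreement_report(RatingMatrix(frame))
        assert (report["Kappa"] == 1.0).all()

    def test_merge_map_folds_categories(self, control_matrix):
        merged = agreement_report(
            control_matrix, merge_map={"High risk": "Elevated", "Very high risk": "Elevated"}
        )
        assert "Elevated" in set(merged["Category"])
        assert len(merged) == 4  # 3 categories + global

    def test_csv_renderable(self, control_matrix, tmp_path):
        path = tmp_path / "report.csv"
        agreement_report(control_matrix).to_csv(path, index=False)
        back = pd.read_csv(path)
        assert list(back.columns)[:2] == ["Category", "Kappa"]
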