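"""Multi-rater categorical agreement statistics.

Implements the chance-corrected agreement machinery used to compare the
automated risk evaluations against a panel of nephrologists:

* Cohen's kappa, ``k = (po - pe) / (1 - pe)``, where ``po`` is the observed
  proportion of subjects rated identically by two raters and ``pe`` the
  agreement expected by chance from the raters' marginal label frequencies.
* Per-category kappa: labels collapsed to a one-vs-rest binary before pairwise
  kappas are computed and averaged over all rater pairs.
* Global kappa: the mean of all pairwise Cohen kappas (default), or Fleiss'
  kappa as a labeled alternative combination rule.
* 95% confidence intervals: the large-sample Wald interval
  ``k +/- 1.96 * sqrt(po (1 - po) / (n (1 - pe)^2))``, with no bias or
  prevalence adjustment and bounds deliberately NOT clipped to [-1, 1].
* An interpretation scale: absence (k <= 0), slight (<= 0.20), fair (<= 0.40),
  moderate (<= 0.60), substantial (<= 0.80), almost perfect (> 0.80).

A kappa is undefined when both raters use a single identical label (pe = 1);
that surfaces as a typed :class:`UndefinedKappaError`, never a silent NaN.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RatingMatrix",
    "AgreementResult",
    "UndefinedKappaError",
    "cohen_kappa",
    "per_category_kappa",
    "global_kappa",
    "fleiss_kappa",
    "kappa_confidence_interval",
    "interpret_kappa",
    "agreement_report",
]

Z_95 = 1.96


class UndefinedKappaError(ValueError):
    """pe = 1 (all ratings a single shared label): kappa has no value."""


@dataclass(frozen=True)
class AgreementResult:
    """Kappa with its ingredients, 95% CI and interpretation.

    For results pooled over several rater pairs, ``kappa`` is the mean of the
    pairwise kappas and ``po``/``pe`` are the means of the pairwise observed
    and expected agreements; for a single pair the identity
    ``kappa = (po - pe) / (1 - pe)`` holds exactly.
    """

    kappa: float
    po: float
    pe: float
    ci_low: float
    ci_high: float
    n: int
    interpretation: str
    method: str = "cohen"


class RatingMatrix:
    """Subjects x raters grid of categorical labels from a declared set."""

    def __init__(
        self,
        ratings: pd.DataFrame,
        categories: Sequence[Hashable] | None = None,
    ):
        if ratings.shape[1] < 2:
            raise ValueError("need at least 2 raters")
        if ratings.shape[0] < 1:
            raise ValueError("need at least 1 subject")
        if categories is None:
            categories = sorted(pd.unique(ratings.values.ravel()), key=str)
        categories = list(categories)
        observed = set(map(str, ratings.values.ravel()))
        declared = set(map(str, categories))
        if not observed <= declared:
            raise ValueError(
                f"undeclared categories in ratings: {sorted(observed - declared)}"
            )
        self.ratings = ratings
        self.categories = categories

    @property
    def raters(self) -> list[str]:
        return [str(c) for c in self.ratings.columns]

    @property
    def n_subjects(self) -> int:
        return int(self.ratings.shape[0])

    def codes(self) -> np.ndarray:
        """Integer-coded ratings (subjects x raters) in declared category order."""
        index = {c: i for i, c in enumerate(self.categories)}
        return np.array(
            [[index[v] for v in self.ratings[col]] for col in self.ratings.columns]
        ).T

    def collapse(self, category: Hashable) -> "RatingMatrix":
        """One-vs-rest binary view of the grid for ``category``."""
        if category not in self.categories:
            raise KeyError(f"category {category!r} not declared")
        binary = self.ratings.apply(lambda col: (col == category).astype(int))
        return RatingMatrix(binary, categories=[0, 1])

    def relabel(self, mapping: Mapping[Hashable, Hashable]) -> "RatingMatrix":
        """Merge/rename categories (e.g. fold stages 3a and 3b into one)."""
        merged = self.ratings.apply(lambda col: col.map(lambda v: mapping.get(v, v)))
        new_categories = list(dict.fromkeys(mapping.get(c, c) for c in self.categories))
        return RatingMatrix(merged, categories=new_categories)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        categories: Sequence[Hashable] | None = None,
        id_column: str | None = None,
    ) -> "RatingMatrix":
        """Read a ratings table whose first (or named) column is the subject id."""
        frame = pd.read_csv(path, dtype=str)
        id_column = id_column or frame.columns[0]
        frame = frame.set_index(id_column)
        return cls(frame, categories=categories)

    def to_csv(self, path: str | Path, id_column: str = "ID") -> None:
        self.ratings.rename_axis(id_column).to_csv(path)


# ---------------------------------------------------------------------------
# kappa core

def _pair_kappa(a: np.ndarray, b: np.ndarray, k: int, names: tuple[str, str]) -> tuple[float, float, float]:
    """(kappa, po, pe) for two integer-coded rating vectors."""
    n = a.size
    po = float(np.mean(a == b))
    marginal_a = np.bincount(a, minlength=k) / n
    marginal_b = np.bincount(b, minlength=k) / n
    pe = float(marginal_a @ marginal_b)
    if pe >= 1.0:
        raise UndefinedKappaError(
            f"kappa undefined for pair {names[0]} vs {names[1]}: "
            "both raters constant with the same label (pe = 1)"
        )
    return (po - pe) / (1.0 - pe), po, pe


def kappa_confidence_interval(
    kappa: float, po: float, pe: float, n: int
) -> tuple[float, float]:
    """95% Wald interval around kappa; bounds are not clipped to [-1, 1].

    Standard error: ``sqrt(po (1 - po) / (n (1 - pe)^2))``.  Degenerate cases
    (po of exactly 0 or 1) give SE = 0, collapsing the interval to a point.
    """
    if n < 1:
        raise ValueError("need n >= 1 subjects")
    if pe >= 1.0:
        raise UndefinedKappaError("pe = 1: confidence interval undefined")
    se = float(np.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2)))
    return kappa - Z_95 * se, kappa + Z_95 * se


def interpret_kappa(kappa: float) -> str:
    """Map a kappa value onto the qualitative agreement scale."""
    if not np.isfinite(kappa):
        raise ValueError("kappa must be finite")
    if kappa <= 0:
        return "absence"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def _result(kappa: float, po: float, pe: float, n: int, method: str) -> AgreementResult:
    low, high = kappa_confidence_interval(kappa, po, pe, n)
    return AgreementResult(
        kappa=kappa, po=po, pe=pe, ci_low=low, ci_high=high, n=n,
        interpretation=interpret_kappa(kappa), method=method,
    )


def cohen_kappa(matrix: RatingMatrix, raters: tuple[str, str] | None = None) -> AgreementResult:
    """Cohen's kappa between exactly two raters.

    ``raters`` selects a pair out of a wider panel; without it the matrix must
    have exactly two columns.
    """
    frame = matrix.ratings
    if raters is not None:
        frame = frame[list(raters)]
    elif frame.shape[1] != 2:
        raise ValueError("matrix has more than 2 raters; pass raters=(a, b)")
    sub = RatingMatrix(frame, categories=matrix.categories)
    codes = sub.codes()
    names = (str(frame.columns[0]), str(frame.columns[1]))
    kappa, po, pe = _pair_kappa(codes[:, 0], codes[:, 1], len(matrix.categories), names)
    return _result(kappa, po, pe, sub.n_subjects, method="cohen")


def _mean_pairwise(
    matrix: RatingMatrix, method: str, skip_undefined: bool = False
) -> AgreementResult:
    codes = matrix.codes()
    k = len(matrix.categories)
    names = matrix.raters
    kappas, pos, pes = [], [], []
    for i, j in itertools.combinations(range(codes.shape[1]), 2):
        try:
            kappa, po, pe = _pair_kappa(codes[:, i], codes[:, j], k, (names[i], names[j]))
        except UndefinedKappaError:
            if skip_undefined:
                continue
            raise
        kappas.append(kappa)
        pos.append(po)
        pes.append(pe)
    if not kappas:
        raise UndefinedKappaError("kappa undefined for every rater pair")
    kappa, po, pe = float(np.mean(kappas)), float(np.mean(pos)), float(np.mean(pes))
    return _result(kappa, po, pe, matrix.n_subjects, method=method)


def per_category_kappa(matrix: RatingMatrix, category: Hashable) -> AgreementResult:
    """One-vs-rest kappa for one category, averaged over all rater pairs.

    Pairs in which neither rater ever uses the category carry no information
    about it (their binary columns are identically zero, pe = 1) and are
    skipped; the undefined-kappa signal is raised only when the category is
    absent from the ratings of every rater.
    """
    if not (matrix.ratings == category).any().any():
        raise UndefinedKappaError(
            f"category {category!r} never used by any rater: kappa undefined"
        )
    binary = matrix.collapse(category)
    return _mean_pairwise(binary, method="cohen per-category", skip_undefined=True)


def global_kappa(matrix: RatingMatrix, method: str = "mean_pairwise") -> AgreementResult:
    """Agreement pooled over the whole panel.

    ``mean_pairwise`` (default) averages Cohen's kappa over all rater pairs;
    ``fleiss`` uses Fleiss' multi-rater kappa instead and flags it in the
    result's ``method`` field.
    """
    if method == "mean_pairwise":
        return _mean_pairwise(matrix, method="mean pairwise cohen")
    if method == "fleiss":
        return fleiss_kappa(matrix)
    raise ValueError(f"unknown method {method!r}")


def fleiss_kappa(matrix: RatingMatrix) -> AgreementResult:
    """Fleiss' kappa over the full panel (the alternative combination rule)."""
    from statsmodels.stats import inter_rater

    codes = matrix.codes()
    table, _ = inter_rater.aggregate_raters(codes, n_cat=len(matrix.categories))
    kappa = float(inter_rater.fleiss_kappa(table, method="fleiss"))
    # observed/expected agreement per Fleiss' definitions
    n_raters = codes.shape[1]
    p_cat = table.sum(axis=0) / table.sum()
    p_subject = ((table ** 2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    po = float(p_subject.mean())
    pe = float((p_cat ** 2).sum())
    if pe >= 1.0:
        raise UndefinedKappaError("pe = 1: Fleiss' kappa undefined")
    return _result(kappa, po, pe, matrix.n_subjects, method="fleiss")


def agreement_report(
    matrix: RatingMatrix,
    merge_map: Mapping[Hashable, Hashable] | None = None,
) -> pd.DataFrame:
    """Tabulate per-category kappas plus a global row.

    Columns mirror the conventional report layout: category, kappa, the 95%
    concordance-interval bounds, and the qualitative interpretation.
    ``merge_map`` optionally folds categories together first (e.g. reporting
    stages 3a and 3b as a single "Stage 3" row).
    """
    if merge_map:
        matrix = matrix.relabel(merge_map)
    rows = []
    for category in matrix.categories:
        try:
            res = per_category_kappa(matrix, category)
            rows.append((str(category), res.kappa, res.ci_low, res.ci_high, res.interpretation))
        except UndefinedKappaError:
            rows.append((str(category), float("nan"), float("nan"), float("nan"), "undefined"))
    res = global_kappa(matrix)
    rows.append(("Global Kappa", res.kappa, res.ci_low, res.ci_high, res.interpretation))
    return pd.DataFrame(
        rows,
        columns=["Category", "Kappa", "CI low (95.0%)", "CI high (95.0%)", "Interpretation"],
    )
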