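"""Comparative statistics: chi-square tests with partitioning and letter
displays, Welch t-tests, coefficients of variation, Pearson correlation.

Chi-square partitioning compares m groups over k categories by testing
every 2 x k sub-table; groups whose pairwise tests are non-significant at
alpha share a lowercase letter in the compact letter display. No
multiplicity correction is applied by default (a Bonferroni switch is
available), matching the single-alpha letters conventionally reported with
partitioned chi-square tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    statistic: float
    df: int
    p: float
    significant: bool


@dataclass
class PartitionResult:
    overall: ChiSquareResult
    pairwise: list[PairwiseComparison]
    letters: dict[str, str]


@dataclass
class SummaryStat:
    kind: str  # "t-test" | "CV" | "Pearson"
    value: float
    p: float | None = None
    df: float | None = None
    undefined: bool = False


def chisq_contingency(table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-square on an r x k table, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if (arr < 0).any():
        raise ValueError("contingency table contains negative cells")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"row {i} sums to zero")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise ValueError(f"column {j} sums to zero")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p))


def _compact_letter_display(
    labels: list[str], differs: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one letter covering all groups; every significantly
    different pair splits the letter classes containing both; classes that
    become subsets of another are absorbed. Deterministic: groups and pairs
    are processed in label order.
    """
    classes: list[set[str]] = [set(labels)]
    for a, b in sorted(differs):
        if not differs[(a, b)]:
            continue
        for cls in [c for c in classes if a in c and b in c]:
            classes.remove(cls)
            ca, cb = cls - {b}, cls - {a}
            for new in (ca, cb):
                if not any(new <= other for other in classes):
                    classes.append(new)
    # absorb any class that is a subset of another
    classes = [
        c for c in classes if not any(c < other for other in classes)
    ]
    # order classes for stable letter assignment
    classes.sort(key=lambda c: sorted(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in labels}
    for i, cls in enumerate(classes):
        for g in cls:
            letters[g].append(alphabet[i % len(alphabet)])
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def chisq_partition_pairwise(
    table: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> PartitionResult:
    """Overall m x k chi-square plus all pairwise 2 x k sub-table tests.

    Returns the overall test, every pairwise comparison, and a compact
    letter display at ``alpha`` (optionally Bonferroni-adjusted over the
    m*(m-1)/2 pairs).
    """
    arr = np.asarray(table, dtype=float)
    m = arr.shape[0]
    if m < 2:
        raise ValueError("need at least two groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(m)]
    labels = list(labels)
    overall = chisq_contingency(arr)
    n_pairs = m * (m - 1) // 2
    threshold = alpha / n_pairs if bonferroni else alpha
    pairwise: list[PairwiseComparison] = []
    differs: dict[tuple[str, str], bool] = {}
    for i, j in combinations(range(m), 2):
        res = chisq_contingency(arr[[i, j], :])
        sig = res.p < threshold
        pairwise.append(
            PairwiseComparison(
                pair=(labels[i], labels[j]),
                statistic=res.statistic,
                df=res.df,
                p=res.p,
                significant=sig,
            )
        )
        key = tuple(sorted((labels[i], labels[j])))
        differs[key] = sig
    letters = _compact_letter_display(sorted(labels), differs)
    return PartitionResult(overall=overall, pairwise=pairwise, letters=letters)


def two_sample_ttest(a: Sequence[float], b: Sequence[float]) -> SummaryStat:
    """Welch two-sample t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return SummaryStat(
        kind="t-test", value=float(res.statistic), p=float(res.pvalue), df=float(res.df)
    )


def coefficient_of_variation(values: Sequence[float]) -> SummaryStat:
    """Sample standard deviation over the mean (NaN-flagged for zero mean)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    mean = float(v.mean())
    if mean == 0:
        return SummaryStat(kind="CV", value=math.nan, undefined=True)
    return SummaryStat(kind="CV", value=float(v.std(ddof=1)) / mean)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> SummaryStat:
    """Pearson's r with two-sided p (NaN-flagged for constant input)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of at least three values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SummaryStat(kind="Pearson", value=math.nan, undefined=True)
    r, p = sps.pearsonr(x, y)
    return SummaryStat(kind="Pearson", value=float(r), p=float(p))
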