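"""The audit's test battery with Benjamini-Hochberg correction.

Four tests cover the audit's contrasts:

* chi-square goodness of fit of generated-case demographics against fixed
  reference (survey) proportions;
* 2x2 association tests for binary outcomes (top-3 inclusion, referral,
  imaging), using Pearson chi-square without continuity correction, or the
  two-sided point-probability Fisher exact test whenever any expected cell
  is at or below the conventional threshold of 5 (the branch taken is
  recorded per result);
* Mann-Whitney rank-sum comparisons for penalised ranks and Likert
  ratings (exact when both samples are small and tie-free, else the
  tie-corrected normal approximation with continuity correction);
* Benjamini-Hochberg step-up adjustment within declared test families,
  with significance flagged at 0.05 (p < 0.05) and 0.001 (p <= 0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ReferenceDistribution",
    "TestResult",
    "chisq_gof",
    "assoc_test_2x2",
    "mann_whitney",
    "bh_adjust",
    "bh_adjust_pvalues",
]

ALPHA_STAR = 0.05     # "*" convention: adjusted p < 0.05
ALPHA_DAGGER = 0.001  # dagger convention: adjusted p <= 0.001


@dataclass(frozen=True)
class ReferenceDistribution:
    """Reference level proportions for one (disease, attribute) pair."""

    disease: str
    attribute: str
    proportions: dict[str, float]
    source: str = "reference survey"

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")
        for level, p in self.proportions.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"proportion for {level} must be in (0, 1)")


@dataclass(frozen=True)
class TestResult:
    test: str          # chisq_gof | chisq_2x2 | fisher_2x2 | mann_whitney
    statistic: float
    p_raw: float
    df: Optional[float] = None
    p_adjusted: Optional[float] = None
    family_id: Optional[str] = None
    label: Optional[str] = None   # what was contrasted, for export
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0:
            raise ValueError("p_raw outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p below raw p")

    @property
    def effective_p(self) -> float:
        return self.p_adjusted if self.p_adjusted is not None else self.p_raw

    @property
    def significant_05(self) -> bool:
        return self.effective_p < ALPHA_STAR

    @property
    def significant_001(self) -> bool:
        return self.effective_p <= ALPHA_DAGGER


def chisq_gof(
    observed_counts: dict[str, int], reference: ReferenceDistribution
) -> TestResult:
    """Goodness of fit of observed level counts to reference proportions."""
    if set(observed_counts) != set(reference.proportions):
        raise ValueError(
            f"levels {sorted(observed_counts)} do not match reference "
            f"{sorted(reference.proportions)}"
        )
    levels = sorted(reference.proportions)
    obs = np.array([observed_counts[lvl] for lvl in levels], dtype=float)
    total = obs.sum()
    if total < 1:
        raise ValueError("total count must be >= 1")
    expected = total * np.array([reference.proportions[lvl] for lvl in levels])
    if np.any(expected <= 0):
        raise ValueError("zero expected count under reference distribution")
    stat, p = sps.chisquare(obs, f_exp=expected)
    return TestResult(
        test="chisq_gof", statistic=float(stat), p_raw=float(p),
        df=float(len(levels) - 1), n=int(total),
    )


def assoc_test_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Association in a 2x2 table.

    Pearson chi-square without continuity correction when every expected
    cell exceeds 5; the two-sided Fisher exact test (point-probability
    method) whenever any expected cell is 5 or smaller. Degenerate margins
    yield p = 1 with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    n = t.sum()
    if n <= 0:
        raise ValueError("grand total must be positive")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        warnings.warn("degenerate 2x2 margins; association undefined, p = 1")
        return TestResult(test="chisq_2x2", statistic=0.0, p_raw=1.0, df=1.0, n=int(n))
    expected = np.outer(rows, cols) / n
    if expected.min() <= 5:
        _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
        return TestResult(test="fisher_2x2", statistic=float(t[0, 0]),
                          p_raw=float(min(p, 1.0)), df=None, n=int(n))
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(test="chisq_2x2", statistic=float(stat), p_raw=float(p),
                      df=float(df), n=int(n))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test (U reported for the first sample).

    Exact enumeration when both samples have size <= 8 and there are no
    ties across the pooled data; otherwise the normal approximation with
    midrank tie correction and continuity correction. Identical constant
    samples yield p = 1 with a warning.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xa, ya])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across samples; p = 1")
        return TestResult(test="mann_whitney", statistic=float(xa.size * ya.size / 2.0),
                          p_raw=1.0, n=int(pooled.size))
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (xa.size <= 8 and ya.size <= 8 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided",
                           method=method, use_continuity=True)
    return TestResult(test="mann_whitney", statistic=float(res.statistic),
                      p_raw=float(min(res.pvalue, 1.0)), n=int(pooled.size))


def bh_adjust_pvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("family must be non-empty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def bh_adjust(results: Sequence[TestResult]) -> list[TestResult]:
    """Adjust raw p-values within each ``family_id`` group.

    Results with ``family_id=None`` form their own singleton families.
    Input order is preserved.
    """
    by_family: dict[object, list[int]] = {}
    for i, r in enumerate(results):
        key = r.family_id if r.family_id is not None else ("__solo__", i)
        by_family.setdefault(key, []).append(i)
    adjusted: list[Optional[TestResult]] = [None] * len(results)
    for indices in by_family.values():
        q = bh_adjust_pvalues([results[i].p_raw for i in indices])
        for i, qi in zip(indices, q):
            adjusted[i] = replace(results[i], p_adjusted=float(qi))
    return [r for r in adjusted if r is not None]
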