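"""Cohort-comparison statistics for clinical characteristics tables.

Categorical variables: Pearson chi-square (Yates continuity correction by
default on 2x2 tables, none on r x c) or Fisher's exact test; continuous
variables: pooled-variance two-sample t (computable from printed
mean +/- SD summaries) or Mann-Whitney U. Pooled stage-wise event
proportions use exact rational arithmetic before rounding.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "chisq_2x2",
    "chisq_rxc",
    "fisher_exact_2x2",
    "two_sample_t",
    "two_sample_t_from_stats",
    "mann_whitney",
    "stagewise_proportions",
]


def _check_table(table: np.ndarray, square_2x2: bool = False) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if square_2x2 and t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    return t


def chisq_2x2(table, continuity_correction: bool = True) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, Yates-corrected by default.

    Returns (statistic, two-sided p), df = 1.
    """
    t = _check_table(table, square_2x2=True)
    stat, p, _, _ = stats.chi2_contingency(t, correction=continuity_correction)
    return float(stat), float(p)


def chisq_rxc(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c table, no continuity correction.

    Returns (statistic, df, p). Callers should consider Fisher's exact test
    when any expected count is < 5 (expected counts available via
    ``scipy.stats.chi2_contingency``).
    """
    t = _check_table(table)
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def expected_counts(table) -> np.ndarray:
    """Expected counts under independence (for Fisher-fallback decisions)."""
    t = _check_table(table)
    return stats.contingency.expected_freq(t)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (hypergeometric tail-probability sum)."""
    t = _check_table(table, square_2x2=True)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t test on raw samples; pooled variance unless ``welch``.

    Returns (t, df, two-sided p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def two_sample_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t test from printed summary statistics (mean, SD, n)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    df = (
        n1 + n2 - 2
        if not welch
        else (sd1**2 / n1 + sd2**2 / n2) ** 2
        / ((sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1))
    )
    return float(res.statistic), float(df), float(res.pvalue)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with normal approximation and tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def stagewise_proportions(
    counts_by_cohort: Sequence[np.ndarray],
) -> list[dict]:
    """Pooled per-stage event proportions across cohorts.

    Each element of ``counts_by_cohort`` is a stages x 2 array of
    (event-negative, event-positive) counts. Cohorts are pooled per stage
    and the positive proportion computed with exact rational arithmetic.
    Returns one dict per stage with numerator, denominator and percentage.
    """
    tables = [np.asarray(t, int) for t in counts_by_cohort]
    shape = tables[0].shape
    if any(t.shape != shape for t in tables):
        raise ValueError("cohort tables must have the same shape")
    out = []
    for stage in range(shape[0]):
        pos = sum(int(t[stage, 1]) for t in tables)
        total = sum(int(t[stage, :].sum()) for t in tables)
        if total == 0:
            raise ValueError(f"stage {stage}: zero denominator")
        frac = Fraction(pos, total)
        out.append(
            {
                "stage": stage,
                "positive": pos,
                "total": total,
                "proportion": frac,
                "percent": float(frac * 100),
            }
        )
    return out
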