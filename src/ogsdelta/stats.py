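"""Statistical comparisons between gene classes and report arithmetic.

Frequency contrasts use Pearson chi-square on the 2x2 table with one degree
of freedom and no continuity correction; the Yates-corrected variant is
reserved for protein-domain frequency contrasts.  Mean contrasts run both a
two-sided Kolmogorov-Smirnov test and a Welch t-test and report the least
significant (largest) P-value, so no normality or equal-variance assumption
is leaned on.  No multiple-testing correction is applied across feature
comparisons; raw P-values are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class ChisqResult:
    statistic: Optional[float]
    p_value: Optional[float]
    reason: Optional[str] = None


@dataclass
class MeanComparison:
    ks_statistic: float
    ks_p: float
    welch_statistic: float
    welch_p: float

    @property
    def p_reported(self) -> float:
        """The least significant of the two P-values."""
        return max(self.ks_p, self.welch_p)


def _table_2x2(a_success: int, a_total: int, b_success: int, b_total: int) -> np.ndarray:
    if a_total <= 0 or b_total <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= a_success <= a_total) or not (0 <= b_success <= b_total):
        raise ValueError("successes must be between 0 and the group total")
    return np.array([[a_success, a_total - a_success],
                     [b_success, b_total - b_success]], dtype=float)


def chisq_prop(a_success: int, a_total: int, b_success: int, b_total: int) -> ChisqResult:
    """Pearson chi-square (1 df, no continuity correction) on two proportions."""
    table = _table_2x2(a_success, a_total, b_success, b_total)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ChisqResult(None, None, reason="zero margin in 2x2 table")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    assert dof == 1
    return ChisqResult(float(stat), float(p))


def chisq_yates_2x2(table: Sequence[Sequence[float]]) -> ChisqResult:
    """Yates-corrected chi-square on a 2x2 table (domain-frequency contrasts)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return ChisqResult(None, None, reason="zero margin in 2x2 table")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=True)
    assert dof == 1
    return ChisqResult(float(stat), float(p))


def mean_comparison(sample_a: Sequence[float], sample_b: Sequence[float]) -> MeanComparison:
    """KS + Welch on two samples; ``p_reported`` is the max of the two."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least two observations")
    if a.std() == 0 and b.std() == 0 and len(set(a)) == 1 and a[0] == b[0]:
        # constant, equal samples: no evidence of any difference
        return MeanComparison(0.0, 1.0, 0.0, 1.0)
    ks = sps.ks_2samp(a, b, alternative="two-sided")
    welch = sps.ttest_ind(a, b, equal_var=False)
    welch_p = float(welch.pvalue)
    if math.isnan(welch_p):  # zero variance in both groups, different means
        welch_p = 0.0 if a.mean() != b.mean() else 1.0
    return MeanComparison(float(ks.statistic), float(ks.pvalue),
                          float(welch.statistic), welch_p)


# ---------------------------------------------------------------------------
# Derived report arithmetic
# ---------------------------------------------------------------------------

def count_delta(new: int, old: int) -> int:
    return new - old


def percent_increase(new: float, old: float) -> float:
    """(new - old) / old * 100, one decimal; undefined for old = 0."""
    if old == 0:
        raise ValueError("percent increase undefined for old = 0")
    return round((new - old) / old * 100.0, 1)


def percent_reduction(old: float, new: float) -> int:
    """(old - new) / old * 100, rounded to the nearest integer."""
    if old == 0:
        raise ValueError("percent reduction undefined for old = 0")
    return round((old - new) / old * 100.0)


def coverage_percent(hits: float, total: float) -> float:
    """hits / total * 100, one decimal."""
    if total == 0:
        raise ValueError("coverage undefined for total = 0")
    return round(hits / total * 100.0, 1)


def class_percent(count: int, total: int) -> float:
    return coverage_percent(count, total)
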