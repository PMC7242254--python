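"""Two-group descriptive and comparative statistics.

Reproduces the summary-table stage: per-group mean +/- SD and a two-sided
p-value chosen by the study's gate — Shapiro-Wilk normality in both groups
and an F test of variance homogeneity select the pooled t-test; any failed
gate falls back to the Mann-Whitney U test. Chi-square handles 2x2
categorical tables with an automatic Yates continuity correction when
expected counts are small.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "GroupSummary",
    "TestPolicy",
    "ChiSquareResult",
    "summarize",
    "compare_groups",
    "mann_whitney_u",
    "chi_square_2x2",
]

# exact Mann-Whitney enumeration up to this per-group size; beyond it the
# tie-corrected normal approximation with continuity correction is used
_EXACT_LIMIT = 8


@dataclass(frozen=True)
class GroupSummary:
    variable: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    p_value: float
    test_used: str  # t_student | mann_whitney_u | chi_square


@dataclass(frozen=True)
class TestPolicy:
    """Gates for test selection.

    ``normality_test`` maps a sample to a p-value (pluggable; defaults to
    Shapiro-Wilk). ``force`` skips the gates entirely and names the test.
    """

    __test__ = False  # not a pytest class despite the name

    normality_test: Optional[Callable[[Sequence[float]], float]] = None
    alpha: float = 0.05
    force: Optional[str] = None  # t_student | mann_whitney_u

    def normality_p(self, values: Sequence[float]) -> float:
        if self.normality_test is not None:
            return float(self.normality_test(values))
        return float(stats.shapiro(np.asarray(values, dtype=float)).pvalue)


def summarize(values: Sequence[float]) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and count.

    SD is NaN for a single observation (undefined, flagged rather than 0).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("summarize requires at least one value")
    mean = float(arr.mean())
    if arr.size < 2:
        sd = float("nan")
    elif arr.min() == arr.max():
        sd = 0.0  # exact, avoids catastrophic-cancellation dust
    else:
        sd = float(arr.std(ddof=1))
    return mean, sd, int(arr.size)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U statistic of the first sample and two-sided p.

    U counts pairs (x in a, y in b) with x > y, plus half for ties. The
    p-value is by exhaustive enumeration over group assignments when both
    groups have at most 8 observations, otherwise by the tie-corrected
    normal approximation with a 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise DomainError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mean_u = n1 * n2 / 2.0

    if n1 <= _EXACT_LIMIT and n2 <= _EXACT_LIMIT:
        # enumerate every assignment of n1 pooled observations to group one
        dev = abs(u1 - mean_u)
        n = n1 + n2
        hits = total = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in itertools.combinations(range(n), n1):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mean_u) >= dev - 1e-12:
                hits += 1
        return u1, hits / total

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma_sq <= 0:  # all values identical
        return u1, 1.0
    diff = u1 - mean_u
    z = (diff - math.copysign(0.5, diff)) / math.sqrt(sigma_sq) if diff != 0 else 0.0
    return u1, float(2.0 * stats.norm.sf(abs(z)))


def _f_test_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test of variance equality."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dist = stats.f(a.size - 1, b.size - 1)
    return float(2.0 * min(dist.cdf(f), dist.sf(f)))


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    policy: Optional[TestPolicy] = None,
    variable: str = "",
) -> GroupSummary:
    """Compare two samples with the gated test-selection rule."""
    policy = policy or TestPolicy()
    arr_a = np.asarray(a, dtype=float)
    arr_b = np.asarray(b, dtype=float)
    if arr_a.size < 3 or arr_b.size < 3:
        raise DomainError("compare_groups requires n >= 3 in each group")

    mean_a, sd_a, n_a = summarize(arr_a)
    mean_b, sd_b, n_b = summarize(arr_b)

    if policy.force is not None:
        test = policy.force
        if test not in ("t_student", "mann_whitney_u"):
            raise DomainError(f"unknown forced test {test!r}")
    else:
        degenerate = sd_a == 0 or sd_b == 0
        if degenerate:
            normal = False
        else:
            normal = (
                policy.normality_p(arr_a) > policy.alpha
                and policy.normality_p(arr_b) > policy.alpha
            )
        equal_var = (not degenerate) and _f_test_p(arr_a, arr_b) > policy.alpha
        test = "t_student" if (normal and equal_var) else "mann_whitney_u"

    if test == "t_student":
        p = float(stats.ttest_ind(arr_a, arr_b, equal_var=True).pvalue)
    else:
        _, p = mann_whitney_u(arr_a, arr_b)

    return GroupSummary(
        variable=variable,
        mean_a=mean_a,
        sd_a=sd_a,
        n_a=n_a,
        mean_b=mean_b,
        sd_b=sd_b,
        n_b=n_b,
        p_value=min(p, 1.0),
        test_used=test,
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    yates_applied: bool


def chi_square_2x2(
    table: Sequence[Sequence[float]], correction: Optional[bool] = None
) -> ChiSquareResult:
    """Pearson chi-square for a 2x2 table.

    ``correction=None`` (default) applies the Yates continuity correction
    automatically when any expected count is below 5; True/False force it
    on/off. A zero row or column marginal makes the test undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise DomainError("chi_square_2x2 expects a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise DomainError("counts must be nonnegative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    total = t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise DomainError("a zero marginal makes the chi-square test undefined")
    expected = np.outer(rows, cols) / total
    yates = bool((expected < 5).any()) if correction is None else bool(correction)
    dev = np.abs(t - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(statistic=statistic, p_value=p, yates_applied=yates)
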