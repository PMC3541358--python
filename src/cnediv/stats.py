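"""The four hypothesis tests used by the comparison pipeline.

Self-contained implementations of the Pearson chi-square test on a 2x2
table, the one-tailed Fisher exact test, the two-sample t test (Welch or
pooled) and one-way ANOVA.  Test statistics are computed directly from
their defining formulas; tail probabilities for chi-square, t and F come
from the corresponding scipy.stats distributions.  The Fisher test is
fully exact: it enumerates the hypergeometric distribution over all
tables with the observed margins using integer binomial coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ContingencyTable2x2",
    "StatTestResult",
    "DegenerateTableError",
    "chi_square_2x2",
    "fisher_one_tail",
    "two_sample_t",
    "anova_oneway",
]


class DegenerateTableError(ValueError):
    """A contingency-table margin is zero where the test needs it positive."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are groups, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError(f"counts must be non-negative integers, got {v}")
        if self.total < 1:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @classmethod
    def coerce(cls, table) -> "ContingencyTable2x2":
        if isinstance(table, cls):
            return table
        (a, b), (c, d) = table
        return cls(int(a), int(b), int(c), int(d))


@dataclass(frozen=True)
class StatTestResult:
    """Outcome of one hypothesis test.

    ``df`` is a float for chi-square and t, a (between, within) pair for
    ANOVA, and None for the exact Fisher test.
    """

    test: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    tails: int = 2

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "tails": self.tails,
        }


def chi_square_2x2(table, yates: bool = False) -> StatTestResult:
    """Pearson chi-square test of independence on a 2x2 table.

    The statistic is sum((O - E)^2 / E) over the four cells with expected
    counts from the margins; df = 1.  With ``yates`` the absolute
    deviations are reduced by 0.5 (continuity correction, floored at 0).
    A zero row or column margin leaves the expected counts undefined and
    raises :class:`DegenerateTableError`.
    """
    t = ContingencyTable2x2.coerce(table)
    if 0 in t.row_margins or 0 in t.col_margins:
        raise DegenerateTableError("zero margin: expected counts undefined")
    n = t.total
    observed = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    expected = np.outer(t.row_margins, t.col_margins) / n
    dev = np.abs(observed - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float(np.sum(dev**2 / expected))
    p = float(_sps.chi2.sf(statistic, 1))
    name = "chi_square_yates" if yates else "chi_square"
    return StatTestResult(name, statistic, 1.0, min(p, 1.0), tails=2)


@lru_cache(maxsize=65536)
def _hypergeom_pmf_table(n: int, r1: int, c1: int) -> tuple[int, tuple[float, ...]]:
    """Exact hypergeometric pmf over cell *a* for fixed margins.

    Returns (k_min, probabilities) where probabilities[i] is P(a = k_min+i)
    for a table with total n, first-row margin r1 and first-column margin
    c1.  Computed with exact integer binomials, normalised once.
    """
    k_min = max(0, r1 + c1 - n)
    k_max = min(r1, c1)
    weights = [
        math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(k_min, k_max + 1)
    ]
    denom = math.comb(n, c1)
    return k_min, tuple(w / denom for w in weights)


def fisher_one_tail(table, direction: str = "greater") -> StatTestResult:
    """One-tailed Fisher exact test on a 2x2 table.

    ``direction="greater"`` sums the hypergeometric probability of all
    tables (with the observed margins) whose top-left cell is as large or
    larger than observed, i.e. tests enrichment of outcome 1 in group 1;
    ``"less"`` tests the opposite tail.  Degenerate margins admit a single
    table and give p = 1.  The reported statistic is the observed
    top-left count.
    """
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    t = ContingencyTable2x2.coerce(table)
    r1, _ = t.row_margins
    c1, _ = t.col_margins
    k_min, pmf = _hypergeom_pmf_table(t.total, r1, c1)
    idx = t.a - k_min
    if direction == "greater":
        p = sum(pmf[idx:])
    else:
        p = sum(pmf[: idx + 1])
    return StatTestResult(
        "fisher_one_tail", float(t.a), None, min(p, 1.0), tails=1
    )


def two_sample_t(
    xs: Sequence[float], ys: Sequence[float], welch: bool = True
) -> StatTestResult:
    """Two-sample t test, Welch (default) or pooled-variance, two-tailed.

    Welch uses the Welch-Satterthwaite df.  Two constant samples with
    equal means give t = 0, p = 1; a zero-variance situation with unequal
    means is undefined and raises ValueError.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    name = "welch_t" if welch else "pooled_t"
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return StatTestResult(name, 0.0, float(nx + ny - 2), 1.0, tails=2)
        raise ValueError("zero variance in both samples with unequal means")
    if welch:
        se2 = vx / nx + vy / ny
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = sp2 * (1 / nx + 1 / ny)
        df = nx + ny - 2
    statistic = float((mx - my) / math.sqrt(se2))
    p = float(2.0 * _sps.t.sf(abs(statistic), df))
    return StatTestResult(name, statistic, float(df), min(p, 1.0), tails=2)


def anova_oneway(groups: Sequence[Sequence[float]]) -> StatTestResult:
    """One-way fixed-effects ANOVA across k groups.

    F = (between-group SS / (k-1)) / (within-group SS / (N-k)); each group
    needs at least two observations.  Zero within-group variance with
    identical group means gives F = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs n >= 2")
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    grand = sum(g.sum() for g in arrays) / n_total
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return StatTestResult("anova_oneway", 0.0, (float(df1), float(df2)), 1.0)
        statistic = math.inf
        p = 0.0
    else:
        statistic = float((ss_between / df1) / (ss_within / df2))
        p = float(_sps.f.sf(statistic, df1, df2))
    return StatTestResult(
        "anova_oneway", statistic, (float(df1), float(df2)), min(p, 1.0), tails=2
    )
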