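"""Exact and rank statistics shared by every analysis stage.

The two tests that carry the headline results — the two-sided Fisher exact
test and the upper-tail hypergeometric overlap test — are implemented here
directly.  Fisher p-values for small tables are computed with exact integer
weights so that ties between equally-likely tables are resolved exactly
rather than through a floating-point epsilon; the hypergeometric tail is a
log-space summation of log-gamma terms and remains accurate for tails far
below double underflow thresholds of naive products (p ~ 1e-121 in the
motivating analysis).  Rank and correlation tests wrap scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

__all__ = [
    "Table2x2",
    "TestResult",
    "OverlapTestResult",
    "fisher_exact",
    "hypergeom_overlap",
    "mann_whitney_u",
    "benjamini_hochberg",
    "pearson_r",
    "one_sample_proportion_test",
]

# Above this grand total the Fisher test switches from exact integer
# enumeration to scipy's float implementation (indistinguishable at that
# scale, far faster).
_EXACT_FISHER_LIMIT = 1000


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table; rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("2x2 table is all zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    odds_ratio: float | None = None


@dataclass(frozen=True)
class OverlapTestResult:
    """Hypergeometric overlap of two subsets of a common tile universe."""

    universe: int
    set_a: int
    set_b: int
    observed: int
    expected: float
    p: float


def _as_table(t: Table2x2 | list | tuple | np.ndarray) -> Table2x2:
    if isinstance(t, Table2x2):
        return t
    arr = np.asarray(t, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return Table2x2(int(arr[0, 0]), int(arr[0, 1]), int(arr[1, 0]), int(arr[1, 1]))


def fisher_exact(table: Table2x2 | list | tuple | np.ndarray) -> TestResult:
    """Two-sided Fisher exact test by the point-probability method.

    The two-sided p-value sums the probabilities of all tables with the same
    margins whose point probability does not exceed that of the observed
    table.  For grand totals up to 1000 the comparison uses exact integer
    weights C(r1, x)·C(r2, c1−x), so ties contribute exactly; larger tables
    fall back to scipy's implementation.
    """
    t = _as_table(table)
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    if t.total > _EXACT_FISHER_LIMIT:
        _, p = sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
        return TestResult(statistic=t.odds_ratio(), p=float(p), odds_ratio=t.odds_ratio())
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[t.a - lo]
    total = sum(weights)
    p = sum(w for w in weights if w <= w_obs) / total
    return TestResult(statistic=t.odds_ratio(), p=float(p), odds_ratio=t.odds_ratio())


def hypergeom_overlap(universe: int, set_a: int, set_b: int, observed: int) -> OverlapTestResult:
    """Upper-tail hypergeometric test for the overlap of two tile sets.

    Under the null that a ``set_b``-sized subset is drawn uniformly from a
    universe of ``universe`` tiles of which ``set_a`` are marked, the overlap
    X is Hypergeometric(universe, set_a, set_b).  Returns the expected
    overlap set_a·set_b/universe and P(X >= observed), computed by
    log-space summation so extreme tails do not underflow intermediate terms.
    """
    N, K, n, k = int(universe), int(set_a), int(set_b), int(observed)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("set sizes must lie within the universe")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"observed overlap {k} inconsistent with set sizes")
    expected = K * n / N if N > 0 else 0.0
    hi = min(K, n)
    if k == 0:
        p = 1.0
    else:
        j = np.arange(k, hi + 1)
        logpmf = (
            gammaln(K + 1) - gammaln(j + 1) - gammaln(K - j + 1)
            + gammaln(N - K + 1) - gammaln(n - j + 1) - gammaln(N - K - n + j + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )
        p = float(min(1.0, math.exp(logsumexp(logpmf))))
    return OverlapTestResult(N, K, n, k, expected, p)


def mann_whitney_u(x, y, exact_limit: int = 20) -> TestResult:
    """Two-sided Mann–Whitney U test with midrank ties.

    Exact enumeration when both samples have at most ``exact_limit``
    observations and no ties span the two samples; otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= exact_limit and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved.

    q_i = min over j with p_(j) >= p_(i) of m·p_(j)/rank_j, clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def pearson_r(x, y) -> TestResult:
    """Sample Pearson correlation with a two-sided t-test p (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("samples must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    res = sps.pearsonr(x, y)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue))


def one_sample_proportion_test(k: int, n: int, p0: float) -> TestResult:
    """Two-sided normal-approximation score test for a single proportion.

    z = (k/n − p0) / sqrt(p0(1−p0)/n), no continuity correction.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    z = (k / n - p0) / math.sqrt(p0 * (1 - p0) / n)
    p = 2 * sps.norm.sf(abs(z))
    return TestResult(statistic=float(z), p=float(min(1.0, p)))
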