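"""Shared statistical tests: chi-square overlap, Wilcoxon rank-sum with
effect size r, Fisher exact by hypergeometric summation, methylation-level
contrasts and Benjamini-Hochberg adjustment.

The rank-sum test is exact (full enumeration of rank assignments) for small
tie-free samples and otherwise uses the normal approximation with tie and
continuity corrections.  The effect size is r = |Z|/sqrt(N), binned into the
star categories used throughout the figures: ``*`` r <= 0.10,
``**`` 0.10 < r <= 0.15, ``***`` r > 0.15, and ``ns`` when p >= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "RankTestResult",
    "chi2_overlap",
    "wilcoxon_rank_sum",
    "fisher_exact_2x2",
    "methylation_compare",
    "bh_adjust",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts a,b / c,d (rows: e.g. marked/unmarked; cols: up/not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RankTestResult:
    u: float
    z: float
    p: float
    r: float
    stars: str
    exact: bool


def chi2_overlap(table: ContingencyTable2x2, yates: bool = False):
    """Pearson chi-square test of independence on a 2x2 table.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1.  A zero margin is
    an error (the test is undefined).  ``yates`` applies the continuity
    correction |ad - bc| -> max(|ad - bc| - N/2, 0).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin: chi-square test undefined")
    det = abs(a * d - b * c)
    if yates:
        det = max(det - n / 2, 0.0)
    chi2 = n * det * det / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), 1, p


def _stars(p: float, r: float, alpha: float = 0.05) -> str:
    if p >= alpha:
        return "ns"
    if r <= 0.10:
        return "*"
    if r <= 0.15:
        return "**"
    return "***"


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    continuity: bool = True,
    exact_max_n: int = 10,
) -> RankTestResult:
    """Unpaired two-sided rank-sum (Mann-Whitney) test.

    Exact null by full enumeration of rank assignments when both samples
    have <= ``exact_max_n`` observations and there are no ties; otherwise
    the normal approximation with tie correction and (optional) continuity
    correction.  U is the Mann-Whitney statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    n = nx + ny
    ranks = sps.rankdata(pooled)
    rx = ranks[:nx].sum()
    u = rx - nx * (nx + 1) / 2.0
    m = nx * ny
    has_ties = len(np.unique(pooled)) < n

    if not has_ties and nx <= exact_max_n and ny <= exact_max_n:
        # exact: U is a function of which ranks go to x; enumerate them all
        lo = min(u, m - u)
        count = 0
        total = 0
        for combo in combinations(range(n), nx):
            total += 1
            s = sum(combo) + nx  # ranks are 1-based
            uu = s - nx * (nx + 1) / 2.0
            if uu <= lo or uu >= m - lo:
                count += 1
        p = count / total
        # z only for the effect size; keep the same correction conventions
        z = _rank_z(u, nx, ny, pooled, continuity)
        r = abs(z) / np.sqrt(n)
        return RankTestResult(float(u), float(z), float(min(p, 1.0)), float(r),
                              _stars(p, r), True)

    z = _rank_z(u, nx, ny, pooled, continuity)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    r = abs(z) / np.sqrt(n)
    return RankTestResult(float(u), float(z), p, float(r), _stars(p, r), False)


def _rank_z(u: float, nx: int, ny: int, pooled: np.ndarray, continuity: bool) -> float:
    n = nx + ny
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    num = u - mu
    if continuity:
        num = np.sign(num) * max(abs(num) - 0.5, 0.0)
    return float(num / np.sqrt(var))


def fisher_exact_2x2(
    table: ContingencyTable2x2,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> float:
    """Fisher exact test p-value by direct hypergeometric summation.

    Conditional on the margins, cell ``a`` is hypergeometric.  ``greater``
    sums the upper tail in a, ``less`` the lower; ``two-sided`` sums the
    probability of all tables no more likely than the observed one.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    r1 = a + b  # row 1 margin
    c1 = a + c  # column 1 margin
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    if alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    else:
        p = pmf[pmf <= p_obs * (1 + 1e-9)].sum()
    return float(min(1.0, max(p, 0.0)))


def methylation_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    weights_a: Sequence[float] | None = None,
    weights_b: Sequence[float] | None = None,
):
    """Compare CpG methylation levels between two groups of regions/CpGs.

    Returns (mean_a, mean_b, RankTestResult).  Means are coverage-weighted
    when weights are given (the global-level comparison); the significance
    test is the unweighted rank-sum on the per-unit values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty methylation group")
    mean_a = float(np.average(a, weights=weights_a))
    mean_b = float(np.average(b, weights=weights_b))
    res = wilcoxon_rank_sum(a, b)
    return mean_a, mean_b, res


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out
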