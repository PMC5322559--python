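"""2x2 contingency testing for phylogenetic-profile co-occurrence.

Presence/absence of two gene families across a genome compendium forms a
2x2 table: a = both present, b = first only, c = second only, d = neither.
Association between families (e.g. a candidate gene versus SelD) is scored
with Pearson's chi-square (df = 1, optional Yates continuity correction)
or, for the small counts arising in clade-enrichment scans, Fisher's exact
test on the hypergeometric null.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import erfc
from scipy.stats import hypergeom


@dataclass(frozen=True)
class Contingency2x2:
    """Counts with rows = factor 1 present/absent, columns = factor 2
    present/absent: a=+/+, b=+/-, c=-/+, d=-/-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name}={v} must be a nonnegative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    @classmethod
    def from_vectors(cls, x: Sequence[bool], y: Sequence[bool]) -> "Contingency2x2":
        x = np.asarray(x, dtype=bool)
        y = np.asarray(y, dtype=bool)
        if x.shape != y.shape:
            raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
        return cls(a=int(np.sum(x & y)), b=int(np.sum(x & ~y)),
                   c=int(np.sum(~x & y)), d=int(np.sum(~x & ~y)))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p: float
    yates: bool
    direction: int  # sign of (ad - bc): +1 positive association, -1 negative, 0 none
    degenerate: bool = False
    df: int = 1


def chisq_statistic_2x2(a, b, c, d, yates: bool = True):
    """Vectorised chi-square statistic for 2x2 tables (array-safe).

    Uncorrected: n (ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)).  Yates subtracts
    n/2 from |ad - bc| (floored at 0) before squaring.  Tables with a zero
    marginal get statistic 0.
    """
    a, b, c, d = (np.asarray(v, dtype=float) for v in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    cross = a * d - b * c
    if yates:
        cross = np.maximum(np.abs(cross) - n / 2.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * cross ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    return stat


def chisq_sf_df1(stat):
    """Survival function of chi-square with df=1 via the complementary
    error function: P(X >= stat) = erfc(sqrt(stat / 2))."""
    stat = np.asarray(stat, dtype=float)
    return erfc(np.sqrt(stat / 2.0))


def chisq_2x2(table: Contingency2x2, yates: bool = True) -> ChiSquareResult:
    """Pearson chi-square test for a 2x2 table (df = 1).

    A zero marginal makes the statistic undefined; such tables are returned
    as statistic 0, p = 1, flagged degenerate.
    """
    if table.n < 1:
        raise ValueError("empty table")
    degenerate = 0 in table.margins
    stat = float(chisq_statistic_2x2(table.a, table.b, table.c, table.d, yates=yates))
    p = 1.0 if degenerate else float(chisq_sf_df1(stat))
    cross = table.a * table.d - table.b * table.c
    direction = (cross > 0) - (cross < 0)
    return ChiSquareResult(statistic=stat, p=min(p, 1.0), yates=yates,
                           direction=int(direction), degenerate=degenerate)


def cooccurrence_test(x: Sequence[bool], y: Sequence[bool],
                      yates: bool = True) -> tuple[Contingency2x2, ChiSquareResult]:
    """Chi-square co-occurrence test between two aligned presence vectors."""
    table = Contingency2x2.from_vectors(x, y)
    return table, chisq_2x2(table, yates=yates)


def fisher_exact_2x2(table: Contingency2x2, side: str = "greater") -> float:
    """Fisher's exact test on the margin-conditioned hypergeometric null.

    ``side="greater"`` sums the upper tail over values of the a-cell at or
    above the observed one (positive association); ``"two-sided"`` sums the
    point probabilities not exceeding the observed one.  A zero margin
    leaves a single attainable table, so p = 1.
    """
    if side not in ("greater", "two-sided"):
        raise ValueError(f"side must be 'greater' or 'two-sided', got {side!r}")
    if table.n < 1:
        raise ValueError("empty table")
    r1, _r2, c1, _c2 = table.margins
    n = table.n
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    if lo == hi:  # zero margin (or fully determined table)
        return 1.0
    rv = hypergeom(n, r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    if side == "greater":
        p = float(pmf[support >= table.a].sum())
    else:
        p_obs = float(rv.pmf(table.a))
        p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(p, 1.0)
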