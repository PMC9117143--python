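"""Exact binomial and contingency-table statistics.

Implements the estimators the trial analysis reports for response
endpoints: the Blaker exact binomial confidence interval (by inverting the
two-sided acceptability function), the Cochran–Mantel–Haenszel chi-square
test, the unpooled Wald interval for a difference of proportions, and the
Woolf logit interval for an odds ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 count table: rows are groups, columns responder/non-responder.

    Layout::

                 responder  non-responder
        group 1      a            b
        group 2      c            d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


class ProportionCI(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float


class OddsRatioResult(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # True when the Haldane–Anscombe 0.5 correction was applied


def _blaker_acceptability(p, x: int, n: int):
    """Two-sided acceptability of H0: theta = p having observed x of n.

    The acceptability is the smaller tail probability plus the largest
    attainable probability of the opposite tail not exceeding it.
    Vectorized over ``p``.
    """
    p = np.asarray(p, dtype=float)
    inner = (p > 0.0) & (p < 1.0)
    pi = np.where(inner, p, 0.5)
    p_upper = sps.binom.sf(x - 1, n, pi)   # P(X >= x)
    p_lower = sps.binom.cdf(x, n, pi)      # P(X <= x)
    # opposite-tail probabilities not exceeding the observed tail, located
    # via the quantile function
    a_upper = p_upper + sps.binom.cdf(sps.binom.ppf(p_upper, n, pi) - 1, n, pi)
    a_lower = p_lower + sps.binom.sf(sps.binom.ppf(1.0 - p_lower, n, pi), n, pi)
    out = np.minimum(a_upper, a_lower)
    out = np.where(p <= 0.0, (x == 0) * 1.0, out)
    out = np.where(p >= 1.0, (x == n) * 1.0, out)
    return float(out) if out.ndim == 0 else out


def clopper_pearson_ci(x: int, n: int, conf: float = 0.95) -> ProportionCI:
    """Exact equal-tailed (Clopper–Pearson) binomial interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else sps.beta.ppf(alpha / 2, x, n - x + 1)
    hi = 1.0 if x == n else sps.beta.ppf(1 - alpha / 2, x + 1, n - x)
    return ProportionCI(x / n, float(lo), float(hi))


def blaker_ci(x: int, n: int, conf: float = 0.95,
              tol: float = 1e-8) -> ProportionCI:
    """Blaker's exact binomial interval.

    Obtained by inverting the acceptability function: the interval is the
    hull of {p : acceptability(p) > 1 - conf}. It always contains x/n and
    is never wider than the Clopper–Pearson interval at the same level.
    Endpoints are located by scanning inward from the Clopper–Pearson
    bounds and bisecting the crossing.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    alpha = 1.0 - conf
    point = x / n
    cp = clopper_pearson_ci(x, n, conf)

    def _bound(lo: float, hi: float, lower_side: bool) -> float:
        # acceptability >= alpha inside the interval; find the boundary
        # between `lo` (outside) and `hi` (inside) for the lower bound, and
        # symmetrically for the upper bound.
        outer, inner = (lo, hi) if lower_side else (hi, lo)
        # coarse scan from the CP endpoint toward the point estimate
        n_steps = 400
        grid = np.linspace(outer, inner, n_steps + 1)
        accepted = _blaker_acceptability(grid, x, n) >= alpha
        if not accepted.any():
            return inner
        inside_idx = int(np.argmax(accepted))
        if inside_idx == 0:
            return outer
        a, b = grid[inside_idx - 1], grid[inside_idx]  # a outside, b inside
        while abs(b - a) > tol:
            mid = 0.5 * (a + b)
            if _blaker_acceptability(float(mid), x, n) >= alpha:
                b = mid
            else:
                a = mid
        return float(b)

    lo = 0.0 if x == 0 else _bound(cp.ci_low, point, lower_side=True)
    hi = 1.0 if x == n else _bound(point, cp.ci_high, lower_side=False)
    return ProportionCI(point, lo, hi)


def orr_with_blaker_ci(x: int, n: int, conf: float = 0.95) -> ProportionCI:
    """Objective response rate with its Blaker exact confidence interval."""
    return blaker_ci(x, n, conf)


def cmh_response_test(table: TwoByTwo,
                      strata: Optional[Sequence[TwoByTwo]] = None,
                      ) -> tuple[float, float]:
    """Cochran–Mantel–Haenszel chi-square test for 2x2 tables.

    With a single table this is the Mantel–Haenszel statistic without
    continuity correction, i.e. the Pearson chi-square scaled by (N-1)/N.
    ``strata``, when given, are additional strata pooled with ``table``.
    Returns (statistic, two-sided p) on 1 df.
    """
    tables = [table] + (list(strata) if strata else [])
    num = 0.0
    var = 0.0
    any_valid = False
    for t in tables:
        n = t.n
        r1, r2 = t.a + t.b, t.c + t.d
        c1, c2 = t.a + t.c, t.b + t.d
        if n <= 1 or min(r1, r2, c1, c2) == 0:
            continue
        any_valid = True
        num += t.a - r1 * c1 / n
        var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
    if not any_valid:
        raise ValueError("all strata have a zero margin")
    if var == 0.0:
        return 0.0, 1.0
    stat = num * num / var
    return float(stat), float(sps.chi2.sf(stat, df=1))


def rate_difference_ci(x1: int, n1: int, x2: int, n2: int,
                       conf: float = 0.90) -> ProportionCI:
    """Difference of two proportions, in percentage points, with an
    unpooled Wald normal-approximation interval."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    diff = p1 - p2
    se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z = sps.norm.ppf(0.5 + conf / 2)
    return ProportionCI(100 * diff, 100 * (diff - z * se),
                        100 * (diff + z * se))


def odds_ratio_ci(table: TwoByTwo, conf: float = 0.95) -> OddsRatioResult:
    """Odds ratio (a·d)/(b·c) with the Woolf logit interval.

    A zero cell triggers the Haldane–Anscombe correction (0.5 added to
    every cell), flagged in the result.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        warnings.warn("zero cell: applying Haldane–Anscombe 0.5 correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + conf / 2)
    log_or = np.log(or_)
    return OddsRatioResult(float(or_), float(np.exp(log_or - z * se)),
                           float(np.exp(log_or + z * se)), corrected)
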