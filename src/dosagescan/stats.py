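"""Inferential statistics for region comparisons and cytological counts.

Two-sample Kolmogorov-Smirnov tests (variant vs control expression of a
region's genes), Fisher's exact 2x2 test for enrichment of up-regulated
genes between regions, and Wilson binomial intervals for small cell-count
proportions. Computation is delegated to scipy / statsmodels; the exact
vs asymptotic switch for the KS p-value follows the effective sample size
n_x * n_y / (n_x + n_y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "KsResult",
    "FisherResult",
    "ProportionResult",
    "ks_two_sample",
    "fisher_exact_2x2",
    "proportion_ci",
]


@dataclass
class KsResult:
    """Two-sample KS test: D is the ECDF supremum distance."""

    D: float
    p_value: float
    n_x: int
    n_y: int
    direction: int  # sign of median(x) - median(y)
    method: str  # "exact" or "asymp"

    def to_dict(self) -> dict:
        return {
            "test": "ks_two_sample",
            "D": self.D,
            "p_value": self.p_value,
            "n_x": self.n_x,
            "n_y": self.n_y,
            "direction": self.direction,
            "method": self.method,
        }


def ks_two_sample(x, y, exact_threshold: float = 35.0) -> KsResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs. The p-value
    uses exact enumeration when the effective sample size
    n_x*n_y/(n_x+n_y) is below ``exact_threshold`` and the asymptotic
    Kolmogorov distribution otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires non-empty samples")
    n_eff = x.size * y.size / (x.size + y.size)
    method = "exact" if n_eff < exact_threshold else "asymp"
    res = sps.ks_2samp(x, y, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(x) - np.median(y)))
    return KsResult(
        D=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_x=int(x.size),
        n_y=int(y.size),
        direction=direction,
        method=method,
    )


@dataclass
class FisherResult:
    """Fisher's exact test on a 2x2 table, two-sided probability criterion."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float  # sample OR (a*d)/(b*c); inf when b*c == 0
    p_value: float

    def to_dict(self) -> dict:
        return {
            "test": "fisher_exact_2x2",
            "table": [list(self.table[0]), list(self.table[1])],
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
        }


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed the observed table's
    (the minimum-likelihood criterion of standard statistical software).
    The reported odds ratio is the sample value (a*d)/(b*c), infinite when
    b*c = 0 and a*d > 0, NaN for a degenerate 0/0.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero 2x2 table")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    return FisherResult(
        table=((int(a), int(b)), (int(c), int(d))),
        odds_ratio=odds,
        p_value=float(min(p, 1.0)),
    )


@dataclass
class ProportionResult:
    """Binomial proportion k/n with a Wilson 95% confidence interval."""

    k: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {
            "test": "proportion_wilson_ci",
            "k": self.k,
            "n": self.n,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def proportion_ci(k: int, n: int, alpha: float = 0.05) -> ProportionResult:
    """Wilson score interval for a binomial proportion (suits small n)."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    low, high = proportion_confint(k, n, alpha=alpha, method="wilson")
    return ProportionResult(
        k=int(k), n=int(n), estimate=k / n,
        ci_low=float(low), ci_high=float(high),
    )
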