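"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and where possible the
libraries) they validate: the KS statistic is the literal ECDF supremum,
the Fisher p-value is an exact-rational hypergeometric enumeration, and
the changepoint fit is a naive per-split least-squares loop.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def ks_statistic_brute(x, y) -> float:
    """Supremum ECDF distance by direct evaluation at every pooled point."""
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    points = np.concatenate([x, y])
    d = 0.0
    for t in points:
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        d = max(d, abs(fx - fy))
    return float(d)


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over fixed-margin tables.

    Exact rational hypergeometric probabilities; a table counts as "at
    least as extreme" when its probability is <= the observed table's up
    to a 1e-7 relative tie tolerance (the convention of standard
    statistical software).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    p_obs = prob(a)
    cutoff = p_obs * Fraction(10_000_001, 10_000_000)  # 1 + 1e-7
    total = sum(prob(k) for k in range(k_min, k_max + 1) if prob(k) <= cutoff)
    return float(min(total, Fraction(1)))


def expected_up_probability(
    pi_dosage: float, pi_compensated: float, noise_log_sd: float,
    threshold: float = 2.0,
) -> float:
    """Probability a duplicated-region gene crosses ratio >= threshold.

    Closed-form/quadrature oracle for the generator's mixture: a fraction
    pi_dosage at multiplier 2, pi_compensated at 1, the rest uniform in
    (1, 2), each with multiplicative noise exp(N(0, sd)). Quadrature is a
    simple fine Riemann sum over the uniform component.
    """
    from scipy.stats import norm

    def cross(d: float) -> float:
        if noise_log_sd == 0:
            return 1.0 if d >= threshold else 0.0
        return float(norm.sf(math.log(threshold / d) / noise_log_sd))

    pi_partial = 1.0 - pi_dosage - pi_compensated
    grid = np.linspace(1.0, 2.0, 20_001)[:-1] + 0.5 / 20_000
    partial = float(np.mean([cross(d) for d in grid[::20]]))  # 1000-pt sum
    return (
        pi_dosage * cross(2.0)
        + pi_compensated * cross(1.0)
        + pi_partial * partial
    )


def changepoint_naive(r: np.ndarray):
    """Naive exhaustive single-changepoint least squares on log2 values.

    Returns (best_j, best_sse, left_mean, right_mean) with the tie broken
    toward smaller j; no model comparison.
    """
    y = np.log2(np.asarray(r, float))
    n = len(y)
    best = None
    for j in range(1, n):
        left, right = y[:j], y[j:]
        sse = float(((left - left.mean()) ** 2).sum()
                    + ((right - right.mean()) ** 2).sum())
        if best is None or sse < best[1] - 1e-15:
            best = (j, sse, float(left.mean()), float(right.mean()))
    return best
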