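"""Closed-form statistical primitives.

Exact binomial machinery (Clopper–Pearson intervals, one-sided exact test
and its power), the conjugate Beta ESS, the Pearson chi-square
heterogeneity statistic used by the calibrated hierarchical model, and the
two-sample Kolmogorov–Smirnov statistic for binary outcomes used by the
power-prior weights.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import BasketData

__all__ = [
    "beta_conjugate_ess",
    "clopper_pearson",
    "exact_binomial_rule",
    "exact_binomial_power",
    "chi_square_heterogeneity",
    "ks_binary",
]


def beta_conjugate_ess(a: float, b: float) -> float:
    """ESS of a conjugate Beta(a, b) prior for a binomial probability.

    A Beta(a, b) prior carries the information of a + b pseudo-observations
    (a successes, b failures) on top of a vague Beta prior.
    """
    if not (a > 0 and b > 0):
        raise ValueError("Beta parameters must be positive")
    return float(a + b)


def clopper_pearson(y: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact equal-tailed binomial confidence interval for y successes in n.

    The lower bound is 0 when y = 0 and the upper bound 1 when y = n.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    y, n = int(y), int(n)
    if n <= 0 or y < 0 or y > n:
        raise ValueError("require 0 <= y <= n with n > 0")
    alpha = 1.0 - level
    lo = 0.0 if y == 0 else float(stats.beta.ppf(alpha / 2, y, n - y + 1))
    hi = 1.0 if y == n else float(stats.beta.ppf(1 - alpha / 2, y + 1, n - y))
    return lo, hi


def exact_binomial_rule(n: int, p0: float, alpha: float) -> int:
    """Critical count of the non-randomized one-sided exact binomial test.

    Returns the smallest c with P(Y >= c | n, p0) <= alpha, i.e. the rule
    "reject H0: p <= p0 iff Y >= c" has size at most alpha.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    n = int(n)
    # P(Y >= c) = sf(c - 1); scan upward for the first tail at or below alpha.
    for c in range(n + 2):
        if stats.binom.sf(c - 1, n, p0) <= alpha + 1e-12:
            return c
    return n + 1  # unreachable: sf(n) = 0


def exact_binomial_power(n: int, p0: float, p1: float, alpha: float) -> float:
    """Power of the exact one-sided test at true response probability p1."""
    if not 0 <= p1 <= 1:
        raise ValueError("p1 must lie in [0, 1]")
    c = exact_binomial_rule(n, p0, alpha)
    return float(stats.binom.sf(c - 1, n, p1))


def chi_square_heterogeneity(data: BasketData) -> float | None:
    """Pearson chi-square statistic of the K x 2 responder table.

    Measures between-indication heterogeneity against the pooled response
    rate; 0 iff all observed proportions are equal.  Returns None when the
    pooled rate is 0 or 1 (statistic not computable), leaving the fallback
    to the caller.
    """
    if data.K < 2:
        raise ValueError("heterogeneity needs at least two indications")
    pooled = data.y.sum() / data.n.sum()
    if pooled <= 0.0 or pooled >= 1.0:
        return None
    # Closed form of the Pearson statistic for a K x 2 table vs pooled rate.
    t = np.sum(data.n * (data.phat - pooled) ** 2) / (pooled * (1.0 - pooled))
    return float(t)


def ks_binary(y_k: int, n_k: int, y_i: int, n_i: int) -> tuple[float, float]:
    """Two-sample KS statistic for binary outcomes, and its scaled form.

    For two-point empirical distributions the KS statistic reduces to the
    absolute difference of observed proportions.  The scaled similarity
    S = max(n_k, n_i)^(1/4) * S_KS feeds the power-prior weights.
    """
    for y, n in ((y_k, n_k), (y_i, n_i)):
        if n <= 0 or y < 0 or y > n:
            raise ValueError("require 0 <= y <= n with n > 0")
    s_ks = abs(y_k / n_k - y_i / n_i)
    s = max(n_k, n_i) ** 0.25 * s_ks
    return float(s_ks), float(s)
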