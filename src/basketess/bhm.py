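"""Fitting the Bayesian hierarchical model and its limiting special cases.

The BHM places a common normal distribution on the per-indication log-odds
theta_k = logit(p_k); the between-group variance sigma2 governs borrowing
strength.  sigma2 = 0 collapses to a pooled analysis (handled exactly by
one-dimensional quadrature, no sampling), sigma2 -> infinity approaches
per-indication independent analysis (available in closed form with a
conjugate Beta prior via :func:`fit_independent`).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit

from ._samplers import gibbs_bhm
from .types import BasketData, McmcSettings, PosteriorSummary, PriorSpec, SIMULATION_SETTINGS

__all__ = [
    "fit_bhm",
    "fit_independent",
    "posterior_reject",
    "logit_normal_quadrature",
    "pooled_quadrature",
]


def _summary_from_draws(p_draws: np.ndarray, level: float,
                        mu_draws: np.ndarray | None = None,
                        s2_draws: np.ndarray | None = None) -> PosteriorSummary:
    alpha = 1.0 - level
    cri = np.column_stack([
        np.quantile(p_draws, alpha / 2, axis=0),
        np.quantile(p_draws, 1 - alpha / 2, axis=0),
    ])
    return PosteriorSummary(
        mean=p_draws.mean(axis=0),
        variance=p_draws.var(axis=0),
        cri=cri,
        level=level,
        draws=p_draws,
        mu_draws=mu_draws,
        sigma2_draws=s2_draws,
    )


def fit_bhm(data: BasketData, prior: PriorSpec,
            settings: McmcSettings = SIMULATION_SETTINGS,
            level: float = 0.95) -> PosteriorSummary:
    """Draw from the BHM posterior; deterministic given ``settings.seed``.

    With ``sigma2_fixed=0`` the exact pooled posterior is computed by
    quadrature and draws are generated by inverse-CDF sampling, so the
    returned summary has the same shape either way.
    """
    if prior.sigma2_fixed == 0.0:
        return pooled_quadrature(data, prior, settings, level)
    p, mu, s2 = gibbs_bhm(
        data.y.astype(np.float64), data.n.astype(np.float64),
        prior.mu_mean, prior.mu_sd,
        prior.sigma2_shape if prior.estimates_sigma2 else 0.0,
        prior.sigma2_scale if prior.estimates_sigma2 else 0.0,
        prior.sigma2_fixed if prior.sigma2_fixed is not None else 0.0,
        prior.estimates_sigma2,
        settings.iterations, settings.burn_in, settings.thin,
        settings.seed, settings.slice_width,
    )
    if not np.all(np.isfinite(p)):
        raise RuntimeError("non-finite posterior draws; check data and prior")
    return _summary_from_draws(p, level, mu_draws=mu,
                               s2_draws=s2 if prior.estimates_sigma2 else None)


def _theta_grid(data: BasketData, prior: PriorSpec, points: int = 4001) -> np.ndarray:
    center = float(np.log((data.y.sum() + 0.5) / (data.n.sum() - data.y.sum() + 0.5)))
    lo = min(center, prior.mu_mean) - 6.0 * max(prior.mu_sd, 1.0)
    hi = max(center, prior.mu_mean) + 6.0 * max(prior.mu_sd, 1.0)
    return np.linspace(lo, hi, points)


def pooled_quadrature(data: BasketData, prior: PriorSpec,
                      settings: McmcSettings = SIMULATION_SETTINGS,
                      level: float = 0.95) -> PosteriorSummary:
    """Exact pooled analysis (sigma2 = 0): all theta_k equal a common mu.

    The one-dimensional posterior over mu is integrated on a grid; the
    reported draws are inverse-CDF samples from that grid.
    """
    grid = _theta_grid(data, prior)
    logpost = stats.norm.logpdf(grid, prior.mu_mean, prior.mu_sd)
    logpost += data.y.sum() * grid - data.n.sum() * np.logaddexp(0.0, grid)
    logpost -= logpost.max()
    w = np.exp(logpost)
    w /= w.sum()
    p = expit(grid)
    mean = float(np.sum(w * p))
    var = float(np.sum(w * (p - mean) ** 2))
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    alpha = 1.0 - level
    lo = float(np.interp(alpha / 2, cdf, p))
    hi = float(np.interp(1 - alpha / 2, cdf, p))
    kept = (settings.iterations - settings.burn_in + settings.thin - 1) // settings.thin
    rng = np.random.default_rng(settings.seed)
    u = rng.random(kept)
    draws_1d = np.interp(u, cdf, p)
    K = data.K
    return PosteriorSummary(
        mean=np.full(K, mean),
        variance=np.full(K, var),
        cri=np.tile([lo, hi], (K, 1)),
        level=level,
        draws=np.tile(draws_1d[:, None], (1, K)),
        mu_draws=np.interp(u, cdf, grid),
    )


def logit_normal_quadrature(y: int, n: int, mu_mean: float, mu_sd: float,
                            points: int = 4001) -> tuple[float, float]:
    """Mean and variance of p for a single binomial arm with a
    logit-normal prior theta ~ N(mu_mean, mu_sd^2); deterministic grid
    integration, used as an independent oracle for the MCMC fitter."""
    lo = min(mu_mean - 6 * mu_sd, -12.0)
    hi = max(mu_mean + 6 * mu_sd, 12.0)
    grid = np.linspace(lo, hi, points)
    logpost = stats.norm.logpdf(grid, mu_mean, mu_sd)
    logpost += y * grid - n * np.logaddexp(0.0, grid)
    logpost -= logpost.max()
    w = np.exp(logpost)
    w /= w.sum()
    p = expit(grid)
    mean = float(np.sum(w * p))
    var = float(np.sum(w * (p - mean) ** 2))
    return mean, var


def fit_independent(data: BasketData, beta_a: float = 0.5,
                    beta_b: float = 0.5, level: float = 0.95) -> PosteriorSummary:
    """Independent per-indication conjugate analysis.

    Each arm gets the closed-form Beta(beta_a + y_k, beta_b + n_k - y_k)
    posterior; no sampling.  Tail probabilities from the returned summary
    are exact Beta tail areas.
    """
    if beta_a <= 0 or beta_b <= 0:
        raise ValueError("Beta prior parameters must be positive")
    a = beta_a + data.y
    b = beta_b + data.n - data.y
    alpha = 1.0 - level
    return PosteriorSummary(
        mean=a / (a + b),
        variance=a * b / ((a + b) ** 2 * (a + b + 1.0)),
        cri=np.column_stack([stats.beta.ppf(alpha / 2, a, b),
                             stats.beta.ppf(1 - alpha / 2, a, b)]),
        level=level,
        beta_a=a.astype(float),
        beta_b=b.astype(float),
    )


def posterior_reject(summary: PosteriorSummary, threshold_rate: float,
                     phi: float) -> np.ndarray:
    """Per-indication efficacy call: Pr(p_k > threshold | data) > phi."""
    if not 0 < phi < 1:
        raise ValueError("phi must lie in (0, 1)")
    return summary.tail_prob(threshold_rate) > phi
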