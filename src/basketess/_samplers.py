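"""Numba Gibbs/slice kernel for the binomial Bayesian hierarchical model.

Model: Y_k ~ Bin(n_k, p_k), theta_k = logit(p_k) ~ N(mu, sigma2),
mu ~ N(mu_mean, mu_sd^2), sigma2 ~ InvGamma(shape, scale) or fixed.

The sampler interleaves a centered Gibbs sweep (slice updates of each
theta_k, conjugate normal update of mu, conjugate inverse-gamma update of
sigma2) with non-centered slice updates of log sigma2 and mu in the
ancillary parameterization eta_k = (theta_k - mu)/sigma.  The interweaving
step is what keeps the chain mixing when the sigma2 hyperprior is so
aggressive (e.g. InvGamma(0.0005, 0.000005)) that the centered chain alone
would be trapped in the funnel near sigma2 = 0.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_STEPOUT = 200
_MAX_SHRINK = 200


@njit(cache=True)
def _softplus(x):
    # log(1 + exp(x)) without overflow
    if x > 35.0:
        return x
    if x < -35.0:
        return np.exp(x)
    return np.log1p(np.exp(x))


@njit(cache=True)
def _log_cond_theta(theta, y, n, mu, sigma2):
    return y * theta - n * _softplus(theta) - 0.5 * (theta - mu) ** 2 / sigma2


@njit(cache=True)
def _slice_theta(x0, y, n, mu, sigma2, w):
    """One slice-sampling update of theta_k | y_k, mu, sigma2."""
    logy = _log_cond_theta(x0, y, n, mu, sigma2) + np.log(np.random.random())
    u = np.random.random() * w
    left = x0 - u
    right = left + w
    j = 0
    while j < _MAX_STEPOUT and _log_cond_theta(left, y, n, mu, sigma2) > logy:
        left -= w
        j += 1
    j = 0
    while j < _MAX_STEPOUT and _log_cond_theta(right, y, n, mu, sigma2) > logy:
        right += w
        j += 1
    for _ in range(_MAX_SHRINK):
        x1 = left + np.random.random() * (right - left)
        if _log_cond_theta(x1, y, n, mu, sigma2) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


@njit(cache=True)
def _log_nc_logs2(v, eta, mu, y, n, ig_shape, ig_scale):
    """log p(v = log sigma2 | eta, mu, data) in the non-centered frame."""
    # InvGamma(a, b) density on sigma2 plus the Jacobian of v = log sigma2:
    # -(a+1) v - b e^{-v} + v = -a v - b e^{-v}
    out = -ig_shape * v - ig_scale * np.exp(-v)
    sig = np.exp(0.5 * v)
    for k in range(y.shape[0]):
        th = mu + sig * eta[k]
        out += y[k] * th - n[k] * _softplus(th)
    return out


@njit(cache=True)
def _slice_logs2(v0, eta, mu, y, n, ig_shape, ig_scale, w):
    logy = _log_nc_logs2(v0, eta, mu, y, n, ig_shape, ig_scale) \
        + np.log(np.random.random())
    u = np.random.random() * w
    left = v0 - u
    right = left + w
    j = 0
    while j < _MAX_STEPOUT and _log_nc_logs2(left, eta, mu, y, n, ig_shape, ig_scale) > logy:
        left -= w
        j += 1
    j = 0
    while j < _MAX_STEPOUT and _log_nc_logs2(right, eta, mu, y, n, ig_shape, ig_scale) > logy:
        right += w
        j += 1
    for _ in range(_MAX_SHRINK):
        v1 = left + np.random.random() * (right - left)
        if _log_nc_logs2(v1, eta, mu, y, n, ig_shape, ig_scale) >= logy:
            return v1
        if v1 < v0:
            left = v1
        else:
            right = v1
    return v0


@njit(cache=True)
def _log_nc_mu(mu, eta, sig, y, n, mu_mean, mu_sd):
    out = -0.5 * (mu - mu_mean) ** 2 / (mu_sd * mu_sd)
    for k in range(y.shape[0]):
        th = mu + sig * eta[k]
        out += y[k] * th - n[k] * _softplus(th)
    return out


@njit(cache=True)
def _slice_mu_nc(x0, eta, sig, y, n, mu_mean, mu_sd, w):
    logy = _log_nc_mu(x0, eta, sig, y, n, mu_mean, mu_sd) + np.log(np.random.random())
    u = np.random.random() * w
    left = x0 - u
    right = left + w
    j = 0
    while j < _MAX_STEPOUT and _log_nc_mu(left, eta, sig, y, n, mu_mean, mu_sd) > logy:
        left -= w
        j += 1
    j = 0
    while j < _MAX_STEPOUT and _log_nc_mu(right, eta, sig, y, n, mu_mean, mu_sd) > logy:
        right += w
        j += 1
    for _ in range(_MAX_SHRINK):
        x1 = left + np.random.random() * (right - left)
        if _log_nc_mu(x1, eta, sig, y, n, mu_mean, mu_sd) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


@njit(cache=True)
def gibbs_bhm(y, n, mu_mean, mu_sd, ig_shape, ig_scale, sigma2_fixed,
              estimate_sigma2, iters, burn, thin, seed, w):
    """Run the interweaved Gibbs sampler; return (p, mu, sigma2) draws.

    Shapes: p draws (kept, K); mu and sigma2 draws (kept,).  Deterministic
    given ``seed``.
    """
    np.random.seed(seed)
    K = y.shape[0]
    kept = (iters - burn + thin - 1) // thin
    p_draws = np.empty((kept, K))
    mu_draws = np.empty(kept)
    s2_draws = np.empty(kept)
    eta = np.empty(K)

    theta = np.empty(K)
    for k in range(K):
        ph = (y[k] + 0.5) / (n[k] + 1.0)
        theta[k] = np.log(ph / (1.0 - ph))
    mu = theta.sum() / K
    if estimate_sigma2:
        sse0 = 0.0
        for k in range(K):
            sse0 += (theta[k] - mu) ** 2
        sigma2 = max(sse0 / K, 0.1)
    else:
        sigma2 = sigma2_fixed

    idx = 0
    for t in range(iters):
        for k in range(K):
            theta[k] = _slice_theta(theta[k], y[k], n[k], mu, sigma2, w)
        # conjugate normal update of mu
        prec = 1.0 / (mu_sd * mu_sd) + K / sigma2
        mean = (mu_mean / (mu_sd * mu_sd) + theta.sum() / sigma2) / prec
        mu = mean + np.random.normal() / np.sqrt(prec)
        if estimate_sigma2:
            sse = 0.0
            for k in range(K):
                sse += (theta[k] - mu) ** 2
            shape = ig_shape + 0.5 * K
            scale = ig_scale + 0.5 * sse
            sigma2 = scale / np.random.gamma(shape, 1.0)
            if sigma2 < 1e-12:
                sigma2 = 1e-12
        # ancillary (non-centered) interweaving step
        sig = np.sqrt(sigma2)
        for k in range(K):
            eta[k] = (theta[k] - mu) / sig
        if estimate_sigma2:
            v = _slice_logs2(np.log(sigma2), eta, mu, y, n, ig_shape, ig_scale, w)
            sigma2 = np.exp(v)
            sig = np.sqrt(sigma2)
        mu = _slice_mu_nc(mu, eta, sig, y, n, mu_mean, mu_sd, w)
        for k in range(K):
            theta[k] = mu + sig * eta[k]

        if t >= burn and (t - burn) % thin == 0:
            for k in range(K):
                p_draws[idx, k] = 1.0 / (1.0 + np.exp(-theta[k]))
            mu_draws[idx] = mu
            s2_draws[idx] = sigma2
            idx += 1
    return p_draws, mu_draws, s2_draws
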