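"""Domain types shared across the package.

A basket trial tests one therapy across ``K`` indications (tumor types),
each with its own enrolled sample size ``n_k`` and responder count ``y_k``.
These containers carry the observed data, the hierarchical-prior
configuration, simulation scenarios, posterior summaries and
effective-sample-size results between modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BasketData",
    "PriorSpec",
    "Scenario",
    "PosteriorSummary",
    "ESSResult",
    "OCResult",
    "McmcSettings",
    "PRIOR_A",
    "PRIOR_B",
]


def _as_int_array(x: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError(f"{name} must contain integers, got {x!r}")
    return arr.astype(np.int64)


@dataclass(frozen=True)
class BasketData:
    """Observed summary of a single-arm basket trial.

    Parameters
    ----------
    labels : indication names, one per basket.
    n : enrolled patients per indication (positive integers).
    y : responders per indication (``0 <= y_k <= n_k``).
    """

    labels: tuple[str, ...]
    n: np.ndarray
    y: np.ndarray

    def __init__(self, labels: Sequence[str], n: Sequence[int], y: Sequence[int]):
        object.__setattr__(self, "labels", tuple(str(s) for s in labels))
        object.__setattr__(self, "n", _as_int_array(n, "n"))
        object.__setattr__(self, "y", _as_int_array(y, "y"))
        if not (len(self.labels) == self.n.size == self.y.size):
            raise ValueError("labels, n and y must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicated indication labels")
        if np.any(self.n <= 0):
            raise ValueError("sample sizes must be positive")
        if np.any(self.y < 0) or np.any(self.y > self.n):
            raise ValueError("responder counts must satisfy 0 <= y_k <= n_k")

    @property
    def K(self) -> int:
        return self.n.size

    @property
    def phat(self) -> np.ndarray:
        """Observed response rates y_k / n_k."""
        return self.y / self.n

    def replace_arm(self, k: int, y_new: int) -> "BasketData":
        """Return a copy with indication ``k``'s responder count replaced."""
        y = self.y.copy()
        y[k] = y_new
        return BasketData(self.labels, self.n, y)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperprior configuration for the Bayesian hierarchical model.

    ``mu_mean``/``mu_sd`` parameterize the normal prior on the common
    log-odds mean mu.  ``sigma2_shape``/``sigma2_scale`` give an
    inverse-gamma prior on the between-group variance sigma^2; alternatively
    ``sigma2_fixed`` pins sigma^2 (0 means pooled analysis, a huge value
    approaches independent analysis).
    """

    mu_mean: float = -2.19
    mu_sd: float = 2.0
    sigma2_shape: float | None = None
    sigma2_scale: float | None = None
    sigma2_fixed: float | None = None
    label: str = ""

    def __post_init__(self):
        if not self.mu_sd > 0:
            raise ValueError("mu_sd must be positive")
        has_ig = self.sigma2_shape is not None or self.sigma2_scale is not None
        if has_ig and self.sigma2_fixed is not None:
            raise ValueError("give either an inverse-gamma prior or a fixed sigma2")
        if has_ig:
            if self.sigma2_shape is None or self.sigma2_scale is None:
                raise ValueError("inverse-gamma prior needs both shape and scale")
            if self.sigma2_shape <= 0 or self.sigma2_scale <= 0:
                raise ValueError("inverse-gamma shape and scale must be positive")
        elif self.sigma2_fixed is None:
            raise ValueError("sigma2 prior unspecified")
        elif self.sigma2_fixed < 0:
            raise ValueError("fixed sigma2 must be >= 0")

    @property
    def estimates_sigma2(self) -> bool:
        return self.sigma2_fixed is None

    def with_fixed_sigma2(self, value: float, label: str = "") -> "PriorSpec":
        return PriorSpec(self.mu_mean, self.mu_sd, sigma2_fixed=value,
                         label=label or self.label)


#: Moderate-borrowing hyperprior used in the RAGNAR study.
PRIOR_A = PriorSpec(-2.19, 2.0, sigma2_shape=0.375, sigma2_scale=1.5, label="Prior A")
#: Aggressive-borrowing hyperprior reflecting near-homogeneity.
PRIOR_B = PriorSpec(-2.19, 2.0, sigma2_shape=0.0005, sigma2_scale=0.000005,
                    label="Prior B")


@dataclass(frozen=True)
class Scenario:
    """A simulation scenario: true per-indication response probabilities."""

    true_orr: tuple[float, ...]
    n: tuple[int, ...]
    null_orr: float = 0.15
    target_orr: float = 0.3
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "true_orr", tuple(float(p) for p in self.true_orr))
        object.__setattr__(self, "n", tuple(int(v) for v in self.n))
        if len(self.true_orr) != len(self.n) or not self.true_orr:
            raise ValueError("true_orr and n must be non-empty, equal-length")
        if any(p < 0 or p > 1 for p in self.true_orr):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(v <= 0 for v in self.n):
            raise ValueError("sample sizes must be positive")
        if not self.null_orr < self.target_orr:
            raise ValueError("null_orr must be below target_orr")

    @property
    def K(self) -> int:
        return len(self.n)


@dataclass
class PosteriorSummary:
    """Per-indication posterior of the response probabilities.

    ``draws`` holds posterior samples of p_k (draws x K) when the fit is
    Monte Carlo; closed-form fits (conjugate Beta posteriors) may omit
    draws and instead carry ``beta_a``/``beta_b`` for exact tail areas.
    """

    mean: np.ndarray
    variance: np.ndarray
    cri: np.ndarray  # (K, 2) equal-tailed interval
    level: float = 0.95
    draws: np.ndarray | None = None
    sigma2_draws: np.ndarray | None = None
    mu_draws: np.ndarray | None = None
    beta_a: np.ndarray | None = None
    beta_b: np.ndarray | None = None

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        self.cri = np.asarray(self.cri, dtype=float)
        if np.any(self.mean < 0) or np.any(self.mean > 1):
            raise ValueError("posterior means must lie in [0, 1]")
        if np.any(self.variance < 0):
            raise ValueError("posterior variances must be nonnegative")
        if self.cri.shape != (self.mean.size, 2) or np.any(self.cri[:, 0] > self.cri[:, 1]):
            raise ValueError("credible intervals must be ordered (K, 2)")

    @property
    def K(self) -> int:
        return self.mean.size

    def tail_prob(self, threshold: float) -> np.ndarray:
        """Pr(p_k > threshold | data) per indication (exact for Beta fits)."""
        if self.beta_a is not None:
            from scipy import stats

            return stats.beta.sf(threshold, self.beta_a, self.beta_b)
        if self.draws is None or self.draws.size == 0:
            raise ValueError("summary carries neither draws nor Beta parameters")
        return np.mean(self.draws > threshold, axis=0)


ESS_OK = "ok"
ESS_NOT_AVAILABLE = "not_available"
ESS_CAPPED = "capped"


@dataclass(frozen=True)
class ESSResult:
    """Effective-sample-size result for one indication.

    ``posterior_ess`` is the independent-analysis sample size whose MSE (or
    variance) matches the Bayesian estimator; ``prior_ess`` subtracts the
    enrolled n_k.  ``status`` is ``not_available`` when the reference rate
    is 0 or 1 (the independent MSE is then identically zero) and ``capped``
    when the match lies beyond the search bound.
    """

    posterior_ess: float | None
    prior_ess: float | None
    mse_bayes: float | None = None
    mse_independent_at_match: float | None = None
    status: str = ESS_OK
    method: str = "mse"

    def __post_init__(self):
        if self.status == ESS_NOT_AVAILABLE:
            if any(v is not None for v in (self.posterior_ess, self.prior_ess,
                                           self.mse_bayes,
                                           self.mse_independent_at_match)):
                raise ValueError("not_available results carry no numbers")
        else:
            if self.posterior_ess is None or self.prior_ess is None:
                raise ValueError("ok results need posterior and prior ESS")


@dataclass(frozen=True)
class OCResult:
    """Operating characteristics for one scenario x design cell."""

    scenario: str
    design: str
    true_orr: tuple[float, ...]
    reject_rate: tuple[float, ...]
    mse: tuple[float, ...]
    prior_ess: tuple[float | None, ...]
    reps: int
    seed: int
    phi: float | None = None
    null_orr: float = 0.15

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if any(r < 0 or r > 1 for r in self.reject_rate):
            raise ValueError("rejection rates are fractions in [0, 1]")


@dataclass(frozen=True)
class McmcSettings:
    """Tuning for the Gibbs/slice sampler behind the BHM fits."""

    iterations: int = 5000
    burn_in: int = 2000
    thin: int = 1
    seed: int = 0
    slice_width: float = 1.0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.slice_width <= 0:
            raise ValueError("slice_width must be positive")

    def with_seed(self, seed: int) -> "McmcSettings":
        return McmcSettings(self.iterations, self.burn_in, self.thin,
                            int(seed), self.slice_width)


#: Settings for single-dataset analyses (longer chains).
ANALYSIS_SETTINGS = McmcSettings(iterations=20000, burn_in=5000)
#: Settings for simulation loops (throughput-oriented).
SIMULATION_SETTINGS = McmcSettings(iterations=5000, burn_in=2000)
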