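"""ESS-based borrowing strategies and their calibration.

Three ways of steering how much a basket analysis borrows:

* **ESS-based model selection** — fall back to independent conjugate
  analysis whenever any indication's analysis-stage prior ESS is negative
  (borrowing is then adding bias, not removing variance).
* **Calibrated BHM (CBHM)** — fix the between-group variance empirically,
  sigma2 = exp{a + b log T} with T a heterogeneity statistic, and choose
  (a, b) so the *design-stage prior ESS* hits interpretable targets.
* **ESS-based power prior** — conjugate pairwise borrowing with logistic
  weights in a scaled Kolmogorov–Smirnov distance, tuned the same way.

Also here: calibration of the shared posterior-probability decision
threshold phi to a target type I error under the global null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bhm import fit_bhm, fit_independent
from .core import chi_square_heterogeneity, ks_binary
from .engine import generate_trial, replication_seeds, run_replications
from .ess import analysis_stage_ess, ess_from_mse
from .types import (
    ESS_NOT_AVAILABLE,
    BasketData,
    ESSResult,
    McmcSettings,
    PosteriorSummary,
    PriorSpec,
    Scenario,
    SIMULATION_SETTINGS,
)

__all__ = [
    "TuningPair",
    "PowerPriorSpec",
    "cbhm_sigma2",
    "fit_cbhm",
    "pp_weight",
    "fit_power_prior",
    "PowerPriorResult",
    "ess_based_model_selection",
    "ModelSelectionResult",
    "calibrate_phi",
    "PhiCalibration",
    "calibrate_tuning",
    "Design",
    "BhmDesign",
    "IndependentDesign",
    "PooledDesign",
    "CbhmDesign",
    "PowerPriorDesign",
    "ModelSelectionDesign",
    "CBHM_TUNING",
    "PP_TUNING",
]

T_FLOOR = 1e-6
SIGMA2_MIN = 1e-4
SIGMA2_MAX = 1e4


@dataclass(frozen=True)
class TuningPair:
    """(a, b) of sigma2 = exp{a + b log T} (CBHM) or of the power-prior
    weight w = 1/(1 + exp{a + b log S})."""

    a: float
    b: float
    context: str = "cbhm"

    def __post_init__(self):
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("tuning parameters must be finite")
        if self.context not in ("cbhm", "power_prior"):
            raise ValueError("context must be 'cbhm' or 'power_prior'")


#: Tuning calibrated so the prior ESS is ~30 per arm in the global
#: alternative and ~0 for the lone null arm in the mixed scenario.
CBHM_TUNING = TuningPair(-2.0, 0.4, "cbhm")
PP_TUNING = TuningPair(2.0, 0.4, "power_prior")


@dataclass(frozen=True)
class PowerPriorSpec:
    """Initial Beta(s1, s2) prior per indication plus the weight tuning."""

    s1: float = 0.5
    s2: float = 0.5
    tuning: TuningPair = PP_TUNING

    def __post_init__(self):
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValueError("initial Beta parameters must be positive")


def cbhm_sigma2(T: float | None, tuning: TuningPair,
                t_floor: float = T_FLOOR,
                sigma2_min: float = SIGMA2_MIN,
                sigma2_max: float = SIGMA2_MAX) -> float:
    """Empirical-Bayes between-group variance sigma2 = exp{a + b log T}.

    T is floored at ``t_floor`` (T = 0 means no observed heterogeneity,
    mapping to the strongest borrowing) and the result is clamped to
    [sigma2_min, sigma2_max].  T = None (pooled rate 0 or 1, statistic not
    computable) falls back to sigma2_max — minimal borrowing.
    """
    if T is None:
        return sigma2_max
    if T < 0:
        raise ValueError("heterogeneity statistic must be nonnegative")
    s2 = float(np.exp(tuning.a + tuning.b * np.log(max(T, t_floor))))
    return float(min(max(s2, sigma2_min), sigma2_max))


def fit_cbhm(data: BasketData, tuning: TuningPair = CBHM_TUNING,
             settings: McmcSettings = SIMULATION_SETTINGS,
             mu_mean: float = -2.19, mu_sd: float = 2.0,
             level: float = 0.95) -> PosteriorSummary:
    """Fit the BHM with sigma2 fixed by the calibrated heterogeneity map."""
    T = chi_square_heterogeneity(data)
    s2 = cbhm_sigma2(T, tuning)
    prior = PriorSpec(mu_mean, mu_sd, sigma2_fixed=s2, label="CBHM")
    return fit_bhm(data, prior, settings, level)


def pp_weight(S: float, tuning: TuningPair) -> float:
    """Logistic borrowing weight in the scaled KS distance S.

    S -> 0 gives weight 1 (identical empirical distributions, full
    borrowing); the weight is strictly decreasing in S for b > 0.
    """
    if S < 0:
        raise ValueError("similarity distance must be nonnegative")
    if S == 0.0:
        return 1.0
    return float(1.0 / (1.0 + np.exp(tuning.a + tuning.b * np.log(S))))


@dataclass
class PowerPriorResult:
    summary: PosteriorSummary
    weights: np.ndarray  # (K, K), w[k, i], diagonal 1
    borrowed_n: np.ndarray  # nominal extra sample per indication


def fit_power_prior(data: BasketData,
                    spec: PowerPriorSpec = PowerPriorSpec(),
                    level: float = 0.95) -> PowerPriorResult:
    """Closed-form pairwise power-prior analysis.

    Indication k's posterior is Beta(s1 + sum_i w_ki y_i,
    s2 + sum_i w_ki (n_i - y_i)) with w_kk = 1 and w_ki a logistic
    function of the scaled KS distance between baskets k and i.  The
    nominal borrowed size is sum_i w_ki n_i - n_k.
    """
    K = data.K
    w = np.eye(K)
    for k in range(K):
        for i in range(K):
            if i == k:
                continue
            _, s = ks_binary(data.y[k], data.n[k], data.y[i], data.n[i])
            w[k, i] = pp_weight(s, spec.tuning)
    a_post = spec.s1 + w @ data.y
    b_post = spec.s2 + w @ (data.n - data.y)
    alpha = 1.0 - level
    summary = PosteriorSummary(
        mean=a_post / (a_post + b_post),
        variance=a_post * b_post / ((a_post + b_post) ** 2 * (a_post + b_post + 1.0)),
        cri=np.column_stack([stats.beta.ppf(alpha / 2, a_post, b_post),
                             stats.beta.ppf(1 - alpha / 2, a_post, b_post)]),
        level=level,
        beta_a=a_post,
        beta_b=b_post,
    )
    borrowed = w @ data.n - data.n
    return PowerPriorResult(summary, w, borrowed)


@dataclass
class ModelSelectionResult:
    summary: PosteriorSummary
    mode: str  # "bhm" or "independent"
    ess: list[ESSResult]


def ess_based_model_selection(
    data: BasketData,
    prior: PriorSpec,
    settings: McmcSettings = SIMULATION_SETTINGS,
    beta_a: float = 0.5,
    beta_b: float = 0.5,
    level: float = 0.95,
) -> ModelSelectionResult:
    """Choose between BHM and independent analysis by analysis-stage ESS.

    If any indication's MSE-based prior ESS is negative, the whole trial
    is analyzed independently with a vague Beta prior; otherwise the BHM
    analysis stands.  Indications with not-available ESS (observed rate 0
    or 100%) are excluded from the negativity check.
    """
    ess_results = [analysis_stage_ess(data, prior, k, settings)
                   for k in range(data.K)]
    negative = any(r.status != ESS_NOT_AVAILABLE and r.prior_ess < 0
                   for r in ess_results)
    if negative:
        summary = fit_independent(data, beta_a, beta_b, level)
        mode = "independent"
    else:
        summary = fit_bhm(data, prior, settings, level)
        mode = "bhm"
    return ModelSelectionResult(summary, mode, ess_results)


# ---------------------------------------------------------------------------
# Design abstraction used by calibration and the simulation engine
# ---------------------------------------------------------------------------


class Design:
    """A borrowing strategy: fits one dataset, yields a PosteriorSummary."""

    name: str = "design"

    def fit(self, data: BasketData, seed: int) -> PosteriorSummary:
        raise NotImplementedError


@dataclass(frozen=True)
class BhmDesign(Design):
    prior: PriorSpec
    settings: McmcSettings = SIMULATION_SETTINGS
    name: str = "bhm"

    def fit(self, data: BasketData, seed: int) -> PosteriorSummary:
        return fit_bhm(data, self.prior, self.settings.with_seed(seed))


@dataclass(frozen=True)
class IndependentDesign(Design):
    beta_a: float = 0.5
    beta_b: float = 0.5
    name: str = "independent"

    def fit(self, data: BasketData, seed: int) -> PosteriorSummary:
        return fit_independent(data, self.beta_a, self.beta_b)


@dataclass(frozen=True)
class PooledDesign(Design):
    mu_mean: float = -2.19
    mu_sd: float = 2.0
    name: str = "pooled"

    def fit(self, data: BasketData, seed: int) -> PosteriorSummary:
        prior = PriorSpec(self.mu_mean, self.mu_sd, sigma2_fixed=0.0)
        return fit_bhm(data, prior, SIMULATION_SETTINGS.with_seed(seed))


@dataclass(frozen=True)
class CbhmDesign(Design):
    tuning: TuningPair = CBHM_TUNING
    settings: McmcSettings = SIMULATION_SETTINGS
    mu_mean: float = -2.19
    mu_sd: float = 2.0
    name: str = "cbhm"

    def fit(self, data: BasketData, seed: int) -> PosteriorSummary:
        return fit_cbhm(data, self.tuning, self.settings.with_seed(seed),
                        self.mu_mean, self.mu_sd)


@dataclass(frozen=True)
class PowerPriorDesign(Design):
    spec: PowerPriorSpec = PowerPriorSpec()
    name: str = "power_prior"

    def fit(self, data: BasketData, seed: int) -> PosteriorSummary:
        return fit_power_prior(data, self.spec).summary


@dataclass(frozen=True)
class ModelSelectionDesign(Design):
    prior: PriorSpec
    settings: McmcSettings = SIMULATION_SETTINGS
    name: str = "ess_ms"

    def fit(self, data: BasketData, seed: int) -> PosteriorSummary:
        res = ess_based_model_selection(data, self.prior,
                                        self.settings.with_seed(seed))
        return res.summary


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhiCalibration:
    phi: float
    achieved_rate: float
    target_alpha: float
    reps: int
    attained: bool = True


def calibrate_phi(
    scenario_null: Scenario,
    design: Design,
    target_alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
    phi_grid: np.ndarray | None = None,
) -> PhiCalibration:
    """Calibrate the shared efficacy threshold phi under the global null.

    Simulates the null scenario once, caches the per-replication posterior
    tail probabilities Pr(p_k > p0 | data), and sweeps a phi grid (the
    sweep is then free).  Picks the smallest phi whose pooled
    per-indication rejection rate does not exceed ``target_alpha`` — for
    continuous tail probabilities this lands the type I error right at the
    target, and for discrete ones (conjugate designs, where only n_k + 1
    outcomes exist) it reproduces the exact-test convention of controlling
    the level rather than overshooting it.  If even the largest phi
    overshoots, that boundary phi is returned with ``attained=False``.
    """
    if any(abs(p - scenario_null.null_orr) > 1e-12 for p in scenario_null.true_orr):
        raise ValueError("calibration scenario must put every arm at the null rate")
    if phi_grid is None:
        phi_grid = np.arange(0.5, 0.999, 0.001)
    _, tails = run_replications(scenario_null, design.fit, reps, seed,
                                threshold=scenario_null.null_orr)
    rates = np.array([(tails > phi).mean() for phi in phi_grid])
    ok = np.nonzero(rates <= target_alpha)[0]
    if ok.size:
        idx, attained = int(ok[0]), True
    else:
        idx, attained = len(phi_grid) - 1, False
    return PhiCalibration(float(phi_grid[idx]), float(rates[idx]),
                          target_alpha, reps, attained)


def _design_stage_ess_all(datasets, fit_seeds, scenario, tuning, context,
                          settings, mu_mean, mu_sd, s1, s2) -> list[ESSResult]:
    """Per-arm design-stage ESS of a tuned design on a fixed replication set."""
    truth = np.asarray(scenario.true_orr)
    sq = np.zeros(scenario.K)
    if context == "cbhm":
        for data, fs in zip(datasets, fit_seeds):
            summary = fit_cbhm(data, tuning, settings.with_seed(fs),
                               mu_mean, mu_sd)
            sq += (summary.mean - truth) ** 2
    else:
        spec = PowerPriorSpec(s1, s2, tuning)
        for data in datasets:
            sq += (fit_power_prior(data, spec).summary.mean - truth) ** 2
    mse = sq / len(datasets)
    return [ess_from_mse(mse[k], truth[k], scenario.n[k])
            for k in range(scenario.K)]


def calibrate_tuning(
    targets: list[tuple[Scenario, int, float]],
    context: str,
    grid_a: np.ndarray | None = None,
    grid_b: np.ndarray | None = None,
    reps: int = 500,
    seed: int = 0,
    settings: McmcSettings = SIMULATION_SETTINGS,
    mu_mean: float = -2.19,
    mu_sd: float = 2.0,
    s1: float = 0.5,
    s2: float = 0.5,
) -> TuningPair:
    """Grid-search (a, b) so simulated design-stage prior ESS hits targets.

    ``targets`` is a list of (scenario, indication index, target prior
    ESS); an indication index of None averages the prior ESS over all
    arms (the natural reading of a target like "each arm around 30" in an
    exchangeable scenario).  The objective is the equally-weighted sum of
    squared deviations.  The same simulated datasets (common random
    numbers) are reused across the grid, so grid comparisons are not
    washed out by simulation noise.  Deterministic given ``seed``.
    """
    if not targets:
        raise ValueError("empty target list")
    if context not in ("cbhm", "power_prior"):
        raise ValueError("context must be 'cbhm' or 'power_prior'")
    if grid_a is None:
        grid_a = np.arange(-6.0, 6.0 + 1e-9, 0.5)
    if grid_b is None:
        grid_b = np.arange(0.0, 2.0 + 1e-9, 0.1)
    grid_a, grid_b = np.atleast_1d(grid_a), np.atleast_1d(grid_b)
    if grid_a.size == 0 or grid_b.size == 0:
        raise ValueError("calibration grid must be non-empty")

    # one shared replication set per distinct scenario
    scen_cache: dict[str, tuple[list[BasketData], list[int]]] = {}
    for si, (scenario, _, _) in enumerate(targets):
        key = repr(scenario)
        if key not in scen_cache:
            pairs = replication_seeds(seed + si, reps)
            datasets = [generate_trial(scenario, ss) for ss, _ in pairs]
            scen_cache[key] = (datasets, [fs for _, fs in pairs])

    def target_ess(results: list[ESSResult], k: int | None) -> float:
        vals = [r.prior_ess for r in (results if k is None else [results[k]])]
        if any(v is None for v in vals):
            return 1e6  # degenerate arm: push this tuning away
        return float(np.mean(vals))

    best = None
    for a in grid_a:
        for b in grid_b:
            tuning = TuningPair(float(a), float(b), context)
            loss = 0.0
            for scenario, k, target in targets:
                datasets, fit_seeds = scen_cache[repr(scenario)]
                results = _design_stage_ess_all(
                    datasets, fit_seeds, scenario, tuning, context,
                    settings, mu_mean, mu_sd, s1, s2)
                loss += (target_ess(results, k) - target) ** 2
            if best is None or loss < best[0]:
                best = (loss, tuning)
    return best[1]
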