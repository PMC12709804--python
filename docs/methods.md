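# Methods

## The problem

In a basket trial one therapy is tested across `K` tumor types
(indications), each contributing `n_k` patients and `y_k` responders on a
binary response endpoint.  Bayesian analyses borrow information across
indications; the question this package answers is *how much* a given
borrowing analysis is worth, expressed in patients.

## Model

The Bayesian hierarchical model (BHM) is

```
Y_k ~ Bin(n_k, p_k),   theta_k = logit(p_k) ~ N(mu, sigma2),  k = 1..K
mu ~ N(mu_mean, mu_sd^2),   sigma2 ~ InvGamma(shape, scale)  (or fixed)
```

`sigma2` governs borrowing: `sigma2 = 0` is pooled analysis (all arms
share one rate) and `sigma2 -> inf` is independent analysis.  The default
`mu` prior is `N(-2.19, 2^2)` — centered near logit(0.10), weakly
informative on the log-odds scale.  Two hyperprior presets are shipped:

* **Prior A** — `sigma2 ~ IG(0.375, 1.5)`: moderate borrowing.
* **Prior B** — `sigma2 ~ IG(0.0005, 0.000005)`: nearly scale-free with
  enormous mass near 0, i.e. aggressive borrowing.

## MSE-based effective sample size

Let `phat_B_k` be the posterior mean of `p_k`.  The *posterior ESS* of
the borrowing analysis for indication `k` is the sample size `m + n_k` at
which an independent binomial analysis attains the same mean squared
error; the *prior ESS* is `m`.  Because the MLE of an independent
analysis is unbiased with MSE exactly `p(1-p)/(m+n)`, matching reduces to
solving `p(1-p)/(m+n) = MSE_B` over integer `m` in `[-n_k+1, m_max]`,
refined to one decimal place by linear interpolation of the signed
distance between the two bracketing integers.  The closed-form root
`p(1-p)/MSE_B - n` agrees with the interpolated value to within 0.2
(property-tested); the grid+interpolation form is kept because it is the
defined estimand and degrades gracefully at the search bounds (`capped`
status instead of extrapolation).

`MSE_B` is obtained two ways:

* **Design stage** (truth known): simulate full trials from a scenario,
  fit the BHM to each, average `(phat_B_k - p_k)^2`.  MSE = variance +
  bias^2 holds exactly on the same replications and is tested as an
  identity.
* **Analysis stage** (truth unknown): replace `p_k` by the observed rate
  `y_k/n_k` and compute the expectation *exactly* by enumerating all
  `n_k + 1` possible own-arm outcomes, refitting with the other arms held
  at their observed data and weighting by `Bin(y'; n_k, y_k/n_k)`.
  Enumeration is preferred to resampling because the support is finite —
  the expectation is exact given the fitter.  A common MCMC seed is used
  across the enumeration so sampler noise largely cancels.

When the reference rate is 0 or 1 the independent-analysis MSE is
identically zero at every sample size, so the ESS is undefined; such arms
carry a `not_available` status rather than a number.

Negative prior ESS means borrowing-induced bias outweighs the variance
reduction — the framework's warning against pooling a heterogeneous arm.

A *variance-ratio* ESS (`posterior ESS = m(1-m)/Var(p_k|data)` with `m`
the posterior mean) is provided for comparison.  This is a
reconstruction: it is defined so that a `Beta(a, b)` posterior yields
exactly `a + b + 1`, and it deliberately ignores bias, which is precisely
why it fails to flag harmful borrowing in heterogeneous scenarios.

## Sampler

The BHM posterior is sampled by a Gibbs scheme written for throughput
(numba-compiled, ~10-20 ms per fit at the default 5,000 iterations):
slice updates of each `theta_k`, a conjugate normal update of `mu`, and a
conjugate inverse-gamma update of `sigma2`, interleaved each sweep with
non-centered (ancillary) slice updates of `log sigma2` and `mu` in the
parameterization `eta_k = (theta_k - mu)/sigma`.  The interweaving is
essential under Prior B: its near-improper hyperprior creates a funnel at
`sigma2 ~ 0` in which a purely centered Gibbs chain stalls (the arms pin
`mu`, `mu` pins the arms).  `sigma2 = 0` is not sampled at all — the
pooled model is integrated exactly on a one-dimensional grid, with draws
generated by inverse-CDF sampling so the result object has the same shape.

Defaults: 5,000 iterations / 2,000 burn-in for simulation loops, 20,000 /
5,000 for single-dataset analysis; a single master seed spawns
per-replication substreams (data and fit separately), so results are
reproducible and independent of evaluation order.  Chains were validated
against deterministic quadrature oracles at both borrowing limits
(`sigma2 = 0` pooled; `sigma2 = 1e4` per-arm logit-normal) and by the
conjugate closed form for the independent analysis.

## Decision rule and calibration

Arm `k` is declared efficacious when `Pr(p_k > p0 | data) > phi` with
`p0 = 0.15`.  A single `phi` shared by all arms is calibrated under the
global-null scenario: the per-replication tail probabilities are computed
once, and the smallest grid value (step 0.001 on (0.5, 0.999)) whose null
rejection rate does not exceed the 5% target is chosen.  Level-control
(rather than nearest-to-target) is deliberate: conjugate designs have
only `n_k + 1` attainable tail values, and the nearest rule would select
a rule overshooting 5% (6.98% at n=30), whereas level-control makes the
calibrated independent design coincide exactly with the one-sided exact
binomial test.  For continuous BHM tails the two rules agree at ~5%.

The exact-test benchmark itself: the non-randomized one-sided 5% test at
`n=30, p0=0.15` rejects iff `Y >= 9` and has power 56.85% at ORR 0.3 —
commonly quoted as ~58%.

## ESS-based designs

* **Model selection (MS)** — compute the analysis-stage prior ESS for
  every arm (under Prior B by default); if any is negative, analyze all
  arms independently with a vague `Beta(0.5, 0.5)` prior.  Arms with
  `not_available` ESS are excluded from the negativity check.  The
  all-or-nothing rule is the default; excluding only the offending arms
  is a documented variant left to the caller for large `K`.
* **Calibrated BHM (CBHM)** — fix `sigma2 = exp{a + b log T}` where `T`
  is the Pearson chi-square statistic of the `K x 2` responder table
  against the pooled rate (uncorrected; the statistic is configurable).
  `T` is floored at `1e-6` (identical observed rates = strongest
  borrowing) and `sigma2` clamped to `[1e-4, 1e4]`; an incomputable `T`
  (pooled rate 0 or 1) falls back to `sigma2_max`, i.e. minimal
  borrowing.
* **Power prior (PP)** — conjugate pairwise borrowing: arm `k`'s
  posterior is `Beta(s1 + sum_i w_ki y_i, s2 + sum_i w_ki (n_i - y_i))`
  with `w_kk = 1` and `w_ki = 1/(1 + exp{a + b log S_ki})`,
  `S_ki = max(n_k, n_i)^(1/4) |y_k/n_k - y_i/n_i|` (the two-sample KS
  statistic reduces to the proportion gap for binary data).  Initial
  `s1 = s2 = 0.5`, matching the vague prior used elsewhere.  The nominal
  borrowed size is `sum_i w_ki n_i - n_k`.

### Tuning calibration

`(a, b)` of CBHM and PP are calibrated by grid search so the simulated
design-stage prior ESS hits interpretable targets — here, ~30 per arm in
the global alternative (equal to `n_k`) and ~0 for the lone null arm of
the mixed scenario.  The "each arm around 30" target is read as the
cross-arm average (the scenario is exchangeable).  The objective is the
equally-weighted sum of squared deviations; the same simulated datasets
are reused across the grid (common random numbers) so grid comparisons
are not washed out by noise.  Default grid `a` in [-6, 6] step 0.5, `b`
in [0, 2] step 0.1; the `b` direction is the flattest, so coarse grids
are recommended when replication is limited.

## Synthetic data and scope

The generator draws `Y_k ~ Bin(n_k, p_k)` independently per arm — exactly
the data-generating process of the benchmark study (five scenarios,
`K = 4`, `n_k = 30`, ORR 0.15/0.30, null 0.15, target 0.30).  It does not
emulate accrual over time, within-indication heterogeneity,
non-exchangeable covariates, or misclassified responses, so passing tests
certify the statistical machinery under the stated model, not robustness
to those real-data features.  Reanalysis of real trial data is supported
through the `indication,n,y` CSV loader; per-cohort counts from published
trials are user-supplied, not shipped.

## Problem sizes and tolerances

Simulation-based quantities are computed at reduced replication as a
desk-scale choice: 2,000 replications in `scripts/acceptance.py`, 500-600
in the acceptance tests, versus 10,000 in the reference study.  Every
stochastic check carries an explicit Monte Carlo tolerance: a
delta-method standard error for matched ESS
(`se = p(1-p)/MSE^2 * se(MSE)`), binomial standard errors for rejection
rates, and 3-sigma bands throughout.  ESS values are reported to one
decimal place; MSE in units of 1e-3; rejection rates in percent.

## Known limitations

* The variance-ratio ESS is a reconstruction (see above); small additive
  constants relative to other definitions are possible.
* The MS design refits the BHM `n_k + 1` times per arm, so simulating its
  operating characteristics at scale is expensive; the implementation is
  exact but best used at analysis time or with modest replication.
* The treatment-difference parameterization
  `theta_k = logit(p_k) - logit(p_k0)`, alternative distance measures
  (relative entropy, log-density curvature), randomized/adaptive basket
  designs and multiple endpoints are out of scope.
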