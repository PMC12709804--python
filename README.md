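# basketess

**Effective sample size for Bayesian basket trials, on the MSE scale.**

Basket trials test one therapy across several tumor types (indications)
that share a molecular target.  Bayesian analyses — most commonly the
Bayesian hierarchical model (BHM) — borrow information across
indications, but "how much is being borrowed?" has no obvious answer: a
posterior between-group variance of 0.13 means little to a clinical
team.  This package answers the question in the most interpretable unit
available, *patients*, for trial statisticians designing or reanalyzing
basket studies.

## The idea

For indication *k* with `n_k` patients, fit the hierarchical model

```
Y_k ~ Bin(n_k, p_k),  logit(p_k) = θ_k ~ N(μ, σ²),
μ ~ N(μ₀, s₀²),  σ² ~ IG(a, b)
```

and measure the mean squared error of its posterior-mean estimator
`p̂ᴮ_k`.  An *independent* binomial analysis with `m + n_k` patients has
MSE exactly `p(1−p)/(m+n_k)`, so there is a unique sample size at which
independence matches the Bayesian MSE:

```
posterior ESS = the m + n_k solving p(1−p)/(m+n_k) = MSE(p̂ᴮ_k)
prior ESS     = posterior ESS − n_k
```

Because MSE = variance + bias², the prior ESS rewards borrowing that
reduces variance and *penalizes* borrowing that adds bias: a negative
prior ESS is a quantitative warning that an indication should probably
not be pooled with the others.  (Variance-ratio ESS, which ignores bias,
is included for comparison.)  The matched ESS drives three designs: model
selection (fall back to independent analysis when any arm's ESS is
negative), a calibrated BHM with `σ² = exp{a + b·log T}` for a
heterogeneity statistic `T`, and a conjugate power prior with pairwise
Kolmogorov–Smirnov weights — the last two tuned so the *prior ESS itself*
hits targets (≈30 per arm under the global alternative, ≈0 for a null
arm in a mixed scenario).

## Worked example

Design-stage question: *if all four arms are truly null (ORR 0.15,
n = 30 each), how much will the model borrow?*

```python
from basketess import PRIOR_A, PRIOR_B, builtin_scenarios, design_stage_ess

scenario = builtin_scenarios()[0]          # global null
for prior in (PRIOR_A, PRIOR_B):
    for k, r in enumerate(design_stage_ess(scenario, prior, reps=500, seed=11)):
        print(prior.label, k + 1, round(r.prior_ess, 1), r.mse_bayes)
```

Output (`python examples/design_stage_ess.py`):

```
Prior A (sigma2 ~ IG(0.375, 1.5)), 500 replications:
  arm 1: prior ESS   10.9   MSE 3.1e-3
  ...
Prior B (sigma2 ~ IG(0.0005, 5e-06)), 500 replications:
  arm 1: prior ESS   76.7   MSE 1.2e-3
  ...
```

Under the moderate Prior A each arm's analysis behaves like an
independent analysis with ~11 extra patients; under the aggressive
Prior B like one with ~75 extra patients — more than twice the arm's own
enrollment, which a review team may consider excessive.  Run the same
scenario with one effective arm among nulls and the null arms' prior ESS
turns negative, flagging harmful borrowing; the companion operating
characteristics (`examples/operating_characteristics.py`) show the
matching type I error inflation.

More narrative scripts live in `examples/`: analysis of an observed
trial CSV with Clopper–Pearson vs BHM estimates and per-arm prior ESS,
power-prior weight matrices, and a scenario × design simulation.

A thin CLI wraps the same functions:

```sh
basketess analyze --data trial.csv --prior A
basketess ess-design --scenario 1 --prior B --reps 1000
basketess simulate --config config.yaml
basketess calibrate-phi --design bhm --prior B
basketess calibrate-tuning --context cbhm
basketess fixtures --out-dir fixtures
```

`analyze` expects a UTF-8 CSV with header `indication,n,y`, one row per
tumor type, so published per-cohort count tables can be transcribed
directly.

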