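"""Analyze one observed basket trial: estimates and prior ESS per arm.

Builds a five-indication trial summary, fits the Bayesian hierarchical
model under the moderate-borrowing prior, and prints for every arm the
frequentist estimate (exact Clopper-Pearson interval), the Bayesian
posterior mean (equal-tailed credible interval), and the analysis-stage
MSE-based prior ESS — the number of extra patients the borrowing is
worth (negative = borrowing is adding bias, NA = observed rate 0%/100%).
"""

from basketess import (
    BasketData,
    PRIOR_A,
    McmcSettings,
    analysis_stage_ess,
    clopper_pearson,
    fit_bhm,
)

data = BasketData(
    labels=["cholangio", "breast", "pancreatic", "glioma", "salivary"],
    n=[25, 16, 20, 12, 18],
    y=[10, 5, 3, 0, 5],
)

settings = McmcSettings(iterations=20000, burn_in=5000, seed=1)
fit = fit_bhm(data, PRIOR_A, settings)
ess_settings = McmcSettings(iterations=5000, burn_in=2000, seed=1)

pooled = data.y.sum() / data.n.sum()
print(f"pooled ORR: {100 * pooled:.1f}%\n")
print(f"{'arm':<12}{'y/n':>7}{'freq % (95% CI)':>22}"
      f"{'BHM % (95% CrI)':>22}{'prior ESS':>11}")
for k, label in enumerate(data.labels):
    lo, hi = clopper_pearson(int(data.y[k]), int(data.n[k]))
    r = analysis_stage_ess(data, PRIOR_A, k, ess_settings)
    ess = "NA" if r.prior_ess is None else f"{r.prior_ess:.1f}"
    print(f"{label:<12}{data.y[k]:>3}/{data.n[k]:<3}"
          f"{100 * data.phat[k]:>8.1f} ({100 * lo:.1f}, {100 * hi:.1f})"
          f"{100 * fit.mean[k]:>10.1f} ({100 * fit.cri[k, 0]:.1f}, "
          f"{100 * fit.cri[k, 1]:.1f})"
          f"{ess:>9}")

print("\nArms near the pooled rate earn positive prior ESS (borrowing "
      "reduces MSE); outlying arms earn small or negative ESS; the "
      "0-responder arm has no defined ESS because the independent-analysis "
      "MSE at its observed rate is identically zero.")
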