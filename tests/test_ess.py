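"""MSE-matching effective sample size: closed-form oracle agreement,
decomposition identities, analysis-stage enumeration, variance-ratio ESS."""

import numpy as np
import pytest
from scipy import stats

from basketess.bhm import fit_bhm, fit_independent
from basketess.ess import (
    analysis_stage_ess,
    design_stage_ess,
    design_stage_mse_bayes,
    ess_from_mse,
    independent_mse,
    variance_ratio_ess,
)
from basketess.types import (
    ESS_CAPPED,
    ESS_NOT_AVAILABLE,
    ESS_OK,
    BasketData,
    McmcSettings,
    PRIOR_A,
    PRIOR_B,
    PriorSpec,
    Scenario,
)

FAST = McmcSettings(iterations=3000, burn_in=1000, seed=5)


class TestIndependentMse:
    def test_degenerate_rate_is_zero(self):
        assert independent_mse(0.0, 30) == 0.0
        assert independent_mse(1.0, 30) == 0.0

    def test_arithmetic(self):
        assert independent_mse(0.5, 10) == pytest.approx(0.025)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(4)
        draws = rng.binomial(30, 0.3, size=200_000) / 30
        mc = np.mean((draws - 0.3) ** 2)
        se = np.std((draws - 0.3) ** 2) / np.sqrt(draws.size)
        assert abs(independent_mse(0.3, 30) - mc) < 3 * se


class TestEssFromMse:
    def test_zero_prior_ess_at_own_sample_size(self):
        r = ess_from_mse(independent_mse(0.3, 30), 0.3, 30)
        assert r.prior_ess == pytest.approx(0.0, abs=1e-9)
        assert r.posterior_ess == pytest.approx(30.0, abs=1e-9)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_not_available_at_degenerate_rate(self, p):
        r = ess_from_mse(1e-3, p, 30)
        assert r.status == ESS_NOT_AVAILABLE
        assert r.prior_ess is None and r.posterior_ess is None

    def test_interpolation_close_to_closed_form(self):
        """Grid + interpolation vs the exact root p(1-p)/mse - n."""
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(300):
            p = rng.uniform(0.02, 0.98)
            n = rng.integers(5, 200)
            # MSE between the n+large and n-small matching extremes
            total = rng.uniform(1.5, 8 * n)
            mse = p * (1 - p) / total
            r = ess_from_mse(mse, p, int(n), m_max=int(12 * n))
            closed = p * (1 - p) / mse - n
            worst = max(worst, abs(r.prior_ess - closed))
        assert worst <= 0.2

    def test_prior_ess_identity_and_match_consistency(self):
        r = ess_from_mse(2e-3, 0.3, 30)
        assert r.status == ESS_OK
        assert r.prior_ess == pytest.approx(r.posterior_ess - 30, abs=1e-12)
        assert r.mse_independent_at_match == pytest.approx(r.mse_bayes,
                                                           rel=0.02)

    def test_capped_when_mse_tiny(self):
        r = ess_from_mse(1e-9, 0.3, 30, m_max=100)
        assert r.status == ESS_CAPPED
        assert r.prior_ess == 100

    def test_capped_when_mse_huge(self):
        # 0.25 exceeds p(1-p)/1 = 0.21: no independent sample size matches
        r = ess_from_mse(0.25, 0.3, 30)
        assert r.status == ESS_CAPPED
        assert r.prior_ess == -29


class TestDesignStage:
    def test_mse_decomposition_identity(self):
        """MSE = Var + Bias^2 holds exactly on the same replications."""
        scenario = Scenario((0.3, 0.15), (15, 15))
        mse, est = design_stage_mse_bayes(scenario, PRIOR_A, reps=40, seed=3,
                                          settings=FAST,
                                          return_estimates=True)
        truth = np.asarray(scenario.true_orr)
        var = est.var(axis=0)
        bias2 = (est.mean(axis=0) - truth) ** 2
        assert mse == pytest.approx(var + bias2, rel=1e-12)

    def test_borrowing_beats_independence_under_homogeneity(self):
        """Strong borrowing on truly homogeneous arms reduces MSE below
        the independent benchmark p(1-p)/n."""
        scenario = Scenario((0.2,) * 4, (20,) * 4)
        prior = PriorSpec(-2.19, 2.0, sigma2_fixed=0.001)
        mse = design_stage_mse_bayes(scenario, prior, reps=120, seed=8,
                                     settings=FAST)
        assert np.all(mse < independent_mse(0.2, 20))

    def test_relabeling_invariance(self):
        """Arms with identical (n, p) have exchangeable design-stage ESS."""
        scenario = Scenario((0.2, 0.2, 0.2), (25,) * 3)
        results = design_stage_ess(scenario, PRIOR_B, reps=150, seed=21,
                                   settings=FAST)
        ess = [r.prior_ess for r in results]
        assert np.ptp(ess) < 0.35 * max(abs(np.mean(ess)), 10.0)


class TestAnalysisStage:
    def test_not_available_at_extreme_observed_rates(self, flat_prior):
        data = BasketData(["a", "b"], [10, 10], [0, 10])
        for k in range(2):
            r = analysis_stage_ess(data, flat_prior, k, FAST)
            assert r.status == ESS_NOT_AVAILABLE

    def test_brute_force_oracle(self, tiny_data, flat_prior):
        """Independent re-implementation: enumerate own-arm outcomes and
        call the fitter directly, then match the MSE by the closed form."""
        k = 0
        r = analysis_stage_ess(tiny_data, flat_prior, k, FAST)

        phat = tiny_data.y[k] / tiny_data.n[k]
        mse = 0.0
        for y_prime in range(tiny_data.n[k] + 1):
            perturbed = BasketData(tiny_data.labels, tiny_data.n,
                                   [y_prime, int(tiny_data.y[1])])
            fit = fit_bhm(perturbed, flat_prior, FAST)
            w = stats.binom.pmf(y_prime, tiny_data.n[k], phat)
            mse += w * (fit.mean[k] - phat) ** 2
        oracle_prior_ess = phat * (1 - phat) / mse - tiny_data.n[k]
        assert r.prior_ess == pytest.approx(oracle_prior_ess, abs=0.25)

    def test_homogeneous_data_borrowing_helps(self, flat_prior):
        """When all arms agree, borrowing cannot hurt: prior ESS > 0."""
        data = BasketData(["a", "b", "c"], [20, 20, 20], [5, 5, 5])
        for prior in (flat_prior, PRIOR_B):
            r = analysis_stage_ess(data, prior, 0, FAST)
            assert r.status == ESS_OK
            assert r.prior_ess > 0


class TestVarianceRatio:
    def test_beta_posterior_identity(self):
        """For a Beta(a, b) posterior the VR posterior ESS is a + b + 1."""
        data = BasketData(["a", "b"], [20, 20], [6, 9])
        fit = fit_independent(data, 0.5, 0.5)
        for k in range(2):
            r = variance_ratio_ess(fit, data, k)
            a, b = fit.beta_a[k], fit.beta_b[k]
            assert r.posterior_ess == pytest.approx(a + b + 1, rel=1e-9)
            assert r.prior_ess == pytest.approx(a + b + 1 - 20, rel=1e-6)
            assert r.method == "variance_ratio"

    def test_inverse_proportional_to_variance(self):
        from basketess.types import PosteriorSummary

        data = BasketData(["a"], [20], [6])
        fit = fit_independent(data)
        base = PosteriorSummary(fit.mean, fit.variance, fit.cri)
        halved = PosteriorSummary(fit.mean, fit.variance / 2, fit.cri)
        r1 = variance_ratio_ess(base, data, 0)
        r2 = variance_ratio_ess(halved, data, 0)
        assert r2.posterior_ess == pytest.approx(2 * r1.posterior_ess)

    def test_degenerate_observed_rate(self):
        data = BasketData(["a"], [20], [0])
        fit = fit_independent(data)
        assert variance_ratio_ess(fit, data, 0).status == ESS_NOT_AVAILABLE

    def test_agrees_with_mse_based_on_homogeneous_data(self, flat_prior):
        """Without bias the two ESS notions coincide approximately."""
        data = BasketData(["a", "b", "c", "d"], [30] * 4, [9, 9, 9, 9])
        fit = fit_bhm(data, flat_prior, FAST)
        vr = variance_ratio_ess(fit, data, 0)
        mse = analysis_stage_ess(data, flat_prior, 0, FAST)
        assert np.sign(vr.prior_ess) == np.sign(mse.prior_ess)
        assert abs(vr.prior_ess - mse.prior_ess) < 0.6 * max(
            abs(vr.prior_ess), abs(mse.prior_ess), 5.0)
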