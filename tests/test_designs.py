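"""Borrowing strategies: CBHM heterogeneity map, power-prior weights and
posteriors, ESS-driven model selection, and calibration."""

import numpy as np
import pytest

from basketess.bhm import fit_independent, pooled_quadrature
from basketess.core import exact_binomial_power, exact_binomial_rule
from basketess.designs import (
    CbhmDesign,
    IndependentDesign,
    PowerPriorDesign,
    PowerPriorSpec,
    TuningPair,
    calibrate_phi,
    calibrate_tuning,
    cbhm_sigma2,
    ess_based_model_selection,
    fit_cbhm,
    fit_power_prior,
    pp_weight,
)
from basketess.types import BasketData, McmcSettings, PRIOR_B, PriorSpec, Scenario

FAST = McmcSettings(iterations=3000, burn_in=1000, seed=5)


class TestCbhmSigma2:
    def test_unit_heterogeneity(self):
        assert cbhm_sigma2(1.0, TuningPair(-2, 0.4)) == pytest.approx(np.exp(-2))

    def test_arbitrary_point(self):
        expected = np.exp(-2 + 0.4 * np.log(10))
        assert cbhm_sigma2(10.0, TuningPair(-2, 0.4)) == pytest.approx(expected)

    def test_monotone_in_t(self):
        t = TuningPair(-2, 0.4)
        vals = [cbhm_sigma2(x, t) for x in (0.01, 0.1, 1, 10, 100)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_floor_and_clamp(self):
        t = TuningPair(-2, 0.4)
        assert cbhm_sigma2(0.0, t) == cbhm_sigma2(1e-6, t)  # floored T
        assert cbhm_sigma2(0.0, TuningPair(-50, 1)) == 1e-4  # clamped below
        assert cbhm_sigma2(1e30, TuningPair(50, 1)) == 1e4  # clamped above
        assert cbhm_sigma2(None, t) == 1e4  # not-computable fallback


class TestFitCbhm:
    def test_identical_proportions_approach_pooled(self):
        """T = 0 maps to a tiny sigma2: estimates collapse to the pooled
        analysis (quadrature oracle)."""
        data = BasketData(list("abcd"), [30] * 4, [6] * 4)
        fit = fit_cbhm(data, TuningPair(-2, 0.4), FAST)
        pooled = pooled_quadrature(data, PriorSpec(-2.19, 2, sigma2_fixed=0.0))
        assert fit.mean == pytest.approx(np.full(4, pooled.mean[0]), abs=0.01)

    def test_discrepant_proportions_approach_independence(self):
        """Large T maps to a large sigma2: estimates stay close to the
        per-arm observed rates instead of collapsing to the pooled 0.42."""
        data = BasketData(["a", "b"], [30, 30], [0, 25])
        fit = fit_cbhm(data, TuningPair(-2, 0.4), FAST)
        assert fit.mean[0] < 0.15
        assert fit.mean[1] > 0.6

    def test_permutation_invariance(self):
        d1 = BasketData(list("abcd"), [30] * 4, [3, 6, 9, 12])
        d2 = BasketData(list("dcba"), [30] * 4, [12, 9, 6, 3])
        f1 = fit_cbhm(d1, TuningPair(-2, 0.4), FAST)
        f2 = fit_cbhm(d2, TuningPair(-2, 0.4), FAST)
        assert f1.mean == pytest.approx(f2.mean[::-1], abs=0.015)


class TestPowerPriorWeights:
    def test_zero_distance_full_weight(self):
        assert pp_weight(0.0, TuningPair(2, 0.4, "power_prior")) == 1.0

    def test_unit_distance(self):
        w = pp_weight(1.0, TuningPair(2, 0.4, "power_prior"))
        assert w == pytest.approx(1 / (1 + np.exp(2)), rel=1e-12)
        assert w == pytest.approx(0.119, abs=5e-4)

    def test_strictly_decreasing(self):
        t = TuningPair(2, 0.4, "power_prior")
        ws = [pp_weight(s, t) for s in (0.01, 0.1, 0.5, 1, 2, 5)]
        assert all(a > b for a, b in zip(ws, ws[1:]))


class TestFitPowerPrior:
    def test_no_borrowing_identity(self):
        """Off-diagonal weights ~0 leave the own-arm conjugate posterior."""
        data = BasketData(["a", "b"], [30, 30], [3, 27])
        # huge a makes every cross-arm weight vanish
        spec = PowerPriorSpec(0.5, 0.5, TuningPair(50, 0.4, "power_prior"))
        res = fit_power_prior(data, spec)
        assert res.summary.beta_a == pytest.approx([3.5, 27.5], abs=1e-6)
        assert res.summary.beta_b == pytest.approx([27.5, 3.5], abs=1e-6)
        assert res.borrowed_n == pytest.approx([0.0, 0.0], abs=1e-4)

    def test_full_borrowing_identity(self):
        """Identical observed rates give weight 1 everywhere: the pooled
        conjugate posterior."""
        data = BasketData(["a", "b", "c"], [30, 30, 30], [6, 6, 6])
        res = fit_power_prior(data, PowerPriorSpec(0.5, 0.5,
                                                   TuningPair(2, 0.4, "power_prior")))
        assert np.all(res.weights == 1.0)
        assert res.summary.beta_a == pytest.approx(np.full(3, 0.5 + 18))
        assert res.summary.beta_b == pytest.approx(np.full(3, 0.5 + 72))
        assert res.borrowed_n == pytest.approx(np.full(3, 60.0))

    def test_chained_arithmetic_oracle(self):
        """Hand-assembled computation: KS distance -> logistic weight ->
        weighted conjugate update, for K=2."""
        data = BasketData(["a", "b"], [30, 30], [6, 15])
        t = TuningPair(2.0, 0.4, "power_prior")
        res = fit_power_prior(data, PowerPriorSpec(0.5, 0.5, t))

        s = 30 ** 0.25 * abs(6 / 30 - 15 / 30)
        w = 1 / (1 + np.exp(2.0 + 0.4 * np.log(s)))
        assert res.weights[0, 1] == pytest.approx(w, rel=1e-12)
        assert res.summary.beta_a[0] == pytest.approx(0.5 + 6 + w * 15)
        assert res.summary.beta_b[0] == pytest.approx(0.5 + 24 + w * 15)
        assert res.summary.beta_a[1] == pytest.approx(0.5 + 15 + w * 6)
        assert res.borrowed_n[0] == pytest.approx(30 * w)

    def test_monotone_in_similarity(self):
        """Closer outcomes borrow more: the nominal borrowed size shrinks
        as the second arm moves away from the first."""
        borrowed = []
        for y2 in (6, 10, 15, 24):
            data = BasketData(["a", "b"], [30, 30], [6, y2])
            res = fit_power_prior(data)
            borrowed.append(res.borrowed_n[0])
        assert all(a > b for a, b in zip(borrowed, borrowed[1:]))


class TestModelSelection:
    def test_negative_ess_triggers_independent(self):
        """A sharply discrepant arm yields negative analysis-stage prior
        ESS; the strategy falls back to Beta(0.5,0.5) independence."""
        data = BasketData(["a", "b"], [12, 12], [2, 11])
        res = ess_based_model_selection(data, PRIOR_B, FAST)
        assert res.mode == "independent"
        assert any(r.prior_ess is not None and r.prior_ess < 0
                   for r in res.ess)
        indep = fit_independent(data, 0.5, 0.5)
        assert res.summary.mean == pytest.approx(indep.mean, rel=1e-12)

    def test_homogeneous_keeps_bhm(self):
        data = BasketData(["a", "b"], [12, 12], [3, 3])
        res = ess_based_model_selection(data, PRIOR_B, FAST)
        assert res.mode == "bhm"
        assert all(r.prior_ess > 0 for r in res.ess)

    def test_decision_invariant_to_arm_order(self):
        d1 = BasketData(["a", "b"], [12, 12], [2, 11])
        d2 = BasketData(["b", "a"], [12, 12], [11, 2])
        m1 = ess_based_model_selection(d1, PRIOR_B, FAST).mode
        m2 = ess_based_model_selection(d2, PRIOR_B, FAST).mode
        assert m1 == m2 == "independent"


class TestCalibratePhi:
    def test_zero_target_is_most_conservative(self, null_scenario):
        cal = calibrate_phi(null_scenario, IndependentDesign(),
                            target_alpha=1e-9, reps=50, seed=1)
        assert cal.achieved_rate == 0.0 or not cal.attained

    def test_rejects_non_null_scenario(self):
        alt = Scenario((0.3,) * 4, (30,) * 4)
        with pytest.raises(ValueError):
            calibrate_phi(alt, IndependentDesign(), reps=10, seed=0)

    def test_independent_design_recovers_exact_test(self, null_scenario):
        """The calibrated conjugate rule is the exact binomial test in
        disguise: same critical count, hence same power."""
        from scipy import stats

        cal = calibrate_phi(null_scenario, IndependentDesign(), 0.05,
                            reps=2000, seed=17)
        tails = stats.beta.sf(0.15, 0.5 + np.arange(31),
                              0.5 + 30 - np.arange(31))
        implied_c = int(np.argmax(tails > cal.phi))
        assert implied_c == exact_binomial_rule(30, 0.15, 0.05)
        power = float(stats.binom.sf(implied_c - 1, 30, 0.3))
        assert power == pytest.approx(exact_binomial_power(30, 0.15, 0.3, 0.05))


class TestCalibrateTuning:
    def test_singleton_grid(self, null_scenario):
        pair = calibrate_tuning([(null_scenario, None, 30.0)], "power_prior",
                                grid_a=np.array([2.0]), grid_b=np.array([0.4]),
                                reps=20, seed=0)
        assert (pair.a, pair.b) == (2.0, 0.4)

    def test_empty_inputs_rejected(self, null_scenario):
        with pytest.raises(ValueError):
            calibrate_tuning([], "power_prior")
        with pytest.raises(ValueError):
            calibrate_tuning([(null_scenario, None, 30.0)], "power_prior",
                             grid_a=np.array([]), grid_b=np.array([0.4]))
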