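"""Multistage calibration: transition law, boundaries, stagewise sizes."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

import enrichsel as es
from enrichsel.multistage import obf_boundaries, stagewise_probabilities


class TestTransitionDensity:
    def test_closed_form_parameters(self):
        # theta=0, equal stage information: mean z/sqrt(2), variance 1/2
        z_prev, i1, i2 = 0.8, 1.0, math.sqrt(2.0)
        grid = np.linspace(-5, 5, 11)
        got = es.transition_density(grid, z_prev, i2, i1, 0.0)
        sd = math.sqrt(0.5)
        want = norm.pdf(grid, loc=z_prev / math.sqrt(2.0), scale=sd)
        assert np.allclose(got, want, atol=1e-12)

    def test_marginal_consistency_under_null(self):
        # Integrating the transition kernel against a standard normal
        # stage-1 law must return a standard normal accumulated law.
        i1, i2 = 1.0, math.sqrt(2.0)
        for z in (-1.0, 0.0, 1.7):
            val, _ = quad(lambda zp: norm.pdf(zp)
                          * es.transition_density(z, zp, i2, i1, 0.0),
                          -9, 9)
            assert val == pytest.approx(norm.pdf(z), abs=1e-9)

    def test_moments_match_direct_accumulation(self):
        # Independent oracle: accumulate two stage increments directly
        # as information-weighted means and compare with the kernel's
        # conditional moments.
        rng = np.random.default_rng(3)
        theta, sigma = 0.5, 1.0
        n1, n2 = 120.0, 180.0
        i1 = es.information_level(n1, sigma)
        i2 = es.information_level(n1 + n2, sigma)
        i_inc = es.information_level(n2, sigma)
        z1 = rng.normal(theta * i1, 1.0, size=1_000_000)
        z_inc = rng.normal(theta * i_inc, 1.0, size=1_000_000)
        z_acc = (i1 * z1 + i_inc * z_inc) / i2
        resid = z_acc - z1 * i1 / i2       # remove the conditional slope
        want_mean = theta * (i2 ** 2 - i1 ** 2) / i2
        want_var = (i2 ** 2 - i1 ** 2) / i2 ** 2
        assert resid.mean() == pytest.approx(want_mean,
                                             abs=3 * resid.std() / 1000)
        assert resid.var() == pytest.approx(want_var, rel=5e-3)

    def test_decreasing_information_rejected(self):
        with pytest.raises(ValueError):
            es.transition_density(0.0, 0.0, 1.0, 1.5, 0.0)


def _one_pop():
    return es.PopulationSet((1.0,), (frozenset({1}),))


class TestCalibrateBoundaries:
    def test_single_population_two_stage_obf_matches_classical_oracle(self):
        # Independent oracle: for one population and equal stages the
        # FWER is P(Z1 >= c*sqrt(2)) + P(Z1 < c*sqrt(2), Zacc >= c) with
        # corr(Z1, Zacc) = sqrt(1/2) — a bivariate-normal closed form.
        cov = np.array([[1.0, math.sqrt(0.5)], [math.sqrt(0.5), 1.0]])
        mvn = multivariate_normal(mean=[0, 0], cov=cov)

        def fwer(c):
            p_stop1 = norm.sf(c * math.sqrt(2.0))
            p_cross2 = (norm.cdf(c * math.sqrt(2.0))
                        - mvn.cdf([c * math.sqrt(2.0), c]))
            return p_stop1 + p_cross2

        c_oracle = brentq(lambda c: fwer(c) - 0.025, 1.8, 2.2, xtol=1e-10)
        b = es.calibrate_boundaries(_one_pop(), 0.025, 2,
                                    lower_bound=-np.inf, binding=False)
        assert b.upper[1] == pytest.approx(c_oracle, abs=1e-4)
        assert b.upper[1] == pytest.approx(1.9774, abs=1e-3)
        assert b.upper[0] == pytest.approx(c_oracle * math.sqrt(2), abs=2e-4)

    def test_degenerate_single_stage(self, ps2, c_alpha_2pop):
        b = es.calibrate_boundaries(ps2, 0.025, 1)
        assert b.upper[0] == pytest.approx(c_alpha_2pop, abs=1e-6)

    def test_obf_bounds_strictly_decreasing(self, design4):
        assert np.all(np.diff(design4.boundaries.upper) < 0)

    def test_constant_grows_with_candidate_count(self, ps2, ps3):
        c1 = es.calibrate_boundaries(_one_pop(), 0.025, 2).upper[1]
        c2 = es.calibrate_boundaries(ps2, 0.025, 2).upper[1]
        c3 = es.calibrate_boundaries(ps3, 0.025, 2).upper[1]
        assert c1 < c2 < c3

    def test_nonbinding_not_smaller_than_binding(self, ps2):
        bind = es.calibrate_boundaries(ps2, 0.025, 2, lower_bound=0.0,
                                       binding=True)
        nonb = es.calibrate_boundaries(ps2, 0.025, 2, lower_bound=0.0,
                                       binding=False)
        assert nonb.upper[1] >= bind.upper[1]


class TestStagewiseProbabilities:
    def test_total_probability_sums_to_one(self, ps3, eff3, design4):
        total = 0.0
        for w in range(3):
            probs = stagewise_probabilities(ps3, eff3,
                                            list(design4.stage_n),
                                            design4.boundaries, w)
            total += sum(p["efficacy"] + p["futility"] for p in probs)
        assert total == pytest.approx(1.0, abs=1e-5)

    def test_matches_simulation(self, ps3, eff3, design4, design4_records):
        rec = design4_records
        R = len(rec)
        for w in range(3):
            probs = stagewise_probabilities(ps3, eff3,
                                            list(design4.stage_n),
                                            design4.boundaries, w)
            for k, decision in ((1, "efficacy"), (2, "efficacy"),
                                (1, "futility"), (2, "futility")):
                if decision == "efficacy":
                    hit = ((rec["W"] == w) & (rec["M"] == k)
                           & rec["rejected"])
                else:
                    hit = ((rec["W"] == w) & (rec["M"] == k)
                           & ~rec["rejected"])
                p_hat = hit.mean()
                band = 3 * math.sqrt(max(p_hat * (1 - p_hat), 1e-9) / R)
                assert probs[k - 1][decision] == pytest.approx(
                    p_hat, abs=band), (w, k, decision)

    def test_invalid_stage_and_decision_rejected(self, ps3, eff3, design4):
        with pytest.raises(ValueError):
            es.stagewise_probability(ps3, eff3, list(design4.stage_n),
                                     design4.boundaries, 0, 1, "halt")
        with pytest.raises(ValueError):
            es.stagewise_probability(ps3, eff3, list(design4.stage_n),
                                     design4.boundaries, 0, 5, "efficacy")


class TestErrorSpending:
    def test_all_spend_at_final_stage(self):
        b = es.error_spending_boundaries(_one_pop(), [0.0, 0.025])
        assert np.isinf(b.upper[0])
        assert b.upper[1] == pytest.approx(norm.ppf(0.975), abs=1e-4)

    def test_all_spend_at_stage_one_matches_single_stage(self, ps2,
                                                         c_alpha_2pop):
        b = es.error_spending_boundaries(ps2, [0.025, 0.0])
        assert b.upper[0] == pytest.approx(c_alpha_2pop, abs=1e-5)

    def test_split_schedule_matches_closed_form_oracle(self):
        # stage-1 bound spends 0.005; stage-2 bound brings the total to
        # 0.025 given the stage-1 bound — bivariate normal closed form.
        a1, a2 = 0.005, 0.020
        c1 = norm.ppf(1 - a1)
        cov = np.array([[1.0, math.sqrt(0.5)], [math.sqrt(0.5), 1.0]])
        mvn = multivariate_normal(mean=[0, 0], cov=cov)

        def excess(c2):
            return (norm.cdf(c1) - mvn.cdf([c1, c2])) - a2

        c2_oracle = brentq(excess, 1.5, 3.0, xtol=1e-10)
        b = es.error_spending_boundaries(_one_pop(), [a1, a2])
        assert b.upper[0] == pytest.approx(c1, abs=1e-4)
        assert b.upper[1] == pytest.approx(c2_oracle, abs=1e-4)

    def test_negative_spend_rejected(self):
        with pytest.raises(ValueError):
            es.error_spending_boundaries(_one_pop(), [-0.01, 0.035])


class TestStagewiseSampleSize:
    def test_single_stage_degenerate_consistency(self, ps3, eff3, design2):
        spec = es.DesignSpec(ps3, stages=1,
                             power_definition="select-target-and-reject",
                             target=0)
        d = es.required_stagewise_sample_size(spec, eff3)
        assert d.stage_n == (design2.n_full,)
        assert d.boundaries.upper[0] == pytest.approx(design2.critical_value,
                                                      abs=1e-6)

    def test_achieved_power_brackets_goal(self, ps3, eff3, design4):
        assert design4.achieved_power >= 0.8
        from enrichsel.multistage import _powered_probability
        spec = design4.spec
        K = spec.stages
        below = _powered_probability(spec, eff3,
                                     [design4.stage_n[0] - 3] * K,
                                     design4.boundaries)
        assert below < 0.8


class TestEnrichment:
    def test_subgroup_path_concentrates_patients(self, ps2):
        sched = es.enrichment_information_update(ps2, 0, [276.0, 276.0],
                                                 sigma=0.72)
        s1 = sched[0]
        assert s1.cumulative_totals[-1] == pytest.approx(414.0)
        assert s1.cumulative_totals[-1] / 552.0 == pytest.approx(0.75)

    def test_full_population_path_stays_proportional(self, ps2):
        sched = es.enrichment_information_update(ps2, 1, [276.0, 276.0],
                                                 sigma=0.72)
        assert sched[0].cumulative_totals[-1] == pytest.approx(276.0)

    def test_accumulated_information_identity(self, ps2):
        sched = es.enrichment_information_update(ps2, 0, [276.0, 276.0],
                                                 sigma=0.72)[0]
        assert sched.information(2) == pytest.approx(
            math.sqrt(414.0) / (2 * 0.72), rel=1e-12)
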