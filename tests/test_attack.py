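"""Unit tests for the likelihood-ratio membership attack."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import beaconrisk as br
from beaconrisk.riskmodel import BetaParams


def loglik_brute(x, p_no):
    """Independent per-term oracle for the response log-likelihood."""
    total = 0.0
    for xi in x:
        total += xi * math.log(1 - p_no) + (1 - xi) * math.log(p_no)
    return total


class TestLRTStatistics:
    @given(
        n=st.integers(1, 50),
        dn=st.floats(0.05, 0.5),
        ratio=st.floats(0.05, 1.0),
        delta=st.floats(0.01, 0.5),
        data=st.data(),
    )
    @settings(max_examples=200)
    def test_linear_form_equals_term_by_term_difference(
        self, n, dn, ratio, delta, data
    ):
        # construct a valid configuration: delta * D_{N-1} <= D_N
        dn1 = dn * ratio / delta
        if dn1 >= 1.0:
            dn1 = 0.999
        x = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        s = br.lrt_statistics(x, dn, dn1, delta)
        oracle = loglik_brute(x, dn) - loglik_brute(x, delta * dn1)
        assert s.lam == pytest.approx(oracle, rel=1e-9, abs=1e-9)
        assert s.linear_form == pytest.approx(s.lam, rel=1e-9, abs=1e-9)

    def test_all_yes_closed_form(self):
        x = np.ones(20, dtype=int)
        s = br.lrt_statistics(x, 0.2, 0.25, 0.1)
        assert s.lam == pytest.approx(20 * np.log((1 - 0.2) / (1 - 0.1 * 0.25)))

    def test_degenerate_equal_likelihoods(self):
        # D_N = delta * D_{N-1} (exactly representable): hypotheses identical
        for x in (np.ones(10, int), np.zeros(10, int), np.array([1, 0, 1, 1])):
            s = br.lrt_statistics(x, 0.125, 0.25, 0.5)
            assert s.B == 0.0 and s.C == 0.0 and s.lam == 0.0

    def test_no_answer_impossible_under_exact_model_when_delta_zero(self):
        s = br.lrt_statistics(np.array([1, 0, 1]), 0.1, 0.2, 0.0)
        assert s.h1_impossible
        assert s.L_H1 == -np.inf and s.lam == np.inf
        # all-yes stays finite
        s2 = br.lrt_statistics(np.ones(5, int), 0.1, 0.2, 0.0)
        assert not s2.h1_impossible and np.isfinite(s2.lam)

    def test_sign_of_c(self):
        s = br.lrt_statistics(np.array([1, 0]), 0.2, 0.25, 0.1)
        assert s.C < 0  # strict when delta*D_{N-1} < D_N

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            br.lrt_statistics(np.array([1]), 0.1, 0.9, 0.5)  # delta*D_{N-1} > D_N


class TestQuerySelection:
    def test_reference_target_is_inconclusive(self):
        panel = br.SNPPanel(freqs=np.full(10, 0.4), chrom=np.full(10, "1"),
                            pos=np.arange(10))
        plan = br.select_query_positions(np.zeros(10, dtype=np.int8), panel, 5, seed=0)
        assert plan.inconclusive and plan.n == 0

    def test_budget_truncation_and_shortfall(self):
        panel = br.SNPPanel(freqs=np.full(10, 0.4), chrom=np.full(10, "1"),
                            pos=np.arange(10))
        row = np.zeros(10, dtype=np.int8)
        row[[2, 5, 7]] = 1
        full = br.select_query_positions(row, panel, 8, seed=1)
        assert set(full.indices) == {2, 5, 7} and full.shortfall == 5
        part = br.select_query_positions(row, panel, 2, seed=1)
        assert part.n == 2 and part.shortfall == 0
        assert set(part.indices) <= {2, 5, 7}

    def test_mean_alt_site_count_matches_closed_form(self):
        panel = br.sample_neutral_frequencies(20_000, 2_000, seed=2)
        gm = br.sample_genotypes(panel, 200, seed=3)
        counts = (gm.entries > 0).sum(axis=1)
        p = 1 - (1 - panel.freqs) ** 2
        expected = p.sum()
        se = np.sqrt(np.sum(p * (1 - p)) / gm.num_individuals)
        assert abs(counts.mean() - expected) <= 3 * se


class TestResponses:
    def test_empty_query_list(self, small_sim):
        _, _, db = small_sim
        assert br.collect_responses(db, []).n == 0

    def test_member_with_no_error_gets_all_yes(self, small_sim):
        panel, gm, db = small_sim
        row = gm.entries[0]  # a beacon member
        plan = br.select_query_positions(row, panel, 500, seed=4)
        r = br.collect_responses(db, plan.as_queries(panel))
        assert r.n == 500 and r.sum_x == 500

    def test_out_of_beacon_yes_rate_matches_model(self, small_sim):
        panel, gm, db = small_sim
        profile = br.profile_from_panel(panel, db.N, delta=0.0)
        presence = db.presence_vector(panel)
        rates = []
        for j in range(200, 260):  # non-members
            plan = br.select_query_positions(gm.entries[j], panel, 10_000, seed=j)
            rates.append(presence[plan.indices].mean())
        se = np.sqrt(profile.D_N / (len(rates) * 2000))  # conservative
        assert np.mean(rates) == pytest.approx(1 - profile.D_N, abs=3 * max(se, 5e-4))


class TestDecision:
    def test_boundary_is_strict(self):
        profile = br.compute_threshold(498, BetaParams(0.1131, 0.8574))
        n = profile.n
        t = profile.threshold_at(n)
        at = br.LRTStatistics(n=n, sum_x=t, r_e=t / n, L_H0=0, L_H1=0,
                              B=0, C=0, lam=0)
        above = br.LRTStatistics(n=n, sum_x=t + 1, r_e=(t + 1) / n, L_H0=0,
                                 L_H1=0, B=0, C=0, lam=0)
        assert not br.decide_membership(at, profile)
        assert br.decide_membership(above, profile)

    def test_inconclusive_target_not_rejected(self):
        profile = br.compute_threshold(498, BetaParams(0.1131, 0.8574))
        empty = br.LRTStatistics(n=0, sum_x=0, r_e=float("nan"), L_H0=0,
                                 L_H1=0, B=0, C=0, lam=0)
        assert not br.decide_membership(empty, profile)

    def test_all_yes_rejected_above_crossover(self):
        profile = br.compute_threshold(498, BetaParams(0.1131, 0.8574))
        crossover = profile.z**2 * (1 - profile.D_N) / profile.D_N
        n_hi = int(np.ceil(crossover * 1.05))
        n_lo = max(1, int(np.floor(crossover * 0.95)))
        assert profile.threshold_at(n_hi) < n_hi  # all-yes rejects
        assert profile.threshold_at(n_lo) >= n_lo  # all-yes cannot reject


class TestPowerAnalytic:
    def test_null_equals_alternative_gives_alpha(self):
        panel = br.sample_neutral_frequencies(20_000, 500, seed=5)
        profile = br.profile_from_panel(panel, N=20, delta=1e-3, n=2_000)
        null_profile = dataclasses.replace(profile, theta1=profile.theta0)
        power = br.power_analytic(null_profile, 2_000)
        step = stats.binom.pmf(null_profile.threshold_at(2_000), 2_000,
                               null_profile.theta0)
        assert abs(power - 0.05) <= step + 0.005

    def test_step_function_at_crossover_when_delta_zero(self):
        profile = br.compute_threshold(498, BetaParams(0.1131, 0.8574), delta=0.0)
        assert profile.theta1 == 1.0
        crossover = profile.z**2 * (1 - profile.D_N) / profile.D_N
        assert br.power_analytic(profile, int(crossover * 0.9)) == 0.0
        assert br.power_analytic(profile, int(crossover * 1.1)) == 1.0

    def test_matches_monte_carlo_binomial(self):
        panel = br.sample_neutral_frequencies(20_000, 500, seed=6)
        profile = br.profile_from_panel(panel, N=20, delta=0.2, n=500)
        analytic = br.power_analytic(profile, 500)
        rng = np.random.default_rng(7)
        draws = rng.binomial(500, profile.theta1, size=100_000)
        mc = (draws > profile.threshold_at(500)).mean()
        se = np.sqrt(max(analytic * (1 - analytic), 1e-8) / 100_000)
        assert abs(mc - analytic) <= 3 * se + 1e-4


class TestCohort:
    def test_zero_budget_rejects_nothing(self, small_sim):
        panel, gm, db = small_sim
        (o,) = br.run_attack_cohort(
            db, panel, gm, np.arange(20), np.arange(200, 220), [0], seed=8
        )
        assert o.power == 0.0 and o.type1_error == 0.0

    def test_overlapping_cohorts_rejected(self, small_sim):
        panel, gm, db = small_sim
        with pytest.raises(ValueError):
            br.run_attack_cohort(db, panel, gm, [0, 1], [1, 2], [10])

    def test_seeded_runs_are_identical(self, small_sim):
        panel, gm, db = small_sim
        kw = dict(budgets=[100, 1000], delta=1e-3, seed=9)
        a = br.run_attack_cohort(db, panel, gm, np.arange(10),
                                 np.arange(200, 210), **kw)
        b = br.run_attack_cohort(db, panel, gm, np.arange(10),
                                 np.arange(200, 210), **kw)
        for oa, ob in zip(a, b):
            assert np.array_equal(oa.case_sums, ob.case_sums)
            assert np.array_equal(oa.control_sums, ob.control_sums)
            assert oa.power == ob.power and oa.type1_error == ob.type1_error

    def test_shortfall_targets_still_evaluated(self, small_sim):
        panel, gm, db = small_sim
        (o,) = br.run_attack_cohort(
            db, panel, gm, np.arange(5), np.arange(200, 205), [10_000_000], seed=10
        )
        assert (o.case_ns < 10_000_000).all()
        assert (o.case_ns > 0).all()
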