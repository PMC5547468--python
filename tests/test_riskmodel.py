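"""Unit tests for the closed-form risk analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import betaln

import beaconrisk as br
from beaconrisk.riskmodel import BetaParams

# published risk table: (label, N, a', b', D_N, t'_alpha)
RISK_TABLE = [
    ("1kG-phase1", 1092, 0.0735, 1.0096, 0.0005594974767507827, 1826),
    ("1kG-affymetrix", 1074, 0.6483, 1.2876, 1.5352703647724165e-05, 99084),
    ("GoNL", 498, 0.1131, 0.8574, 0.0009412979457329326, 1005),
    ("SSMP", 100, 0.1848, 0.8500, 0.00403048895537907, 234),
    ("simulation", 2000, 0.1178793, 1.1188360, 0.00022374264418961542, 4900),
]


class TestComputeDN:
    @pytest.mark.parametrize("label,N,ap,bp,dn,_t", RISK_TABLE)
    def test_reference_values(self, label, N, ap, bp, dn, _t):
        assert br.compute_DN(N, BetaParams(ap, bp)) == pytest.approx(dn, rel=1e-6)

    def test_uniform_limit_is_exact(self):
        # a' = b' = 0, i.e. (a, b) = (1, 1): Gamma(2)/Gamma(1) = 1
        for N in (1, 10, 500):
            assert br.compute_DN(N, BetaParams(0.0, 0.0)) == pytest.approx(
                1.0 / (2 * N + 2), rel=1e-12
            )

    def test_matches_exact_beta_expectation(self):
        params = BetaParams(0.1848, 0.85)
        a, b = params.a, params.b
        N = 1000
        oracle = np.exp(betaln(a, b + 2 * N) - betaln(a, b))
        assert br.compute_DN(N, params) == pytest.approx(oracle, rel=0.01)
        assert br.exact_DN(N, params) == pytest.approx(oracle, rel=1e-12)

    @given(
        ap=st.floats(0.05, 0.7),
        bp=st.floats(0.8, 1.3),
        n=st.integers(1, 5000),
    )
    @settings(max_examples=100)
    def test_strictly_decreasing_in_n(self, ap, bp, n):
        params = BetaParams(ap, bp)
        assert br.compute_DN(n + 1, params) < br.compute_DN(n, params)

    def test_n_zero_convention(self):
        assert br.compute_DN(0, BetaParams(0.1, 1.0)) == 1.0


class TestExpectedQueries:
    def test_unit_exponent(self):
        assert br.expected_queries(777, BetaParams(0.0, 1.0)) == 777.0

    def test_simulation_scale(self):
        n = br.expected_queries(2000, BetaParams(0.1178793, 1.118836))
        assert n == pytest.approx(2000 ** 1.1178793, rel=1e-12)
        assert n == pytest.approx(4899.6, abs=0.2)

    def test_affymetrix_scale(self):
        assert br.expected_queries(1074, BetaParams(0.6483, 1.2876)) == pytest.approx(
            9.9e4, rel=0.01
        )


class TestFitBeta:
    def test_mle_recovers_beta_sample(self):
        rng = np.random.default_rng(100)
        sample = rng.beta(0.1179, 1.1188, size=1_000_000)
        params = br.fit_beta(sample, method="mle")
        assert params.a_prime == pytest.approx(0.1179, abs=0.01)
        assert params.b_prime == pytest.approx(1.1188, abs=0.01)

    def test_uniform_sample_fits_unit_shapes(self):
        rng = np.random.default_rng(101)
        params = br.fit_beta(rng.random(1_000_000), method="mle")
        assert params.a_prime == pytest.approx(1.0, abs=0.05)
        assert params.b_prime == pytest.approx(1.0, abs=0.05)

    def test_moment_fit_of_neutral_panel_matches_published_simulation_row(self):
        panel = br.sample_neutral_frequencies(100_000, 20_000, seed=102)
        params = br.fit_beta(panel, method="moments")
        assert params.a_prime == pytest.approx(0.1178793, abs=0.05)
        assert params.b_prime == pytest.approx(1.1188360, abs=0.05)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            br.fit_beta(np.full(100, 0.25))
        with pytest.raises(ValueError):
            br.fit_beta(np.array([0.0, 0.5]))


class TestThreshold:
    @pytest.mark.parametrize("label,N,ap,bp,_d,t", RISK_TABLE)
    def test_reference_thresholds_within_one_count(self, label, N, ap, bp, _d, t):
        # the published table mixes rounding conventions at the +-1 level;
        # the floor convention reproduces four rows exactly
        profile = br.compute_threshold(N, BetaParams(ap, bp), delta=1e-3, alpha=0.05)
        assert abs(profile.t_alpha_prime - t) <= 1

    def test_alpha_half_threshold_is_mean_count(self):
        params = BetaParams(0.1131, 0.8574)
        profile = br.compute_threshold(498, params, delta=1e-3, alpha=0.5)
        assert profile.z == 0.0
        assert profile.t_alpha_prime == int(np.floor(profile.n * profile.theta0))

    def test_exact_quantile_mode(self):
        params = BetaParams(0.1131, 0.8574)
        p = br.compute_threshold(498, params, alpha=0.05, paper_z=False)
        assert p.z == pytest.approx(stats.norm.isf(0.05), rel=1e-12)

    def test_null_quantile_close_to_threshold(self):
        # empirical 95th percentile of Binomial(n, theta0) for the GoNL
        # profile lies within one sigma0*n of t'_alpha
        profile = br.compute_threshold(498, BetaParams(0.1131, 0.8574))
        rng = np.random.default_rng(103)
        draws = rng.binomial(profile.n, profile.theta0, size=100_000)
        q95 = np.percentile(draws, 95)
        assert abs(q95 - profile.t_alpha_prime) <= profile.sigma0 * profile.n

    def test_threshold_monotone_in_budget(self):
        profile = br.compute_threshold(498, BetaParams(0.1131, 0.8574))
        ts = [profile.threshold_at(n) for n in range(1, 3000, 13)]
        assert all(b >= a for a, b in zip(ts, ts[1:]))

    def test_single_member_uses_d0(self):
        profile = br.compute_threshold(1, BetaParams(0.1, 1.0))
        assert profile.D_N1 == 1.0
        assert profile.d0_flagged

    def test_rejection_rate_matches_binomial_tail_in_clt_regime(self):
        # where n*D_N is large the normal-approximation threshold holds its
        # nominal level up to binomial discreteness
        profile = br.profile_from_panel(
            br.sample_neutral_frequencies(20_000, 500, seed=104), N=20,
            delta=1e-3, alpha=0.05, n=2_000,
        )
        exact = stats.binom.sf(profile.threshold_at(2_000), 2_000, profile.theta0)
        step = stats.binom.pmf(profile.threshold_at(2_000), 2_000, profile.theta0)
        assert abs(exact - 0.05) <= step + 0.005
        rng = np.random.default_rng(105)
        draws = rng.binomial(2_000, profile.theta0, size=100_000)
        mc = (draws > profile.threshold_at(2_000)).mean()
        assert abs(mc - exact) <= 3 * np.sqrt(exact * (1 - exact) / 100_000)


class TestSpectrumDN:
    def test_matches_direct_average(self):
        rng = np.random.default_rng(106)
        f = rng.beta(0.2, 1.2, size=1_000)
        f = f[(f > 0) & (f < 1)]
        w = 1 - (1 - f) ** 2
        direct = np.sum(w * (1 - f) ** 40) / np.sum(w)
        assert br.spectrum_DN(f, 20) == pytest.approx(direct, rel=1e-12)

    def test_decreasing_in_n(self):
        panel = br.sample_neutral_frequencies(10_000, 1_000, seed=107)
        ds = [br.spectrum_DN(panel, n) for n in (1, 5, 20, 100, 500)]
        assert all(b < a for a, b in zip(ds, ds[1:]))


class TestRiskReport:
    def test_reproduces_published_table(self):
        rows = [(l, N, ap, bp) for l, N, ap, bp, _d, _t in RISK_TABLE]
        df = br.risk_report(rows, delta=1e-3, alpha=0.05)
        for (_l, _N, _ap, _bp, dn, t), rec in zip(RISK_TABLE, df.itertuples()):
            assert rec.D_N == pytest.approx(dn, rel=1e-6)
            assert abs(rec.t_alpha_prime - t) <= 1

    def test_empty_rows_give_empty_table(self):
        df = br.risk_report([])
        assert len(df) == 0
        assert list(df.columns) == [
            "label", "N", "a_prime", "b_prime", "D_N", "n", "t_alpha_prime",
        ]

    def test_report_is_deterministic(self, tmp_path):
        rows = [("x", 498, 0.1131, 0.8574)]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        br.risk_report(rows, path=p1)
        br.risk_report(rows, path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_row_errors_carry_labels(self):
        with pytest.raises(ValueError, match="badrow"):
            br.risk_report([("badrow", 0, 0.1, 1.0)])
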