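"""Heterogeneity statistics, subgroup contrasts, PSA and tornado sensitivity."""

import numpy as np
import pytest

from krtecon import cba, heterogeneity as het


class TestCochranQ:
    def test_identical_values_zero(self):
        q, df = het.cochran_q([3.0, 3.0, 3.0], [1.0, 2.0, 0.5])
        assert q == pytest.approx(0.0)
        assert df == 2

    def test_two_country_hand_computation(self):
        # equal unit weights, BE (2, 4): weighted mean 3, Q = 1+1 = 2
        q, df = het.cochran_q([2.0, 4.0], [1.0, 1.0])
        assert q == pytest.approx(2.0)
        assert df == 1

    def test_q_scales_linearly_with_weight_scale(self):
        be = [1.5, 2.5, 4.0, 3.2]
        w = np.array([1.0, 2.0, 0.5, 1.5])
        q1, _ = het.cochran_q(be, w)
        q2, _ = het.cochran_q(be, 10 * w)
        assert q2 == pytest.approx(10 * q1)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            het.cochran_q([1.0, 2.0], [1.0, 0.0])


class TestISquared:
    def test_boundary_q_equals_df(self):
        assert het.i_squared(13.0, 13) == 0.0

    def test_printed_heterogeneity_value(self):
        raw = het.i_squared(27_956.4, 13)
        assert raw == pytest.approx(99.9535, abs=1e-3)
        assert round(raw) == 100

    def test_clamped_below_df(self):
        assert het.i_squared(5.0, 13) == 0.0
        assert het.i_squared(0.0, 13) == 0.0

    def test_range(self):
        for q in (0.1, 1.0, 50.0, 1e6):
            assert 0.0 <= het.i_squared(q, 5) <= 100.0


class TestTauSquared:
    def test_homogeneous_sample_degenerate_interval(self):
        tau2, (lo, hi), clamped = het.tau_squared_and_prediction_interval(
            [3.0] * 5, [100.0] * 5
        )
        assert tau2 == 0.0 and clamped
        # interval only reflects the (tiny) within-country variance
        assert hi - lo == pytest.approx(2 * 1.96 * np.sqrt(1 / 100.0))

    def test_interval_symmetric_about_mu(self):
        rng = np.random.default_rng(1)
        be = rng.uniform(1, 6, size=10)
        w = rng.uniform(0.5, 2.0, size=10)
        tau2, (lo, hi), _ = het.tau_squared_and_prediction_interval(be, w, mu=3.0)
        assert (3.0 - lo) == pytest.approx(hi - 3.0)

    def test_recovers_known_between_country_variance(self):
        # N=200 countries, true between-country variance 1.5, small and known
        # within-country variance: the moment estimator recovers the truth to
        # within 10% (averaged over seeded replicates; a single panel's
        # sample variance has ~10% sampling error itself at this size)
        n, tau2_true, v_within = 200, 1.5, 0.04
        estimates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            truth = rng.normal(3.5, np.sqrt(tau2_true), size=n)
            observed = truth + rng.normal(0, np.sqrt(v_within), size=n)
            weights = np.full(n, 1.0 / v_within)
            tau2, _, clamped = het.tau_squared_and_prediction_interval(
                observed, weights
            )
            assert not clamped
            estimates.append(tau2)
        assert np.mean(estimates) == pytest.approx(tau2_true, rel=0.10)


class TestSubgroupWelch:
    def test_worked_example_mean_difference(self):
        # groups constructed to have means 2.01 (n=6) and 4.28 (n=8)
        high = 2.01 + np.array([-0.5, -0.3, -0.1, 0.1, 0.3, 0.5])
        low = 4.28 + np.array([-0.7, -0.5, -0.3, -0.1, 0.1, 0.3, 0.5, 0.7])
        res = het.subgroup_welch(high, low)
        assert res.mean_high == pytest.approx(2.01)
        assert res.mean_low == pytest.approx(4.28)
        assert res.difference == pytest.approx(-2.27, abs=1e-12)
        assert res.n_high == 6 and res.n_low == 8

    def test_identical_groups_null_result(self):
        x = np.array([2.0, 3.0, 4.0])
        res = het.subgroup_welch(x, x)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_welch_df_bounded_by_pooled_df(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(0, rng.uniform(0.5, 3), size=rng.integers(3, 10))
            b = rng.normal(1, rng.uniform(0.5, 3), size=rng.integers(3, 10))
            res = het.subgroup_welch(a, b)
            assert res.welch_df <= len(a) + len(b) - 2 + 1e-9

    def test_detects_true_group_difference(self):
        # simulated groups matched to the subgroup-table dispersion: a true
        # 2.27-year gap is detected at alpha=0.01 in the large majority of
        # replicates (power check, scaled-down replicate count)
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            high = rng.normal(2.01, 0.56, size=6)  # SD from CI half-width
            low = rng.normal(4.28, 1.35, size=8)
            if het.subgroup_welch(high, low).p < 0.01:
                rejections += 1
        assert rejections / reps > 0.80

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            het.subgroup_welch([1.0], [2.0, 3.0])


class TestLDCorrelation:
    def test_perfect_antimonotone(self):
        ld = np.array([5.0, 10.0, 20.0, 30.0])
        be = 6.0 - 0.1 * ld
        r, p = het.ld_correlation(ld, be)
        assert r == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        ld = rng.uniform(5, 40, 12)
        be = rng.uniform(1, 6, 12)
        r1, _ = het.ld_correlation(ld, be)
        r2, _ = het.ld_correlation(3.0 * ld + 7.0, 0.5 * be - 1.0)
        assert r1 == pytest.approx(r2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            het.ld_correlation([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])


def _default_dists(cv=0.1):
    return het.PSADistributions(
        c_dialysis=het.CostDistribution(62_000.0, cv * 62_000.0),
        c_post_tx=het.CostDistribution(25_000.0, cv * 25_000.0),
        c_tx_initial=het.CostDistribution(117_000.0, cv * 117_000.0),
    )


class TestMonteCarloPSA:
    def test_degenerate_distributions_collapse_to_deterministic(self):
        dists = _default_dists(cv=0.0)
        res = het.monte_carlo_psa(dists, cba.CBAParams(), M=1000, seed=0)
        expected = cba.npv(62_000.0 - 25_000.0, cba.CBAParams(), 117_000.0)
        assert res.npv_mean == pytest.approx(expected)
        assert res.npv_ci[0] == pytest.approx(res.npv_ci[1])

    def test_probability_npv_positive_under_default_uncertainty(self):
        res = het.monte_carlo_psa(_default_dists(), cba.CBAParams(), M=10_000, seed=1)
        assert res.prob_npv_positive > 0.95

    def test_percentile_interval_covers_analytic_mean(self):
        # the central 95% interval of the NPV distribution contains the
        # deterministic NPV at the distribution means in >= 93/100 seeded runs
        dists = _default_dists()
        center = cba.npv(62_000.0 - 25_000.0, cba.CBAParams(), 117_000.0)
        covered = sum(
            1 for seed in range(100)
            if (lambda r: r.npv_ci[0] <= center <= r.npv_ci[1])(
                het.monte_carlo_psa(dists, cba.CBAParams(), M=1000, seed=seed)
            )
        )
        assert covered >= 93

    def test_seeded_reproducibility(self):
        r1 = het.monte_carlo_psa(_default_dists(), cba.CBAParams(), M=1000, seed=5)
        r2 = het.monte_carlo_psa(_default_dists(), cba.CBAParams(), M=1000, seed=5)
        assert r1.npv_mean == r2.npv_mean

    def test_normal_family_rejection_policy(self):
        # a normal dialysis-cost distribution straddling zero triggers the
        # resample-and-count policy instead of propagating negative costs
        dists = het.PSADistributions(
            c_dialysis=het.CostDistribution(5_000.0, 10_000.0, family="normal"),
            c_post_tx=het.CostDistribution(1_000.0, 10.0),
            c_tx_initial=het.CostDistribution(50_000.0, 100.0),
        )
        res = het.monte_carlo_psa(dists, cba.CBAParams(), M=1000, seed=2)
        assert res.n_rejected > 0
        assert np.all(res.be_draws > 0)

    def test_small_m_rejected(self):
        with pytest.raises(ValueError):
            het.monte_carlo_psa(_default_dists(), cba.CBAParams(), M=10)


class TestTornado:
    BASE = {"c_dialysis": 62_000.0, "c_post_tx": 25_000.0, "c_tx_initial": 117_000.0}

    def test_zero_discount_rate_raises_npv(self):
        df = het.tornado_analysis(self.BASE)
        row = df[df["parameter"] == "discount_rate 0%"].iloc[0]
        assert row["delta"] > 0

    def test_cheaper_dialysis_lowers_npv(self):
        df = het.tornado_analysis(self.BASE)
        row = df[df["parameter"] == "c_dialysis -20%"].iloc[0]
        assert row["delta"] < 0

    def test_irrelevant_parameter_zero_swing(self):
        df = het.tornado_analysis(
            self.BASE,
            perturbations=[("post-tx x1", {"c_post_tx": 1.0}, {}),
                           ("dialysis -20%", {"c_dialysis": 0.8}, {})],
        )
        assert df[df["parameter"] == "post-tx x1"].iloc[0]["delta"] == 0.0

    def test_rows_ordered_by_absolute_swing(self):
        df = het.tornado_analysis(self.BASE)
        swings = df["abs_swing"].to_numpy()
        assert np.all(np.diff(swings) <= 0)
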