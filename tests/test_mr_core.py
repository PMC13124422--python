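import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twostepmr import HarmonizedSet, egger, harmonize, ivw, to_odds_ratio, wald_ratio, weighted_median
from twostepmr.mr_core import DegenerateInstrumentError, InsufficientInstrumentsError, _weighted_median_point
from twostepmr.synthetic import SimConfig, simulate_two_sample

from conftest import random_harmonized


class TestWaldRatio:
    def test_exact_division(self):
        est = wald_ratio(0.5, 0.05, 0.25, 0.05, "first")
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome_effect(self):
        est = wald_ratio(1.0, 0.1, 0.0, 0.1, "first")
        assert est.beta == 0.0 and est.se == pytest.approx(0.1)

    def test_second_order_se_matches_simulation(self):
        rng = np.random.default_rng(7)
        g = rng.normal(0.2, 0.02, 1_000_000)
        G = rng.normal(0.1, 0.03, 1_000_000)
        mc_sd = np.std(G / g)
        est = wald_ratio(0.2, 0.02, 0.1, 0.03, "second")
        assert est.se == pytest.approx(mc_sd, rel=0.03)

    def test_zero_gamma_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.1, 0.1, 0.1)


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        h = HarmonizedSet("x", "y", ["rs1"], [0.5], [0.05], [0.25], [0.05])
        with pytest.warns(UserWarning):
            est = ivw(h)
        w = wald_ratio(0.5, 0.05, 0.25, 0.05, "first")
        assert est.beta == pytest.approx(w.beta) and est.se == pytest.approx(w.se)

    def test_exact_proportionality_toy(self, proportional_h):
        est = ivw(proportional_h, model="fixed")
        assert est.beta == pytest.approx(0.5)
        assert est.extras["cochran_q"] == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(5))
    def test_origin_regression_equals_weighted_mean_of_ratios(self, seed):
        h = random_harmonized(np.random.default_rng(seed))
        est = ivw(h, model="fixed")
        ratios = h.Gamma / h.gamma
        weights = h.gamma**2 / h.se_Gamma**2
        assert est.beta == pytest.approx(np.sum(weights * ratios) / np.sum(weights), abs=1e-12)

    def test_parameter_recovery_without_pleiotropy(self):
        # strong instruments, two independent samples of 50k
        cfg = dict(n_snps=8, gamma_sd=0.15, n_exposure=50_000, n_outcome=50_000, true_beta=0.4)
        ests = []
        for seed in range(500):
            e, o, _, _ = simulate_two_sample(SimConfig(**cfg, seed=seed))
            h, _ = harmonize(e, o)
            ests.append(ivw(h).beta)
        ests = np.array(ests)
        mcse = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.4) < 3 * mcse

    def test_ci_coverage_under_null_model(self):
        hits = 0
        n_rep = 1000
        for seed in range(n_rep):
            e, o, _, _ = simulate_two_sample(
                SimConfig(n_snps=8, gamma_sd=0.15, n_exposure=50_000, n_outcome=50_000,
                          true_beta=0.25, seed=10_000 + seed)
            )
            h, _ = harmonize(e, o)
            est = ivw(h, model="fixed")
            hits += est.ci_low <= 0.25 <= est.ci_high
        # binomial 99.7% band around 0.95 at n=1000
        band = 3 * np.sqrt(0.95 * 0.05 / n_rep)
        assert abs(hits / n_rep - 0.95) < band


class TestEgger:
    def test_exact_proportionality_gives_zero_intercept(self, proportional_h):
        est = egger(proportional_h)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.extras["egger_intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_weighted_least_squares_reference(self):
        sm = pytest.importorskip("statsmodels.api")
        h = random_harmonized(np.random.default_rng(3), n_snps=10)
        est = egger(h)
        X = sm.add_constant(h.gamma)
        fit = sm.WLS(h.Gamma, X, weights=1 / h.se_Gamma**2).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.extras["egger_intercept"] == pytest.approx(fit.params[0], abs=1e-10)
        assert est.se == pytest.approx(fit.bse[1], rel=1e-8)
        assert est.extras["egger_intercept_p"] == pytest.approx(fit.pvalues[0], rel=1e-6)

    def test_recovers_directional_pleiotropy(self):
        # the instrument screen first, as in the real pipeline: it removes
        # null-effect SNPs whose allele orientation would otherwise be
        # decided by sampling noise
        from twostepmr import select_instruments

        intercepts, slopes = [], []
        for seed in range(500):
            e, o, _, ld = simulate_two_sample(
                SimConfig(n_snps=12, gamma_sd=0.15, n_exposure=344_182, n_outcome=50_000,
                          true_beta=0.4, pleiotropy="directional",
                          pleiotropy_magnitude=0.05, seed=seed)
            )
            inst = select_instruments(e, p_threshold=1e-4, ld=ld)
            h, _ = harmonize(e.subset(inst.variant_ids), o)
            est = egger(h)
            intercepts.append(est.extras["egger_intercept"])
            slopes.append(est.beta)
        intercepts, slopes = np.array(intercepts), np.array(slopes)
        assert abs(intercepts.mean() - 0.05) < 3 * intercepts.std(ddof=1) / np.sqrt(500)
        assert abs(slopes.mean() - 0.4) < 3 * slopes.std(ddof=1) / np.sqrt(500)

    def test_intercept_type_i_error_calibrated(self):
        rejections = 0
        n_rep = 1000
        for seed in range(n_rep):
            e, o, _, _ = simulate_two_sample(
                SimConfig(n_snps=10, gamma_sd=0.15, n_exposure=50_000, n_outcome=50_000,
                          true_beta=0.3, seed=30_000 + seed)
            )
            h, _ = harmonize(e, o)
            rejections += egger(h).extras["egger_intercept_p"] < 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < band

    def test_too_few_instruments_rejected(self):
        h = HarmonizedSet("x", "y", ["a", "b"], [0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)


class TestWeightedMedian:
    def test_degenerate_equal_ratios(self):
        h = HarmonizedSet(
            "x", "y", ["a", "b", "c"],
            [0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.1, 0.2], [0.01, 0.02, 0.005],
        )
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_equal_weights_interpolation_matches_enumeration(self):
        # ratios 0.1..0.5 with equal weights 0.2: cumulative half-steps are
        # 0.1, 0.3, 0.5, 0.7, 0.9 -> s=0.5 falls exactly on the third ratio
        gamma = np.ones(5)
        Gamma = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        point = _weighted_median_point(gamma, Gamma, np.ones(5))
        assert point == pytest.approx(0.3)

    def test_robust_to_minority_invalid_instruments(self):
        # 40% of instruments carry large pleiotropy: the weighted median
        # should be less biased than IVW
        wm_est, ivw_est = [], []
        rng = np.random.default_rng(0)
        for rep in range(300):
            h = random_harmonized(rng, n_snps=10, beta=0.3)
            h.Gamma[:4] += 0.15  # invalid minority
            wm_est.append(weighted_median(h, n_boot=100, seed=rep).beta)
            ivw_est.append(ivw(h, model="fixed").beta)
        assert abs(np.mean(wm_est) - 0.3) < abs(np.mean(ivw_est) - 0.3)

    def test_bootstrap_is_seeded(self):
        h = random_harmonized(np.random.default_rng(8))
        a = weighted_median(h, n_boot=500, seed=99)
        b = weighted_median(h, n_boot=500, seed=99)
        assert a.beta == b.beta and a.se == b.se


class TestEstimatorProperties:
    @given(st.integers(0, 50), st.integers(0, 7))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_equivariance_under_joint_sign_flip(self, seed, flip_idx):
        h = random_harmonized(np.random.default_rng(seed))
        flipped = HarmonizedSet(
            "x", "y", h.variant_ids,
            h.gamma.copy(), h.se_gamma, h.Gamma.copy(), h.se_Gamma,
        )
        flipped.gamma[flip_idx] *= -1
        flipped.Gamma[flip_idx] *= -1
        assert ivw(flipped, "fixed").beta == pytest.approx(ivw(h, "fixed").beta, abs=1e-12)
        assert _weighted_median_point(
            flipped.gamma, flipped.Gamma, flipped.se_Gamma
        ) == pytest.approx(_weighted_median_point(h.gamma, h.Gamma, h.se_Gamma), abs=1e-12)

    def test_egger_equals_ivw_when_intercept_zero(self, proportional_h):
        assert egger(proportional_h).beta == pytest.approx(
            ivw(proportional_h, "fixed").beta, abs=1e-10
        )


class TestToOddsRatio:
    @pytest.mark.parametrize(
        "beta,expected_or",
        [(2.352, 10.51), (-2.754, 0.06), (0.0, 1.0)],
    )
    def test_published_and_null_conversions(self, beta, expected_or):
        from conftest import estimate_from_beta_p

        est = estimate_from_beta_p(beta if beta else 0.0, 0.5) if beta == 0 else estimate_from_beta_p(beta, 1e-5)
        o, lo, hi = to_odds_ratio(est)
        assert round(o, 2) == pytest.approx(expected_or)
        assert lo < o < hi
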