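"""Estimator correctness against brute-force oracles and exact small cases."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import assume, given
from scipy import stats

from tsmr import EstimatorError, egger, ivw, wald_ratio, weighted_median
from tsmr.estimators import _egger_fit, _weighted_median_point

from conftest import harmonized_datasets, make_dataset


def oracle_meta_analysis(data):
    """Fixed-effect inverse-variance meta-analysis of per-SNP Wald ratios,
    written as an explicit loop independent of the vectorized implementation."""
    num = den = 0.0
    for rec in data:
        est = rec.beta_outcome / rec.beta_exposure
        se = rec.se_outcome / abs(rec.beta_exposure)
        num += est / se**2
        den += 1.0 / se**2
    return num / den, den**-0.5


def oracle_weighted_median(ratios, weights):
    """Interpolated weighted median via the textbook cumulative-midpoint
    formula, coded with explicit indexing rather than np.interp."""
    order = sorted(range(len(ratios)), key=lambda i: ratios[i])
    r = [ratios[i] for i in order]
    total = sum(weights)
    w = [weights[i] / total for i in order]
    s, cum = [], 0.0
    for wi in w:
        s.append(cum + wi / 2.0)
        cum += wi
    if s[0] >= 0.5:
        return r[0]
    if s[-1] <= 0.5:
        return r[-1]
    for j in range(1, len(s)):
        if s[j] >= 0.5:
            frac = (0.5 - s[j - 1]) / (s[j] - s[j - 1])
            return r[j - 1] + frac * (r[j] - r[j - 1])
    raise AssertionError("unreachable")


class TestWaldRatio:
    def test_zero_outcome_gives_zero_estimate(self):
        data = make_dataset([0.05], [0.0])
        assert wald_ratio(data.records[0]).beta == 0.0

    def test_unit_exposure_is_identity_scaling(self):
        data = make_dataset([1.0], [0.23], sy=[0.05])
        est = wald_ratio(data.records[0])
        assert est.beta == 0.23 and est.se == 0.05 and est.n_snp == 1

    def test_published_lead_snp_ratio(self, vitd):
        rec = next(r for r in vitd if r.rsid == "rs3755967")
        est = wald_ratio(rec)
        assert est.beta == pytest.approx(0.032 / 0.089, abs=1e-12)
        assert est.se == pytest.approx(0.029 / 0.089, abs=1e-12)

    def test_zero_exposure_beta_names_snp(self):
        data = make_dataset([0.0], [0.01])
        with pytest.raises(EstimatorError, match="rs1"):
            wald_ratio(data.records[0])


class TestIvw:
    @given(harmonized_datasets())
    def test_matches_meta_analysis_oracle(self, data):
        beta, se = oracle_meta_analysis(data)
        est = ivw(data, mode="fixed")
        assert est.beta == pytest.approx(beta, rel=1e-10)
        assert est.se == pytest.approx(se, rel=1e-10)

    @given(harmonized_datasets())
    def test_point_estimate_identical_across_modes(self, data):
        assert ivw(data, "fixed").beta == ivw(data, "multiplicative_random").beta

    @given(harmonized_datasets())
    def test_mre_se_never_below_fixed_se(self, data):
        assert ivw(data, "multiplicative_random").se >= ivw(data, "fixed").se

    @given(harmonized_datasets())
    def test_permutation_and_joint_negation_invariance(self, data):
        est = ivw(data).beta
        rev = make_dataset(
            [r.beta_exposure for r in data][::-1],
            [r.beta_outcome for r in data][::-1],
            [r.se_exposure for r in data][::-1],
            [r.se_outcome for r in data][::-1],
        )
        assert ivw(rev).beta == pytest.approx(est, rel=1e-10)
        neg = make_dataset(
            [-r.beta_exposure for r in data],
            [-r.beta_outcome for r in data],
            [r.se_exposure for r in data],
            [r.se_outcome for r in data],
        )
        assert ivw(neg).beta == pytest.approx(est, rel=1e-10)

    def test_single_record_degrades_to_wald_ratio(self):
        data = make_dataset([0.05], [0.02])
        wald = wald_ratio(data.records[0])
        for mode in ("fixed", "multiplicative_random"):
            est = ivw(data, mode)
            assert est.beta == wald.beta and est.se == wald.se

    def test_empty_dataset_errors(self):
        with pytest.raises(EstimatorError, match="empty"):
            ivw(make_dataset([], []))

    def test_published_primary_estimate(self, vitd):
        est = ivw(vitd)
        assert est.or_point == pytest.approx(1.04, abs=0.05)
        assert est.ci_low == pytest.approx(0.58, abs=0.05)
        assert est.ci_high == pytest.approx(1.87, abs=0.06)


class TestWeightedMedian:
    def test_equal_ratios_returns_that_ratio(self):
        data = make_dataset([0.02, 0.05, 0.08], [0.02 * 1.7, 0.05 * 1.7, 0.08 * 1.7])
        est = weighted_median(data, n_boot=10, seed=0)
        assert est.beta == pytest.approx(1.7, rel=1e-10)

    def test_equal_weight_median_of_three(self):
        # ratios {1, 2, 9} with equal weights: cumulative midpoint of the
        # second ratio sits exactly at 0.5
        assert _weighted_median_point(
            np.array([1.0, 2.0, 9.0]), np.array([1.0, 1.0, 1.0])
        ) == pytest.approx(2.0)

    @given(harmonized_datasets())
    def test_matches_independent_interpolation_oracle(self, data):
        ratios = [r.beta_outcome / r.beta_exposure for r in data]
        weights = [r.beta_exposure**2 / r.se_outcome**2 for r in data]
        expected = oracle_weighted_median(ratios, weights)
        got = _weighted_median_point(np.array(ratios), np.array(weights))
        assert got == pytest.approx(expected, abs=1e-8)

    @given(harmonized_datasets())
    def test_estimate_within_ratio_range(self, data):
        est = weighted_median(data, n_boot=10, seed=0)
        ratios = [r.beta_outcome / r.beta_exposure for r in data]
        assert min(ratios) - 1e-12 <= est.beta <= max(ratios) + 1e-12

    def test_dominant_weight_pins_the_estimate(self):
        # one SNP with overwhelming precision carries >50% of the weight
        data = make_dataset(
            [0.1, 0.01, 0.01], [0.05, 0.03, -0.02], sy=[1e-4, 0.5, 0.5]
        )
        est = weighted_median(data, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.5, rel=1e-6)

    def test_bootstrap_se_deterministic_given_seed(self, vitd):
        a = weighted_median(vitd, n_boot=200, seed=7)
        b = weighted_median(vitd, n_boot=200, seed=7)
        c = weighted_median(vitd, n_boot=200, seed=8)
        assert a.se == b.se and a.beta == b.beta
        assert a.se != c.se

    def test_bootstrap_se_matches_replayed_oracle(self, vitd):
        """Replaying the same seeded draws through the loop-coded median
        oracle reproduces the bootstrap SE exactly."""
        n_boot, seed = 300, 11
        est = weighted_median(vitd, n_boot=n_boot, seed=seed)
        bx, sx, by, sy = vitd.arrays()
        k = len(bx)
        rng = np.random.default_rng(seed)
        bx_star = rng.normal(bx, sx, size=(n_boot, k))
        by_star = rng.normal(by, sy, size=(n_boot, k))
        reps = []
        for b in range(n_boot):
            ratios = list(by_star[b] / bx_star[b])
            weights = list(bx_star[b] ** 2 / sy**2)
            reps.append(oracle_weighted_median(ratios, weights))
        assert est.se == pytest.approx(float(np.std(reps, ddof=1)), abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(EstimatorError, match=">= 3"):
            weighted_median(make_dataset([0.1, 0.1], [0.1, 0.1]), seed=0)
        with pytest.raises(EstimatorError, match="n_boot"):
            weighted_median(
                make_dataset([0.1] * 3, [0.1] * 3), n_boot=1, seed=0
            )


class TestEgger:
    def test_noiseless_line_recovered_exactly(self):
        bx = np.array([0.02, 0.05, 0.08, 0.11])
        a, b = 0.013, 0.8
        data = make_dataset(bx, a + b * bx)
        slope, intercept = egger(data)
        assert slope.beta == pytest.approx(b, abs=1e-10)
        assert intercept.intercept == pytest.approx(a, abs=1e-10)

    @given(harmonized_datasets())
    def test_matches_statsmodels_wls(self, data):
        bx, _, by, sy = data.arrays()
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assume(fit.ssr > 1e-30)  # a perfect fit leaves both inferences undefined
        slope, intercept = egger(data)
        assert slope.beta == pytest.approx(fit.params[1], rel=1e-8)
        assert intercept.intercept == pytest.approx(fit.params[0], rel=1e-8, abs=1e-12)
        assert slope.se == pytest.approx(fit.bse[1], rel=1e-6)
        assert intercept.se == pytest.approx(fit.bse[0], rel=1e-6)
        assert slope.pvalue == pytest.approx(fit.pvalues[1], rel=1e-6, abs=1e-12)
        assert intercept.pvalue == pytest.approx(fit.pvalues[0], rel=1e-6, abs=1e-12)

    @given(harmonized_datasets())
    def test_zero_intercept_fit_reproduces_ivw(self, data):
        coef, _, _ = _egger_fit(data, with_intercept=False)
        assert coef[0] == pytest.approx(ivw(data, "fixed").beta, rel=1e-10)

    def test_published_intercept_test(self, vitd, calcium, pth):
        for data, expected in [(vitd, 0.243), (calcium, 0.997), (pth, 0.832)]:
            _, intercept = egger(data)
            assert intercept.pvalue == pytest.approx(expected, abs=0.03)

    def test_collinear_design_errors(self):
        data = make_dataset([0.05] * 4, [0.01, 0.02, 0.0, 0.03])
        with pytest.raises(EstimatorError, match="collinear"):
            egger(data)

    def test_too_few_instruments(self):
        with pytest.raises(EstimatorError, match=">= 3"):
            egger(make_dataset([0.1, 0.2], [0.1, 0.1]))


class TestCalibration:
    def test_ivw_unbiased_with_nominal_coverage_on_valid_instruments(self):
        """Monte-Carlo: valid instruments, no pleiotropy, true effect 0.25.
        The mean IVW estimate stays within 2 MC SEs of truth and the 95% CI
        covers it at close to nominal rate."""
        from tsmr import harmonize, simulate_pair, table1_like_config

        true_beta = 0.25
        cfg = table1_like_config("25OHD", true_beta=true_beta, seed=123)
        n_rep = 500
        est, covered = [], 0
        for i in range(n_rep):
            pair = simulate_pair(cfg, seed=i)
            data = harmonize(pair.exposure, pair.outcome)
            fit = ivw(data)
            est.append(fit.beta)
            lo = fit.beta - 1.959964 * fit.se
            hi = fit.beta + 1.959964 * fit.se
            covered += lo <= true_beta <= hi
        est = np.array(est)
        mc_se = est.std(ddof=1) / np.sqrt(n_rep)
        assert abs(est.mean() - true_beta) < 2 * mc_se
        assert 0.92 <= covered / n_rep <= 0.975
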