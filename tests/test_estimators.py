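import numpy as np
import pytest
import statsmodels.api as sm
from sklearn.base import clone

from mrkit.estimators import (
    wald_ratio, ivw, egger, weighted_median, weighted_mode,
    IVWEstimator, EggerEstimator, WeightedMedianEstimator,
    WeightedModeEstimator, _weighted_median, run_methods,
)
from mrkit.synth import harmonized_from_arrays


class TestWaldRatio:
    def test_basic(self):
        ratio, se = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert ratio == pytest.approx(0.5)
        assert se == pytest.approx(0.2)

    def test_zero_outcome(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.02)[0] == 0.0

    def test_negative_exposure_effect(self):
        ratio, se = wald_ratio(-0.1, 0.01, 0.2, 0.02)
        assert ratio == pytest.approx(-2.0)
        assert se == pytest.approx(0.2)

    def test_zero_exposure_errors(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIVW:
    def test_identical_ratios(self):
        h = harmonized_from_arrays([1.0, 1.0], [0.01, 0.01],
                                   [0.5, 0.5], [0.1, 0.2])
        r = ivw(h)
        assert r.beta == pytest.approx(0.5)
        assert r.or_ == pytest.approx(np.exp(0.5))

    def test_single_snp_reduces_to_wald_ratio(self):
        h = harmonized_from_arrays([0.1], [0.01], [0.05], [0.02])
        r = ivw(h)
        assert r.method == "WaldRatio"
        assert r.beta == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)

    def test_matches_wls_through_origin(self, rng):
        """Independent oracle: statsmodels WLS with no intercept."""
        for _ in range(10):
            n = int(rng.integers(3, 30))
            bx = rng.normal(0.1, 0.05, n)
            bx[np.abs(bx) < 1e-3] = 0.05
            by = rng.normal(0.05, 0.03, n)
            so = rng.uniform(0.01, 0.1, n)
            fit = sm.WLS(by, bx, weights=1 / so**2).fit()
            est = IVWEstimator().fit(bx, by, se_out=so)
            assert est.beta_ == pytest.approx(fit.params[0], rel=1e-10)
            # fixed-effect SE matches WLS with scale pinned to 1
            est_fixed = IVWEstimator(random_effects=False).fit(bx, by, se_out=so)
            se_closed = np.sqrt(1 / np.sum(bx**2 / so**2))
            assert est_fixed.se_ == pytest.approx(se_closed, rel=1e-10)

    def test_random_effects_never_shrinks_se(self, rng):
        bx = rng.normal(0.1, 0.05, 10)
        by = rng.normal(0.0, 0.1, 10)
        so = np.full(10, 0.01)
        fe = IVWEstimator(random_effects=False).fit(bx, by, se_out=so)
        re = IVWEstimator(random_effects=True).fit(bx, by, se_out=so)
        assert re.se_ >= fe.se_


class TestEgger:
    def test_exact_proportional_data(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        h = harmonized_from_arrays(bx, 0.01 * np.ones(4), 0.5 * bx,
                                   0.02 * np.ones(4))
        r = egger(h)
        assert r.beta == pytest.approx(0.5, abs=1e-10)
        assert r.intercept == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine_data(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        h = harmonized_from_arrays(bx, 0.01 * np.ones(4),
                                   0.02 + 0.5 * bx, 0.02 * np.ones(4))
        r = egger(h)
        assert r.beta == pytest.approx(0.5, abs=1e-10)
        assert r.intercept == pytest.approx(0.02, abs=1e-10)

    def test_matches_statsmodels_wls(self, rng):
        """Oracle: WLS with intercept on positively-oriented effects,
        with the multiplicative random-effects inflation applied by hand."""
        n = 12
        bx = rng.normal(0.1, 0.05, n)
        by = 0.03 + 0.4 * np.abs(bx) * np.sign(bx) + rng.normal(0, 0.01, n)
        so = rng.uniform(0.01, 0.05, n)
        sign = np.sign(bx)
        X = sm.add_constant(bx * sign)
        fit = sm.WLS(by * sign, X, weights=1 / so**2).fit()
        est = EggerEstimator().fit(bx, by, se_out=so)
        assert est.intercept_ == pytest.approx(fit.params[0], rel=1e-9)
        assert est.beta_ == pytest.approx(fit.params[1], rel=1e-9)
        infl = max(1.0, fit.scale) / fit.scale  # statsmodels scales by RSS/(n-2)
        assert est.se_ == pytest.approx(fit.bse[1] * np.sqrt(infl), rel=1e-9)

    def test_requires_three_instruments(self):
        h = harmonized_from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(ValueError, match="3 instruments"):
            egger(h)

    def test_recovers_directional_pleiotropy(self, rng):
        """Simulation oracle: mean intercept ≈ injected pleiotropy mean."""
        intercepts = []
        for s in range(300):
            r = np.random.default_rng(s)
            bx = r.normal(0.1, 0.03, 50) * r.choice([-1, 1], 50)
            alpha = r.normal(0.03, 0.01, 50) * np.sign(bx)
            so = np.full(50, 0.005)
            by = 0.1 * bx + alpha + r.normal(0, so)
            est = EggerEstimator().fit(bx, by, se_out=so)
            intercepts.append(est.intercept_)
        mc_se = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert abs(np.mean(intercepts) - 0.03) < 2 * mc_se + 1e-4


class TestWeightedMedian:
    def test_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = harmonized_from_arrays(bx, 0.01 * np.ones(3), bx, 0.02 * np.ones(3))
        assert weighted_median(h, seed=1).beta == pytest.approx(1.0)

    def test_equal_weight_interpolation(self):
        # ratios {0, 1, 2}, equal weights → cumulative {1/6, 3/6, 5/6} → 1
        assert _weighted_median(np.array([0.0, 1.0, 2.0]),
                                np.ones(3)) == pytest.approx(1.0)

    def test_interpolation_oracle(self, rng):
        """Brute-force re-derivation of the half-weight convention."""
        for _ in range(25):
            n = int(rng.integers(3, 15))
            ratios = rng.normal(0, 1, n)
            w = rng.uniform(0.1, 2, n)
            order = np.argsort(ratios)
            r_s, w_s = ratios[order], w[order]
            s = (np.cumsum(w_s) - 0.5 * w_s) / w_s.sum()
            if s[0] >= 0.5:
                expected = r_s[0]
            elif s[-1] <= 0.5:
                expected = r_s[-1]
            else:
                k = int(np.searchsorted(s, 0.5, side="right")) - 1
                frac = (0.5 - s[k]) / (s[k + 1] - s[k])
                expected = r_s[k] + frac * (r_s[k + 1] - r_s[k])
            assert _weighted_median(ratios, w) == pytest.approx(expected)

    def test_majority_valid_beats_contamination(self):
        # 60% of weight at ratio 0.1, 40% far away: median sits with majority
        bx = np.full(10, 0.1)
        so = np.full(10, 0.01)
        by = 0.1 * bx
        by[6:] = 0.5 * bx[6:]
        h = harmonized_from_arrays(bx, 0.01 * np.ones(10), by, so)
        assert weighted_median(h, seed=1).beta == pytest.approx(0.1, abs=0.01)


class TestWeightedMode:
    def test_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = harmonized_from_arrays(bx, 0.01 * np.ones(3), 0.7 * bx,
                                   0.02 * np.ones(3))
        assert weighted_mode(h, seed=1).beta == pytest.approx(0.7, abs=1e-6)

    def test_cluster_with_outliers(self):
        """Density-argmax oracle: the 7-SNP cluster at 0.5 wins over 2 at 3.0."""
        bx = np.full(9, 0.1)
        by = np.r_[np.full(7, 0.05), np.full(2, 0.30)]
        by = by + np.linspace(-0.002, 0.002, 9)  # break exact ties
        so = np.full(9, 0.01)
        est = WeightedModeEstimator(seed=3).fit(bx, by, se_out=so)
        assert abs(est.beta_ - 0.5) < max(est.bandwidth_, 0.05)

    def test_large_phi_limit_drifts_to_weighted_mean(self):
        bx = np.full(4, 0.1)
        by = np.array([0.02, 0.02, 0.06, 0.06])
        so = np.full(4, 0.01)
        tight = WeightedModeEstimator(phi=0.1, seed=0).fit(bx, by, se_out=so)
        wide = WeightedModeEstimator(phi=50.0, seed=0).fit(bx, by, se_out=so)
        mean_ratio = np.mean(by / bx)
        assert abs(wide.beta_ - mean_ratio) < abs(tight.beta_ - mean_ratio)


class TestCrossCutting:
    def test_sign_equivariance(self, rng):
        """Flipping the reported allele of single SNPs (negating both effects)
        leaves every estimator unchanged."""
        n = 8
        bx = rng.normal(0.1, 0.05, n)
        by = 0.3 * bx + rng.normal(0, 0.01, n)
        sx, so = np.full(n, 0.01), np.full(n, 0.02)
        flip = rng.choice([-1.0, 1.0], n)
        h1 = harmonized_from_arrays(bx, sx, by, so)
        h2 = harmonized_from_arrays(bx * flip, sx, by * flip, so)
        for fn in (ivw, egger):
            assert fn(h1).beta == pytest.approx(fn(h2).beta, rel=1e-9)
        assert weighted_median(h1, seed=5).beta == pytest.approx(
            weighted_median(h2, seed=5).beta, rel=1e-9)
        assert weighted_mode(h1, seed=5).beta == pytest.approx(
            weighted_mode(h2, seed=5).beta, rel=1e-6)

    def test_bootstrap_se_reproducible(self, simple_harmonized):
        a = weighted_median(simple_harmonized, seed=42)
        b = weighted_median(simple_harmonized, seed=42)
        c = weighted_median(simple_harmonized, seed=43)
        assert a.se == b.se
        assert a.se != c.se

    def test_run_methods_returns_all_four(self, simple_harmonized):
        results = run_methods(simple_harmonized, seed=1)
        assert [r.method for r in results] == [
            "IVW", "Egger", "WeightedMedian", "WeightedMode"]
        for r in results:
            assert r.or_ == pytest.approx(np.exp(r.beta))
            assert 0 < r.pval <= 1
            assert r.ci_low < r.or_ < r.ci_high

    def test_sklearn_estimator_api(self):
        est = WeightedMedianEstimator(n_boot=50, seed=7)
        assert est.get_params()["n_boot"] == 50
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est2 = IVWEstimator().set_params(random_effects=False)
        assert est2.random_effects is False

    def test_convergence_to_truth_with_valid_instruments(self):
        """All estimators approach θ as instruments strengthen."""
        r = np.random.default_rng(99)
        n = 80
        bx = r.normal(0.15, 0.03, n) * r.choice([-1, 1], n)
        sx = np.full(n, 0.002)
        so = np.full(n, 0.002)
        by = 0.1 * bx + r.normal(0, so)
        h = harmonized_from_arrays(bx + r.normal(0, sx), sx, by, so)
        for fn, kw in [(ivw, {}), (egger, {}),
                       (weighted_median, {"seed": 1}),
                       (weighted_mode, {"seed": 1})]:
            assert fn(h, **kw).beta == pytest.approx(0.1, abs=0.02)
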