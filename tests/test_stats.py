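import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soapct.stats import (aic_select, ancova_slopes, anova_tukey,
                          fit_through_origin, reproducibility_correlation)


class TestFitThroughOrigin:
    def test_exact_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_through_origin(x, 2.0 * x, 1)
        assert fit.coefficients == pytest.approx((2.0,))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.model == "linear_origin"

    def test_exact_quadratic(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = fit_through_origin(x, 3.0 * x**2, 2)
        assert fit.coefficients == pytest.approx((0.0, 3.0), abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_no_intercept_in_prediction(self):
        x = np.array([1.0, 2.0, 3.0])
        fit = fit_through_origin(x, 2.0 * x + 1.0, 1)  # data has an offset
        assert fit.predict(0.0) == 0.0  # the curve still passes the origin

    def test_coefficient_recovery_under_noise(self):
        """y = 0.4x + noise (5% of range, n=8): the slope is recovered
        within 10% in at least 95 of 100 seeded replicates."""
        x = np.linspace(1.0, 10.0, 8)
        ok = 0
        for s in range(100):
            rng = np.random.default_rng(900 + s)
            y = 0.4 * x + rng.normal(0, 0.05 * np.ptp(0.4 * x), x.size)
            fit = fit_through_origin(x, y, 1)
            ok += abs(fit.coefficients[0] - 0.4) / 0.4 < 0.10
        assert ok >= 95

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_through_origin([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], 1)
        with pytest.raises(ValueError):
            fit_through_origin([1.0], [1.0], 1)
        with pytest.raises(ValueError):
            fit_through_origin([1, 2, 3], [1, 2, 3], 3)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), degree=st.sampled_from([1, 2]))
    def test_normal_equations_satisfied(self, seed, degree):
        """Residuals are orthogonal to every basis column (to 1e-8
        relative), i.e. the normal equations hold."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.5, 10.0, 12)
        y = rng.normal(0.0, 5.0, 12) + x
        fit = fit_through_origin(x, y, degree)
        resid = y - fit.predict(x)
        scale = float(np.abs(y).sum()) + 1.0
        for p in range(1, degree + 1):
            assert abs(np.dot(resid, x**p)) / (scale * np.abs(x**p).sum()) < 1e-8


class TestAicSelect:
    def test_equal_rss_prefers_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = 2.0 * x  # both models fit exactly: penalty decides
        sel = aic_select(fit_through_origin(x, y, 1), fit_through_origin(x, y, 2))
        assert sel["preferred"] == "linear_origin"

    def test_different_n_rejected(self):
        f1 = fit_through_origin([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1)
        f2 = fit_through_origin([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], 2)
        with pytest.raises(ValueError):
            aic_select(f1, f2)

    def test_linear_law_recovered(self):
        """AICc keeps the linear model in >= 90% of 200 seeded replicates
        of a pure linear law with 5% noise at n=8."""
        from soapct.validation import aic_recovery_rates
        rates = aic_recovery_rates(seed=123, n_replicates=200)
        assert rates["linear_recovery_rate"] >= 0.90

    def test_quadratic_law_recovered(self):
        """AICc picks the quadratic for a convex quadratic law in >= 90%
        of replicates (the deforming-bullet scenario)."""
        from soapct.validation import aic_recovery_rates
        rates = aic_recovery_rates(seed=123, n_replicates=200)
        assert rates["quadratic_recovery_rate"] >= 0.90


class TestAncovaSlopes:
    def test_distinct_slopes_detected(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 10, 12)
        g1 = (x, 1.0 * x + rng.normal(0, 0.1, 12))
        g2 = (x, 3.0 * x + rng.normal(0, 0.1, 12))
        F, p = ancova_slopes([g1, g2])
        assert p < 1e-3

    def test_matches_statsmodels_interaction_test(self):
        import pandas as pd
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        rng = np.random.default_rng(5)
        x1, x2 = rng.normal(5, 2, 10), rng.normal(5, 2, 12)
        y1 = 1.0 + 2.0 * x1 + rng.normal(0, 1, 10)
        y2 = 0.5 + 2.8 * x2 + rng.normal(0, 1, 12)
        F, p = ancova_slopes([(x1, y1), (x2, y2)])
        df = pd.DataFrame({"x": np.r_[x1, x2], "y": np.r_[y1, y2],
                           "g": ["a"] * 10 + ["b"] * 12})
        full = smf.ols("y ~ C(g)*x", df).fit()
        red = smf.ols("y ~ C(g)+x", df).fit()
        tab = anova_lm(red, full)
        assert F == pytest.approx(float(tab["F"].iloc[1]), rel=1e-9)
        assert p == pytest.approx(float(tab["Pr(>F)"].iloc[1]), rel=1e-9)

    def test_preconditions(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ancova_slopes([(x, x)])  # single group
        with pytest.raises(ValueError):
            ancova_slopes([(x, x), (np.ones(3), np.arange(3.0))])  # constant x


class TestAnovaTukey:
    def test_identical_groups(self):
        F, p, _ = anova_tukey([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert F == 0.0
        assert p == 1.0

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        g1 = rng.normal(0, 1, 10)
        g2 = rng.normal(0, 1, 10)
        g3 = rng.normal(10, 1, 10)  # 10 sd away
        F, p, pairs = anova_tukey([g1, g2, g3])
        assert p < 1e-6
        lookup = {(int(r.group_a), int(r.group_b)): r.p_adj
                  for r in pairs.itertuples()}
        assert lookup[(0, 2)] < 1e-3 and lookup[(1, 2)] < 1e-3
        assert lookup[(0, 1)] > 0.5

    def test_adjusted_p_not_below_unadjusted(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 7) for m in (0.0, 0.4, 0.9, 1.5)]
        _, _, pairs = anova_tukey(groups)
        assert np.all(pairs["p_adj"].to_numpy() >=
                      pairs["p_unadj"].to_numpy() - 1e-12)

    def test_matches_statsmodels_tukey(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        rng = np.random.default_rng(5)
        g1, g2, g3 = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9), rng.normal(2, 1, 7)
        _, _, pairs = anova_tukey([g1, g2, g3])
        tk = pairwise_tukeyhsd(np.r_[g1, g2, g3], ["a"] * 8 + ["b"] * 9 + ["c"] * 7)
        np.testing.assert_allclose(pairs["p_adj"].to_numpy(), tk.pvalues, atol=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([[1.0, 2.0], []])


class TestTypeICalibration:
    def test_null_rejection_rates_near_alpha(self):
        """ANCOVA slope test and one-way ANOVA reject within 3 percentage
        points of the nominal alpha = 0.05 under 500 null replicates."""
        from soapct.validation import type1_error_rates
        rates = type1_error_rates(seed=77, n_replicates=500)
        assert abs(rates["ancova_type1_rate"] - 0.05) <= 0.03
        assert abs(rates["anova_type1_rate"] - 0.05) <= 0.03


class TestPermutationOracle:
    def test_anova_p_close_to_exhaustive_permutation(self):
        """On a fixed two-group micro-dataset (n=6 per group) the F-test
        p agrees with the exhaustive label-permutation p."""
        a = np.array([0.305, -1.04, 0.75, 0.941, -1.951, -1.302])
        b = np.array([1.128, 0.684, 0.983, 0.147, 1.879, 1.778])
        F0, p0, _ = anova_tukey([a, b])
        pool = np.r_[a, b]
        hits = total = 0
        for idx in itertools.combinations(range(12), 6):
            sel = np.zeros(12, bool)
            sel[list(idx)] = True
            Fp, _, _ = anova_tukey([pool[sel], pool[~sel]])
            hits += Fp >= F0 - 1e-12
            total += 1
        assert abs(p0 - hits / total) < 0.03


class TestReproducibility:
    def test_perfect_and_inverse(self):
        assert reproducibility_correlation([1, 2, 3], [1, 2, 3])["pearson_r"] == \
            pytest.approx(1.0)
        assert reproducibility_correlation([1, 2, 3], [3, 2, 1])["pearson_r"] == \
            pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            reproducibility_correlation([1, 1, 1], [1, 2, 3])

    def test_per_group_correlations(self):
        rng = np.random.default_rng(4)
        first = rng.uniform(50, 250, 16)
        second = first * np.exp(rng.normal(0, 0.05, 16))
        groups = np.repeat(["ILS", "TAG", "TSX", "NVU"], 4)
        out = reproducibility_correlation(first, second, groups=groups)
        assert out["pearson_r"] > 0.95
        assert set(out["per_group_r"]) == {"ILS", "TAG", "TSX", "NVU"}
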