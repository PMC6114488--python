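"""Factor encoding, OLS machinery and the nested partial-F test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rqtlscan.linear import (
    MISSING,
    ModelError,
    SkipVariant,
    covariate_adjust,
    encode_genotype_factor,
    fit_ols,
    nested_f_test,
)


def _gvec(counts):
    return np.repeat([0, 1, 2], counts)


class TestEncodeGenotypeFactor:
    @pytest.mark.parametrize(
        "counts, expected_codes, expected_n",
        [
            ((1500, 300, 19), (0, 1), 1800),  # minor homozygotes dropped -> 2-level factor
            ((1000, 500, 100), (0, 1, 2), 1600),
            ((20, 20, 20), (0, 1, 2), 60),  # boundary: count == 20 retained
        ],
    )
    def test_count_filter(self, counts, expected_codes, expected_n):
        f = encode_genotype_factor(_gvec(counts), min_count=20)
        assert f.retained_codes == expected_codes
        assert int(f.sample_mask.sum()) == expected_n
        assert all(f.counts[c] >= 20 for c in f.retained_codes)

    def test_single_surviving_class_is_skip(self):
        with pytest.raises(SkipVariant):
            encode_genotype_factor(_gvec((2000, 15, 5)), min_count=20)

    def test_monomorphic_is_skip(self):
        with pytest.raises(SkipVariant):
            encode_genotype_factor(np.zeros(100, dtype=int))

    def test_missing_calls_excluded(self):
        g = _gvec((50, 50, 50))
        g[:5] = MISSING
        f = encode_genotype_factor(g, min_count=20)
        assert int(f.sample_mask.sum()) == 145
        assert not f.sample_mask[:5].any()

    def test_reference_is_most_frequent(self):
        f = encode_genotype_factor(_gvec((30, 200, 40)), min_count=20)
        assert f.reference == 1


class TestFitOls:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_ols(2.0 * x, np.column_stack([np.ones(10), x]))
        assert fit.params[1] == pytest.approx(2.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_saturated_group_design_fits_group_means(self, rng):
        g = np.repeat([0, 1, 2], 20)
        y = rng.standard_normal(60)
        X = np.column_stack([(g == k).astype(float) for k in range(3)])
        fit = fit_ols(y, X)
        for k in range(3):
            assert fit.fitted[g == k][0] == pytest.approx(y[g == k].mean())

    def test_rss_matches_brute_force(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        fit = fit_ols(y, X)
        assert fit.rss == pytest.approx(float(np.sum((y - fit.fitted) ** 2)))
        assert fit.df_resid == 40 - 4

    def test_aliased_column_dropped_fitted_unchanged(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        X_alias = np.column_stack([X, X[:, 0] + X[:, 1]])
        plain = fit_ols(y, X)
        aliased = fit_ols(y, X_alias, colnames=["a", "b", "c", "a_plus_b"])
        assert aliased.rank == 3
        # one member of the dependent set is dropped (pivoting picks which)
        assert len(aliased.dropped) == 1 and aliased.dropped[0] in {"a", "b", "a_plus_b"}
        np.testing.assert_allclose(aliased.fitted, plain.fitted, atol=1e-10)

    def test_too_few_samples_raises(self, rng):
        with pytest.raises(ModelError):
            fit_ols(rng.standard_normal(3), rng.standard_normal((3, 3)))


class TestNestedFTest:
    def test_identical_models_degenerate(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = rng.standard_normal(20)
        fit = fit_ols(y, X)
        with pytest.raises(ModelError):
            nested_f_test(fit, fit)

    def test_hand_computed_one_way_ancova(self):
        # n=12, one 3-level factor + one covariate; F computed by explicit
        # RSS arithmetic, frozen below.
        y = np.array([1.2, 0.8, 1.5, 1.1, 2.3, 2.7, 2.1, 2.5, 3.9, 3.4, 3.6, 4.1])
        g = np.repeat([0, 1, 2], 4)
        x = np.array([0.1, -0.2, 0.3, 0.0, 0.2, -0.1, 0.1, 0.0, -0.3, 0.2, 0.1, -0.1])
        Xr = np.column_stack([np.ones(12), x])
        Xf = np.column_stack([Xr, (g == 1).astype(float), (g == 2).astype(float)])
        f, df1, df2, p = nested_f_test(fit_ols(y, Xf), fit_ols(y, Xr))
        # independent arithmetic oracle: explicit normal equations
        bf_full, *_ = np.linalg.lstsq(Xf, y, rcond=None)
        bf_red, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rss_f = np.sum((y - Xf @ bf_full) ** 2)
        rss_r = np.sum((y - Xr @ bf_red) ** 2)
        expected = ((rss_r - rss_f) / 2) / (rss_f / 8)
        assert (df1, df2) == (2, 8)
        assert f == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(float(stats.f.sf(expected, 2, 8)), rel=1e-12)

    def test_null_p_uniform(self, rng):
        # simulated null, n=200, df1=2: KS against U(0,1) over 2000 replicates
        pvals = np.empty(2000)
        for i in range(2000):
            y = rng.standard_normal(200)
            g = rng.binomial(2, 0.4, 200)
            Xr = np.ones((200, 1))
            Xf = np.column_stack([Xr, (g == 1).astype(float), (g == 2).astype(float)])
            _, _, _, pvals[i] = nested_f_test(fit_ols(y, Xf), fit_ols(y, Xr))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equivalence_with_normal_equations_oracle(self, seed):
        # random small instances: partial F agrees with a brute-force
        # implementation built directly from the normal equations
        rng = np.random.default_rng(seed)
        n = rng.integers(15, 50)
        p_r = rng.integers(1, 4)
        p_extra = rng.integers(1, 4)
        Xr = np.column_stack([np.ones(n), rng.standard_normal((n, p_r))])
        Xf = np.column_stack([Xr, rng.standard_normal((n, p_extra))])
        y = rng.standard_normal(n)
        f, df1, df2, _ = nested_f_test(fit_ols(y, Xf), fit_ols(y, Xr))

        def brute_rss(X):
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            return float(r @ r)

        rss_f, rss_r = brute_rss(Xf), brute_rss(Xr)
        expected = ((rss_r - rss_f) / p_extra) / (rss_f / (n - Xf.shape[1]))
        assert df1 == p_extra and df2 == n - Xf.shape[1]
        assert f == pytest.approx(expected, rel=1e-8)

    def test_orthogonal_column_never_increases_rss(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 2))])
        y = rng.standard_normal(50)
        base = fit_ols(y, X)
        extra = rng.standard_normal(50)
        bigger = fit_ols(y, np.column_stack([X, extra]))
        assert bigger.rss <= base.rss + 1e-12


class TestCovariateAdjust:
    def test_orthogonal_trait_returns_centered_trait(self, rng):
        c = rng.standard_normal(200)
        t = rng.standard_normal(200)
        # orthogonalize against the span of {1, c} jointly
        X = np.column_stack([np.ones(200), c])
        t_orth = t - X @ np.linalg.solve(X.T @ X, X.T @ t)
        resid = covariate_adjust(t_orth, c[:, None])
        np.testing.assert_allclose(resid, t_orth, atol=1e-10)

    def test_trait_equal_to_covariate_gives_zero(self, rng):
        c = rng.standard_normal(100)
        resid = covariate_adjust(c, c[:, None])
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_residual_mean_zero(self, rng):
        resid = covariate_adjust(rng.standard_normal(150), rng.standard_normal((150, 3)))
        assert abs(resid.mean()) < 1e-9
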