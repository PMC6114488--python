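"""rQTL interaction screen: df accounting, invariances, clustering, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rqtlscan import (
    BootstrapPolicy,
    RqtlInteractionModel,
    SyntheticDesign,
    count_unique_locations,
    per_genotype_correlation,
    rqtl_test,
    screen_genome,
    select_seed_snps,
    simulate_standardized_cohort,
)
from rqtlscan.simulate import cohort_covariate_matrix


def _null_data(rng, n=1000, maf=0.3, rho=-0.2):
    g = rng.binomial(2, maf, n)
    modifier = rng.standard_normal(n)
    y = rho * modifier + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return y, modifier, g


class TestDfAccounting:
    def test_three_genotype_model_has_2_df(self, rng):
        y, modifier, g = _null_data(rng, n=3000, maf=0.3)
        res = rqtl_test(y, modifier, g)
        assert res.df1 == 2
        assert len(res.retained_codes) == 3

    def test_two_genotype_model_has_1_df(self, rng):
        # at maf 0.05 and n=3000 the minor homozygote class (~7 expected)
        # falls below the count-20 filter
        y, modifier, g = _null_data(rng, n=3000, maf=0.05)
        res = rqtl_test(y, modifier, g)
        assert res.df1 == 1
        assert res.retained_codes == (0, 1)


class TestInvariances:
    def test_allele_flip_leaves_test_unchanged(self, rng):
        y, modifier, g = _null_data(rng, n=2000, maf=0.4)
        a = rqtl_test(y, modifier, g)
        b = rqtl_test(y, modifier, 2 - g)
        assert a.fvalue == pytest.approx(b.fvalue, rel=1e-9)
        assert (a.df1, a.df2) == (b.df1, b.df2)

    def test_strong_main_effect_stays_null_calibrated(self, rng):
        # a large marginal SNP effect must not inflate the interaction test
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            y, modifier, g = _null_data(rng, n=800)
            y = y + 0.8 * g  # main effect only
            rejections += rqtl_test(y, modifier, g).p_asymptotic < 0.05
        lo, hi = stats.binom.interval(0.99, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_constant_rho_design_rejects_at_nominal_rate(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            y, modifier, g = _null_data(rng, n=5000, rho=-0.3)
            rejections += rqtl_test(y, modifier, g).p_asymptotic < 0.05
        lo, hi = stats.binom.interval(0.99, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_robust_variant_agrees_under_homoskedasticity(self, rng):
        y, modifier, g = _null_data(rng, n=4000)
        plain = RqtlInteractionModel(y, modifier, g).fit()
        robust = RqtlInteractionModel(y, modifier, g).fit(robust=True)
        assert robust.df1 == plain.df1
        assert robust.fvalue == pytest.approx(plain.fvalue, rel=0.2)


class TestScreenGenome:
    def test_planted_variant_ranks_first(self, epistasis_cohort):
        cohort, gm = epistasis_cohort
        table = screen_genome(cohort, gm, response="tau", modifier="abeta42")
        assert table.iloc[0]["variant_id"] in {"snp0", "snp1"}

    def test_threshold_gates_bootstrap(self, null_cohort):
        cohort, gm = null_cohort
        table = screen_genome(
            cohort, gm, boot_policy=BootstrapPolicy(max_reps=100, seed=1), threshold=5e-8
        )
        assert (table["p_asymptotic"] > 5e-8).all()
        assert (table["n_boot"] == 0).all()

    def test_deterministic_output(self, null_cohort):
        cohort, gm = null_cohort
        t1 = screen_genome(cohort, gm, boot_policy=BootstrapPolicy(max_reps=100, seed=1))
        t2 = screen_genome(cohort, gm, boot_policy=BootstrapPolicy(max_reps=100, seed=1))
        pd.testing.assert_frame_equal(t1, t2)


class TestUniqueLocations:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "p_asymptotic", "variant_id"])

    def test_nearby_chr16_pair_is_one_location(self):
        hits = self._hits(
            [("16", 75_983_693, 1e-9, "a"), ("16", 75_999_881, 2e-9, "b")]
        )
        assert count_unique_locations(hits) == 1

    def test_empty_is_zero(self):
        assert count_unique_locations(self._hits([])) == 0

    def test_three_chromosomes_three_locations(self):
        hits = self._hits(
            [("1", 100, 1e-9, "a"), ("2", 100, 1e-9, "b"), ("3", 100, 1e-9, "c")]
        )
        assert count_unique_locations(hits) == 3

    def test_chain_collapses_by_single_linkage(self):
        hits = self._hits(
            [("1", 0, 1e-9, "a"), ("1", 900_000, 1e-9, "b"), ("1", 1_800_000, 1e-9, "c")]
        )
        assert count_unique_locations(hits, window=1_000_000) == 1

    def test_seed_selection_picks_most_significant(self):
        hits = self._hits(
            [("1", 100, 1e-9, "a"), ("1", 200, 1e-12, "b"), ("2", 100, 1e-10, "c")]
        )
        seeds = select_seed_snps(hits)
        assert set(seeds["variant_id"]) == {"b", "c"}


class TestPerGenotypeCorrelation:
    def test_identical_traits_give_unit_correlation(self, rng):
        t = rng.standard_normal(300)
        g = rng.binomial(2, 0.4, 300)
        cov = rng.standard_normal((300, 2))
        out = per_genotype_correlation(t, t.copy(), cov, g, n_boot_se=20)
        assert np.allclose(out["r"], 1.0)

    def test_independent_traits_near_zero(self, rng):
        t1 = rng.standard_normal(6000)
        t2 = rng.standard_normal(6000)
        g = rng.binomial(2, 0.4, 6000)
        cov = rng.standard_normal((6000, 2))
        out = per_genotype_correlation(t1, t2, cov, g, n_boot_se=200)
        assert (np.abs(out["r"]) < 3 * out["se"]).all()

    def test_small_class_flagged_undefined(self, rng):
        g = np.array([0] * 50 + [1] * 50 + [2] * 2)
        t1 = rng.standard_normal(102)
        t2 = rng.standard_normal(102)
        out = per_genotype_correlation(t1, t2, rng.standard_normal((102, 1)), g, n_boot_se=20)
        row = out[out["genotype"] == 2].iloc[0]
        assert not row["defined"] and np.isnan(row["r"])

    def test_heterogeneity_direction_matches_planted_pattern(self):
        # a significant differential-epistasis rQTL shows more extreme
        # within-genotype correlation in the homozygote classes, as planted
        from rqtlscan import plant_differential_epistasis

        d = plant_differential_epistasis(
            0.6, (0.3, 0.3), SyntheticDesign(n_samples=10_000, seed=31)
        )
        cohort, gm = simulate_standardized_cohort(d)
        cov, _ = cohort_covariate_matrix(cohort)
        res = RqtlInteractionModel.from_dataframe(cohort, gm.genotype("snp0")).fit()
        assert res.p_asymptotic < 1e-4
        pc = per_genotype_correlation(
            cohort["tau"], cohort["abeta42"], cov, gm.genotype("snp0"), n_boot_se=100
        ).set_index("genotype")
        assert pc.loc[0, "r"] < pc.loc[1, "r"] - 0.05
        assert pc.loc[2, "r"] < pc.loc[1, "r"] - 0.05


def test_summary_mentions_key_quantities(rng):
    y, modifier, g = _null_data(rng, n=2500)
    res = rqtl_test(y, modifier, g, variant_id="rs_test", trait_pair="tau/abeta42")
    res.bootstrap(BootstrapPolicy(max_reps=200, seed=0))
    text = res.summary()
    assert "rs_test" in text and "tau/abeta42" in text
    assert "p (empirical)" in text
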