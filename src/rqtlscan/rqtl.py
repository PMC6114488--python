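"""Relationship-QTL (rQTL) screening.

An rQTL is a locus at which the correlation between two quantitative traits
differs by genotype. The screen fits, per variant,

    response = u + covariates + modifier + SNP + modifier * SNP

with the SNP as a factor (classes with fewer than 20 carriers dropped), and
tests the modifier-by-genotype interaction block against the null model
without it: a partial F with numerator df equal to retained genotype classes
minus one (2 df for a three-genotype model, 1 df for two). In the CSF
biomarker application the response is tau or ptau and the modifier is Abeta42,
both on the standardized log10 scale.

`RqtlInteractionModel` / `RqtlResults` follow the statsmodels convention:
build the model from data, call ``fit()``, then ask the results object for
the empirical (bootstrap) p-value or the per-genotype adjusted-correlation
decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import BootstrapPolicy, BootstrapResult, parametric_bootstrap_p
from .linear import (
    MISSING,
    GenotypeFactor,
    LinearFit,
    ModelError,
    SkipVariant,
    _as_genotype_array,
    covariate_adjust,
    covariate_design,
    encode_genotype_factor,
    fit_ols,
    hc3_wald_test,
    nested_f_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RqtlInteractionModel",
    "RqtlResults",
    "rqtl_test",
    "screen_genome",
    "count_unique_locations",
    "select_seed_snps",
    "per_genotype_correlation",
    "GENOME_WIDE_THRESHOLD",
]

GENOME_WIDE_THRESHOLD = 5e-8


class RqtlInteractionModel:
    """Interaction model of one variant's effect on a trait-pair relationship.

    Parameters
    ----------
    response, modifier : array-like
        Standardized trait values; the modifier enters as a continuous
        covariate, never factorized.
    genotype : array-like of {0,1,2,-1}
        Integer calls for the focal variant (-1 or NaN missing).
    covariates : 2-D array-like or None
        Numeric covariate columns (no intercept; one is added).
    min_genotype_count : int
        Genotype classes below this count are dropped before modelling.
    """

    def __init__(
        self,
        response,
        modifier,
        genotype,
        covariates=None,
        *,
        min_genotype_count: int = 20,
        variant_id: str = "",
        trait_pair: str = "trait/modifier",
    ):
        response = np.asarray(response, dtype=float)
        modifier = np.asarray(modifier, dtype=float)
        g = _as_genotype_array(genotype)
        n = response.shape[0]
        if covariates is None:
            covariates = np.empty((n, 0))
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T

        complete = np.isfinite(response) & np.isfinite(modifier) & (g != MISSING)
        complete &= np.isfinite(covariates).all(axis=1)
        # the count filter applies to the analysis (complete-case) sample
        g_cc = np.where(complete, g, MISSING)
        self.factor: GenotypeFactor = encode_genotype_factor(
            g_cc, min_count=min_genotype_count, variant_id=variant_id
        )
        m = self.factor.sample_mask
        self.variant_id = variant_id
        self.trait_pair = trait_pair
        self.response = response[m]
        self.modifier = modifier[m]
        self.covariates = covariates[m]
        self.genotype_codes = g[m]

        gdum, gnames = self.factor.indicators(g)
        inter = self.modifier[:, None] * gdum
        base_names = (
            ["intercept"]
            + [f"cov{j}" for j in range(self.covariates.shape[1])]
            + ["modifier"]
        )
        self._x_reduced = np.column_stack(
            [np.ones(m.sum()), self.covariates, self.modifier, gdum]
        )
        self._reduced_names = base_names + gnames
        self._x_full = np.column_stack([self._x_reduced, inter])
        self._full_names = self._reduced_names + [f"modifier:{s}" for s in gnames]
        self._interaction_cols = np.arange(self._x_reduced.shape[1], self._x_full.shape[1])

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        genotype,
        *,
        response: str = "tau",
        modifier: str = "abeta42",
        covariates: list[str] | None = None,
        **kwargs,
    ) -> "RqtlInteractionModel":
        """Build from a cohort frame; categorical covariates expand to dummies."""
        from .io import DEFAULT_COVARIATES

        cov, _ = covariate_design(data, covariates if covariates is not None else DEFAULT_COVARIATES)
        kwargs.setdefault("trait_pair", f"{response}/{modifier}")
        return cls(
            data[response].to_numpy(float),
            data[modifier].to_numpy(float),
            genotype,
            cov,
            **kwargs,
        )

    def fit(self, robust: bool = False) -> "RqtlResults":
        """Fit full and null models and test the interaction block.

        ``robust=True`` swaps the plain partial F for an HC3 sandwich Wald F;
        the parametric bootstrap (via :meth:`RqtlResults.bootstrap`) remains
        the reference calibration for either statistic.
        """
        full = fit_ols(self.response, self._x_full, self._full_names)
        reduced = fit_ols(self.response, self._x_reduced, self._reduced_names)
        if robust:
            f, df1, df2, p = hc3_wald_test(self.response, self._x_full, self._interaction_cols)
        else:
            f, df1, df2, p = nested_f_test(full, reduced)
        return RqtlResults(
            model=self, full_fit=full, reduced_fit=reduced,
            fvalue=f, df1=df1, df2=df2, p_asymptotic=p, robust=robust,
        )


@dataclass
class RqtlResults:
    """Fitted rQTL interaction test for one variant."""

    model: RqtlInteractionModel
    full_fit: LinearFit
    reduced_fit: LinearFit
    fvalue: float
    df1: int
    df2: int
    p_asymptotic: float
    robust: bool = False
    boot: BootstrapResult | None = None

    @property
    def variant_id(self) -> str:
        return self.model.variant_id

    @property
    def retained_codes(self) -> tuple[int, ...]:
        return self.model.factor.retained_codes

    @property
    def nobs(self) -> int:
        return self.full_fit.nobs

    @property
    def p_empirical(self) -> float | None:
        return self.boot.p if self.boot is not None else None

    def bootstrap(
        self,
        policy: BootstrapPolicy,
        *,
        noise: str = "pooled",
        rng: np.random.Generator | None = None,
    ) -> BootstrapResult:
        """Parametric-bootstrap empirical p for the observed interaction F."""
        groups = self.model.genotype_codes if noise == "stratified" else None
        self.boot = parametric_bootstrap_p(
            self.fvalue, self.reduced_fit, self.model._x_full, self.model._x_reduced,
            policy, noise=noise, groups=groups, rng=rng,
        )
        return self.boot

    def per_genotype_correlation(
        self, n_boot_se: int = 1000, rng: np.random.Generator | None = None
    ) -> pd.DataFrame:
        """Covariate-adjusted trait correlation within each retained genotype."""
        return per_genotype_correlation(
            self.model.response, self.model.modifier, self.model.covariates,
            self.model.genotype_codes, retained=self.retained_codes,
            n_boot_se=n_boot_se, rng=rng,
        )

    def summary(self) -> str:
        lines = [
            "rQTL interaction test" + (" (HC3 robust)" if self.robust else ""),
            "=" * 46,
            f"variant:            {self.variant_id or '(unnamed)'}",
            f"trait pair:         {self.model.trait_pair}",
            f"n used:             {self.nobs}",
            f"genotype classes:   {list(self.retained_codes)} "
            f"(counts {[self.model.factor.counts[c] for c in self.retained_codes]})",
            f"F({self.df1}, {self.df2}) = {self.fvalue:.4f}",
            f"p (asymptotic):     {self.p_asymptotic:.4g}",
        ]
        if self.boot is not None:
            lines.append(
                f"p (empirical):      {self.boot.formatted()}  "
                f"[{self.boot.exceedances} exceedances / {self.boot.reps} replicates]"
            )
        return "\n".join(lines)


def rqtl_test(trait, modifier, genotype, covariates=None, **kwargs) -> RqtlResults:
    """Functional one-shot wrapper around :class:`RqtlInteractionModel`."""
    return RqtlInteractionModel(trait, modifier, genotype, covariates, **kwargs).fit()


def per_genotype_correlation(
    trait1,
    trait2,
    covariates,
    genotype,
    *,
    retained: tuple[int, ...] | None = None,
    n_boot_se: int = 1000,
    rng: np.random.Generator | None = None,
    min_class: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of covariate-adjusted traits within each genotype.

    SEs come from nonparametric resampling of samples within each class.
    Classes with fewer than ``min_class`` samples get NaN estimates and a
    ``defined = False`` flag.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    g = _as_genotype_array(genotype)
    r1 = covariate_adjust(np.asarray(trait1, float), covariates)
    r2 = covariate_adjust(np.asarray(trait2, float), covariates)
    codes = retained if retained is not None else tuple(sorted(set(g[g != MISSING])))
    rows = []
    for code in codes:
        m = g == code
        ncls = int(m.sum())
        if ncls < min_class:
            rows.append({"genotype": code, "n": ncls, "r": np.nan, "se": np.nan, "defined": False})
            continue
        a, b = r1[m], r2[m]
        r = float(np.corrcoef(a, b)[0, 1])
        idx = rng.integers(0, ncls, size=(n_boot_se, ncls))
        ab = a[idx]
        bb = b[idx]
        am = ab - ab.mean(axis=1, keepdims=True)
        bm = bb - bb.mean(axis=1, keepdims=True)
        denom = np.sqrt((am**2).sum(axis=1) * (bm**2).sum(axis=1))
        rstar = (am * bm).sum(axis=1) / denom
        rows.append(
            {"genotype": code, "n": ncls, "r": r, "se": float(np.std(rstar, ddof=1)), "defined": True}
        )
    return pd.DataFrame(rows)


def screen_genome(
    cohort: pd.DataFrame,
    gmatrix,
    *,
    response: str = "tau",
    modifier: str = "abeta42",
    covariates: list[str] | None = None,
    threshold: float = GENOME_WIDE_THRESHOLD,
    min_genotype_count: int = 20,
    boot_policy: BootstrapPolicy | None = None,
    boot_noise: str = "pooled",
) -> pd.DataFrame:
    """Test every variant of ``gmatrix`` for an rQTL on ``response``/``modifier``.

    The bootstrap runs only for variants whose asymptotic p reaches
    ``threshold`` (the two-stage scheme: a fixed genome-wide stage-1 cut,
    empirical p-values only where they matter). Per-variant bootstrap seeds
    derive deterministically from the policy seed and the variant index.
    Variants that cannot be tested are kept with a ``skip_reason``.
    """
    from .linear import covariate_design as _cd
    from .io import DEFAULT_COVARIATES

    cov, _ = _cd(cohort, covariates if covariates is not None else DEFAULT_COVARIATES)
    resp = cohort[response].to_numpy(float)
    mod = cohort[modifier].to_numpy(float)
    rows = []
    for j in range(gmatrix.n_variants):
        v = gmatrix.variants.iloc[j]
        row = {
            "variant_id": v["id"], "chrom": str(v["chrom"]), "pos": int(v["pos"]),
            "ref": v["ref"], "alt": v["alt"], "maf": float(v["maf"]),
            "trait_pair": f"{response}/{modifier}",
            "df1": np.nan, "df2": np.nan, "statistic": np.nan,
            "p_asymptotic": np.nan, "p_empirical": np.nan, "p_bound": np.nan,
            "n_boot": 0, "retained_classes": "", "n_used": 0, "skip_reason": "",
        }
        try:
            model = RqtlInteractionModel(
                resp, mod, gmatrix.calls[:, j].astype(int), cov,
                min_genotype_count=min_genotype_count,
                variant_id=str(v["id"]), trait_pair=f"{response}/{modifier}",
            )
            res = model.fit()
        except SkipVariant as exc:
            row["skip_reason"] = exc.reason
            rows.append(row)
            continue
        except ModelError as exc:
            row["skip_reason"] = f"model_error:{exc}"
            rows.append(row)
            continue
        row.update(
            df1=res.df1, df2=res.df2, statistic=res.fvalue,
            p_asymptotic=res.p_asymptotic,
            retained_classes="/".join(str(c) for c in res.retained_codes),
            n_used=res.nobs,
        )
        if boot_policy is not None and res.p_asymptotic <= threshold:
            rng = np.random.default_rng(np.random.SeedSequence(boot_policy.seed, spawn_key=(j,)))
            boot = res.bootstrap(boot_policy, noise=boot_noise, rng=rng)
            row.update(p_empirical=boot.p, n_boot=boot.reps)
            if boot.is_upper_bound:
                row["p_bound"] = boot.upper_bound
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["p_asymptotic", "variant_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def count_unique_locations(hits: pd.DataFrame, window: int = 1_000_000) -> int:
    """Number of single-linkage position clusters among hits (per chromosome).

    Two hits on the same chromosome within ``window`` base pairs belong to the
    same location; the count is the number of resulting clusters.
    """
    if len(hits) == 0:
        return 0
    count = 0
    for _, grp in hits.groupby(hits["chrom"].astype(str)):
        pos = np.sort(grp["pos"].to_numpy(int))
        count += 1 + int(np.sum(np.diff(pos) > window))
    return count


def select_seed_snps(hits: pd.DataFrame, window: int = 1_000_000) -> pd.DataFrame:
    """One representative hit per unique location: the most significant SNP."""
    if len(hits) == 0:
        return hits
    reps = []
    for _, grp in hits.groupby(hits["chrom"].astype(str)):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(int)
        cluster = np.concatenate([[0], np.cumsum(np.diff(pos) > window)])
        for c in np.unique(cluster):
            sub = grp.iloc[cluster == c]
            reps.append(sub.loc[sub["p_asymptotic"].idxmin()])
    return pd.DataFrame(reps).sort_values("p_asymptotic").reset_index(drop=True)
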