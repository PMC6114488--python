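"""rQTL-seeded gene-by-gene (G×G) interaction screening.

The two-locus test compares a cell-means full model — covariates plus one
free parameter per retained two-locus genotype cell —

    trait = u + covariates + TwoLocusGenotypes

against a reduced model with covariates plus separate single-locus factors

    trait = u + covariates + locusA + locusB.

The full model captures every one- and two-locus effect without explicitly
parameterizing the additive-by-additive / additive-by-dominance /
dominance-by-additive / dominance-by-dominance contrasts, which become
non-orthogonal (or inestimable) under unbalanced or missing cells. Cells with
fewer than five samples are excluded before fitting; with a complete 3x3
table the partial F has 4 numerator df, and in general
df1 = (cells - 1) - (levels_A - 1) - (levels_B - 1) on the masked sample.

Stage-2 multiple testing divides the genome-wide 5e-8 cut by the number of
independent significant rQTL seeding the screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import BootstrapPolicy, BootstrapResult, parametric_bootstrap_p
from .linear import (
    MISSING,
    LinearFit,
    ModelError,
    SkipVariant,
    _as_genotype_array,
    covariate_adjust,
    fit_ols,
    nested_f_test,
)
from .rqtl import GENOME_WIDE_THRESHOLD

__all__ = [
    "TwoLocusCells",
    "TwoLocusInteractionModel",
    "GxgResults",
    "build_two_locus_cells",
    "gxg_test",
    "gxg_threshold",
    "screen_partners",
    "adjusted_cell_means",
]


@dataclass(frozen=True)
class TwoLocusCells:
    """Retained two-locus genotype cells after the minimum-count filter."""

    cells: tuple[tuple[int, int], ...]
    counts: dict[tuple[int, int], int]
    dropped: tuple[tuple[int, int], ...]
    sample_mask: np.ndarray

    @property
    def levels_a(self) -> tuple[int, ...]:
        return tuple(sorted({a for a, _ in self.cells}))

    @property
    def levels_b(self) -> tuple[int, ...]:
        return tuple(sorted({b for _, b in self.cells}))

    @property
    def df1(self) -> int:
        return (len(self.cells) - 1) - (len(self.levels_a) - 1) - (len(self.levels_b) - 1)


def build_two_locus_cells(gvec_a, gvec_b, min_cell: int = 5) -> TwoLocusCells:
    """Cross-tabulate two genotype vectors and drop cells with count < ``min_cell``.

    Samples with a missing call at either locus, or falling in a dropped
    cell, are excluded via ``sample_mask``. Raises :class:`SkipVariant` when
    fewer than two levels of either locus survive.
    """
    a = _as_genotype_array(gvec_a)
    b = _as_genotype_array(gvec_b)
    if a.shape != b.shape:
        raise ModelError("genotype vectors are not aligned")
    ok = (a != MISSING) & (b != MISSING)
    pairs, counts = np.unique(np.column_stack([a[ok], b[ok]]), axis=0, return_counts=True)
    retained, dropped, cnt = [], [], {}
    for (ca, cb), n in zip(pairs, counts):
        cell = (int(ca), int(cb))
        if n >= min_cell:
            retained.append(cell)
            cnt[cell] = int(n)
        else:
            dropped.append(cell)
    cells = TwoLocusCells(
        cells=tuple(sorted(retained)),
        counts=cnt,
        dropped=tuple(sorted(dropped)),
        sample_mask=_cell_mask(a, b, retained),
    )
    if len(cells.levels_a) < 2 or len(cells.levels_b) < 2:
        raise SkipVariant("fewer_than_two_levels_after_cell_filter")
    return cells


def _cell_mask(a, b, retained) -> np.ndarray:
    mask = np.zeros(a.shape[0], dtype=bool)
    for ca, cb in retained:
        mask |= (a == ca) & (b == cb)
    return mask


class TwoLocusInteractionModel:
    """Cell-means vs additive-factors test of two-locus interaction on a trait.

    Single-locus factor levels for the reduced model are recomputed on the
    cell-masked sample, keeping full and reduced models nested on the same
    observations.
    """

    def __init__(
        self,
        trait,
        gvec_a,
        gvec_b,
        covariates=None,
        *,
        min_cell: int = 5,
        variant_a: str = "",
        variant_b: str = "",
        trait_label: str = "trait",
    ):
        trait = np.asarray(trait, dtype=float)
        a = _as_genotype_array(gvec_a)
        b = _as_genotype_array(gvec_b)
        n = trait.shape[0]
        if covariates is None:
            covariates = np.empty((n, 0))
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T

        complete = np.isfinite(trait) & np.isfinite(covariates).all(axis=1)
        a_cc = np.where(complete, a, MISSING)
        b_cc = np.where(complete, b, MISSING)
        self.cells = build_two_locus_cells(a_cc, b_cc, min_cell=min_cell)
        if self.cells.df1 < 1:
            raise SkipVariant("interaction_df_zero_after_cell_filter")
        m = self.cells.sample_mask
        self.variant_a, self.variant_b, self.trait_label = variant_a, variant_b, trait_label
        self.trait = trait[m]
        self.covariates = covariates[m]
        self.codes_a = a[m]
        self.codes_b = b[m]

        nm = int(m.sum())
        base = [np.ones(nm)] + [self.covariates[:, j] for j in range(self.covariates.shape[1])]
        base_names = ["intercept"] + [f"cov{j}" for j in range(self.covariates.shape[1])]
        # reduced: drop-first single-locus indicators on the masked sample
        red_cols, red_names = list(base), list(base_names)
        for lv in self.cells.levels_a[1:]:
            red_cols.append((self.codes_a == lv).astype(float))
            red_names.append(f"a{lv}")
        for lv in self.cells.levels_b[1:]:
            red_cols.append((self.codes_b == lv).astype(float))
            red_names.append(f"b{lv}")
        # full: cell indicators (drop the first cell; intercept absorbs it)
        full_cols, full_names = list(base), list(base_names)
        for ca, cb in self.cells.cells[1:]:
            full_cols.append(((self.codes_a == ca) & (self.codes_b == cb)).astype(float))
            full_names.append(f"cell{ca}{cb}")
        self._x_reduced = np.column_stack(red_cols)
        self._reduced_names = red_names
        self._x_full = np.column_stack(full_cols)
        self._full_names = full_names

    def fit(self) -> "GxgResults":
        full = fit_ols(self.trait, self._x_full, self._full_names)
        reduced = fit_ols(self.trait, self._x_reduced, self._reduced_names)
        f, df1, df2, p = nested_f_test(full, reduced)
        return GxgResults(
            model=self, full_fit=full, reduced_fit=reduced,
            fvalue=f, df1=df1, df2=df2, p_asymptotic=p,
        )


@dataclass
class GxgResults:
    """Fitted two-locus interaction test."""

    model: TwoLocusInteractionModel
    full_fit: LinearFit
    reduced_fit: LinearFit
    fvalue: float
    df1: int
    df2: int
    p_asymptotic: float
    boot: BootstrapResult | None = None

    @property
    def nobs(self) -> int:
        return self.full_fit.nobs

    @property
    def p_empirical(self) -> float | None:
        return self.boot.p if self.boot is not None else None

    def bootstrap(
        self, policy: BootstrapPolicy, *, noise: str = "pooled",
        rng: np.random.Generator | None = None,
    ) -> BootstrapResult:
        groups = None
        if noise == "stratified":
            groups = np.array([f"{a}-{b}" for a, b in zip(self.model.codes_a, self.model.codes_b)])
        self.boot = parametric_bootstrap_p(
            self.fvalue, self.reduced_fit, self.model._x_full, self.model._x_reduced,
            policy, noise=noise, groups=groups, rng=rng,
        )
        return self.boot

    def adjusted_cell_means(
        self, n_boot_se: int = 1000, rng: np.random.Generator | None = None
    ) -> pd.DataFrame:
        return adjusted_cell_means(
            self.model.trait, self.model.codes_a, self.model.codes_b,
            self.model.covariates, cells=self.model.cells.cells,
            n_boot_se=n_boot_se, rng=rng,
        )

    def summary(self) -> str:
        c = self.model.cells
        lines = [
            "two-locus (G×G) interaction test",
            "=" * 46,
            f"loci:               {self.model.variant_a or 'A'} x {self.model.variant_b or 'B'}",
            f"trait:              {self.model.trait_label}",
            f"n used:             {self.nobs}",
            f"retained cells:     {len(c.cells)} (dropped {len(c.dropped)})",
            f"F({self.df1}, {self.df2}) = {self.fvalue:.4f}",
            f"p (asymptotic):     {self.p_asymptotic:.4g}",
        ]
        if self.boot is not None:
            lines.append(f"p (empirical):      {self.boot.formatted()}")
        return "\n".join(lines)


def gxg_test(trait, gvec_a, gvec_b, covariates=None, **kwargs) -> GxgResults:
    """Functional one-shot wrapper around :class:`TwoLocusInteractionModel`."""
    return TwoLocusInteractionModel(trait, gvec_a, gvec_b, covariates, **kwargs).fit()


def gxg_threshold(n_unique_rqtl: int) -> float:
    """Stage-2 significance cut: 5e-8 divided by the number of independent rQTL."""
    if n_unique_rqtl < 1:
        raise ValueError("need at least one unique rQTL location")
    return GENOME_WIDE_THRESHOLD / n_unique_rqtl


def adjusted_cell_means(
    trait, gvec_a, gvec_b, covariates, *, cells=None,
    n_boot_se: int = 1000, rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean of covariate-adjusted trait residuals per two-locus cell, with
    nonparametric resampling SEs."""
    if rng is None:
        rng = np.random.default_rng(0)
    a = _as_genotype_array(gvec_a)
    b = _as_genotype_array(gvec_b)
    resid = covariate_adjust(np.asarray(trait, float), covariates)
    if cells is None:
        ok = (a != MISSING) & (b != MISSING)
        cells = sorted({(int(x), int(y)) for x, y in zip(a[ok], b[ok])})
    rows = []
    for ca, cb in cells:
        m = (a == ca) & (b == cb)
        vals = resid[m]
        ncell = vals.size
        boots = vals[rng.integers(0, ncell, size=(n_boot_se, ncell))].mean(axis=1)
        rows.append(
            {"code_a": ca, "code_b": cb, "n": ncell,
             "mean": float(vals.mean()), "se": float(np.std(boots, ddof=1))}
        )
    return pd.DataFrame(rows)


def screen_partners(
    cohort: pd.DataFrame,
    gmatrix,
    seed_variant_id: str,
    *,
    trait: str = "tau",
    covariates: list[str] | None = None,
    threshold: float = GENOME_WIDE_THRESHOLD,
    min_cell: int = 5,
    boot_policy: BootstrapPolicy | None = None,
    boot_noise: str = "pooled",
    flag_window: int = 1_000_000,
) -> pd.DataFrame:
    """Screen every other variant for two-locus interaction with one rQTL seed.

    Partners on the seed's chromosome within ``flag_window`` are tested but
    flagged (``near_seed``), since local linkage disequilibrium with the seed
    can mimic interaction. The bootstrap runs only for tests reaching
    ``threshold``.
    """
    from .linear import covariate_design as _cd
    from .io import DEFAULT_COVARIATES

    cov, _ = _cd(cohort, covariates if covariates is not None else DEFAULT_COVARIATES)
    y = cohort[trait].to_numpy(float)
    seed_idx = gmatrix.variants.index[gmatrix.variants["id"] == seed_variant_id]
    if len(seed_idx) == 0:
        raise KeyError(f"seed SNP {seed_variant_id!r} not in genotype matrix")
    seed_idx = int(seed_idx[0])
    seed_var = gmatrix.variants.iloc[seed_idx]
    g_seed = gmatrix.calls[:, seed_idx].astype(int)

    rows = []
    for j in range(gmatrix.n_variants):
        if j == seed_idx:
            continue
        v = gmatrix.variants.iloc[j]
        near = str(v["chrom"]) == str(seed_var["chrom"]) and abs(int(v["pos"]) - int(seed_var["pos"])) <= flag_window
        row = {
            "rqtl_id": seed_variant_id, "variant_id": v["id"], "chrom": str(v["chrom"]),
            "pos": int(v["pos"]), "ref": v["ref"], "alt": v["alt"], "maf": float(v["maf"]),
            "trait": trait, "df1": np.nan, "df2": np.nan, "statistic": np.nan,
            "p_asymptotic": np.nan, "p_empirical": np.nan, "p_bound": np.nan, "n_boot": 0,
            "retained_cells": 0, "n_used": 0, "near_seed": bool(near), "skip_reason": "",
        }
        try:
            res = gxg_test(
                y, g_seed, gmatrix.calls[:, j].astype(int), cov,
                min_cell=min_cell, variant_a=seed_variant_id,
                variant_b=str(v["id"]), trait_label=trait,
            )
        except SkipVariant as exc:
            row["skip_reason"] = exc.reason
            rows.append(row)
            continue
        except ModelError as exc:
            row["skip_reason"] = f"model_error:{exc}"
            rows.append(row)
            continue
        row.update(
            df1=res.df1, df2=res.df2, statistic=res.fvalue, p_asymptotic=res.p_asymptotic,
            retained_cells=len(res.model.cells.cells), n_used=res.nobs,
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
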