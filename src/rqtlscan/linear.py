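"""Core linear-model machinery.

Genotype-as-factor encoding with minimum-count filtering, QR-based ordinary
least squares with aliased-column handling, nested-model partial-F tests and
covariate adjustment. Everything downstream (the rQTL interaction screen, the
two-locus cell-means screen and the parametric bootstrap) is built on the
`LinearFit` objects produced here; `LinearFit` keeps the thin-QR factor of its
design so a bootstrap can recompute residual sums of squares with two matrix
products per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "ModelError",
    "SkipVariant",
    "GenotypeFactor",
    "LinearFit",
    "encode_genotype_factor",
    "fit_ols",
    "nested_f_test",
    "covariate_adjust",
    "covariate_design",
    "hc3_wald_test",
    "MISSING",
]

#: sentinel for a missing genotype call in integer-coded vectors
MISSING = -1


class ModelError(ValueError):
    """A model cannot be fit or a test is degenerate."""


class SkipVariant(Exception):
    """A variant cannot be tested; carries a machine-readable reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def _as_genotype_array(gvec) -> np.ndarray:
    g = np.asarray(gvec)
    if g.dtype.kind == "f":
        out = np.full(g.shape, MISSING, dtype=np.int64)
        ok = np.isfinite(g)
        out[ok] = np.rint(g[ok]).astype(np.int64)
        g = out
    else:
        g = g.astype(np.int64)
    bad = (g != MISSING) & ((g < 0) | (g > 2))
    if bad.any():
        raise ModelError(f"genotype codes outside {{0,1,2}} at index {int(np.flatnonzero(bad)[0])}")
    return g


@dataclass(frozen=True)
class GenotypeFactor:
    """Categorical encoding of one variant after the minimum-count class filter.

    ``sample_mask`` indexes the original vector: True for samples whose call is
    non-missing and belongs to a retained class. The reference level is the
    most frequent retained code; test statistics do not depend on this choice.
    """

    variant_id: str
    retained_codes: tuple[int, ...]
    counts: dict[int, int]
    sample_mask: np.ndarray
    reference: int

    @property
    def n_levels(self) -> int:
        return len(self.retained_codes)

    def codes(self, gvec) -> np.ndarray:
        """Masked genotype codes, aligned with ``sample_mask``."""
        return _as_genotype_array(gvec)[self.sample_mask]

    def indicators(self, gvec) -> tuple[np.ndarray, list[str]]:
        """Dummy columns for the non-reference retained codes on the masked sample."""
        g = self.codes(gvec)
        cols, names = [], []
        for code in self.retained_codes:
            if code == self.reference:
                continue
            cols.append((g == code).astype(float))
            names.append(f"g{code}")
        return np.column_stack(cols), names


def encode_genotype_factor(gvec, min_count: int = 20, variant_id: str = "") -> GenotypeFactor:
    """Encode a genotype vector as a factor, dropping classes with count < ``min_count``.

    Samples with missing calls or in under-count classes are excluded through
    ``sample_mask``. Raises :class:`SkipVariant` when fewer than two classes
    survive (the variant is effectively monomorphic in the analysis sample).
    """
    g = _as_genotype_array(gvec)
    observed = g[g != MISSING]
    if np.unique(observed).size < 2:
        raise SkipVariant("monomorphic")
    counts = {int(c): int(n) for c, n in zip(*np.unique(observed, return_counts=True))}
    retained = tuple(sorted(c for c, n in counts.items() if n >= min_count))
    if len(retained) < 2:
        raise SkipVariant("monomorphic_after_count_filter")
    mask = np.isin(g, retained)
    reference = max(retained, key=lambda c: counts[c])
    return GenotypeFactor(
        variant_id=variant_id,
        retained_codes=retained,
        counts={c: counts[c] for c in retained},
        sample_mask=mask,
        reference=reference,
    )


@dataclass
class LinearFit:
    """An OLS fit with rank bookkeeping.

    ``rank`` is the effective model column count after dropping exactly
    aliased columns; ``df_resid = n - rank``. ``q`` is the thin-QR factor of
    the rank-trimmed design, retained so bootstraps can recompute RSS cheaply.
    """

    params: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    df_resid: int
    rank: int
    colnames: list[str]
    dropped: list[str] = field(default_factory=list)
    q: np.ndarray | None = None

    @property
    def nobs(self) -> int:
        return self.fitted.shape[0]

    @property
    def sigma2(self) -> float:
        return self.rss / self.df_resid


def fit_ols(y, X, colnames: list[str] | None = None, rcond: float = 1e-10) -> LinearFit:
    """Least-squares fit via pivoted QR, dropping exactly aliased columns.

    Aliased (linearly dependent) columns are removed and recorded in
    ``dropped``; fitted values and RSS are unaffected by which of a dependent
    set is kept. Raises :class:`ModelError` when the sample is too small to
    leave residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if colnames is None:
        colnames = [f"x{j}" for j in range(p)]
    if len(colnames) != p:
        raise ModelError("colnames length does not match design width")
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ModelError("non-finite values in response or design")

    Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * rcond * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank == 0:
        raise ModelError("design has rank zero")
    if n <= rank:
        raise ModelError(f"n_used={n} does not exceed model rank={rank}")

    keep = np.sort(piv[:rank])
    dropped = [colnames[j] for j in np.sort(piv[rank:])]
    if rank < p:
        Qk, Rk = linalg.qr(X[:, keep], mode="economic")
    else:
        # pivoted QR already spans the full design; re-factor unpivoted for params
        Qk, Rk = linalg.qr(X, mode="economic")
        keep = np.arange(p)
    coef = linalg.solve_triangular(Rk, Qk.T @ y)
    params = np.full(p, np.nan)
    params[keep] = coef
    fitted = X[:, keep] @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    return LinearFit(
        params=params,
        fitted=fitted,
        residuals=resid,
        rss=rss,
        df_resid=n - rank,
        rank=rank,
        colnames=list(colnames),
        dropped=dropped,
        q=Qk,
    )


def nested_f_test(full: LinearFit, reduced: LinearFit) -> tuple[float, int, int, float]:
    """Partial F test of a full model against a nested reduced model.

    F = ((RSS_r - RSS_f) / df1) / (RSS_f / df2) with df1 the effective
    column-count difference and df2 the full model's residual df. Both fits
    must be on the same samples; the caller is responsible for nesting.
    """
    if full.nobs != reduced.nobs:
        raise ModelError("full and reduced fits use different sample sizes")
    df1 = full.rank - reduced.rank
    df2 = full.df_resid
    if df1 <= 0:
        raise ModelError("degenerate test: full model adds no effective columns")
    if full.rss <= 0.0:
        raise ModelError("degenerate test: saturated full model (RSS = 0)")
    num = max(reduced.rss - full.rss, 0.0) / df1
    f = num / (full.rss / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), int(df1), int(df2), p


def covariate_adjust(trait, covariates) -> np.ndarray:
    """Residuals of a trait regressed on an intercept plus covariates."""
    trait = np.asarray(trait, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != trait.shape[0]:
        C = C.T
    X = np.column_stack([np.ones_like(trait), C])
    return fit_ols(trait, X).residuals


def covariate_design(df: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, list[str]]:
    """Numeric covariate matrix (no intercept) from a cohort frame.

    Categorical/object columns (e.g. the study label) expand to drop-first
    dummies; numeric columns pass through.
    """
    blocks, names = [], []
    for col in columns:
        s = df[col]
        if s.dtype.kind in "OUS" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            blocks.append(dummies.to_numpy())
            names.extend(dummies.columns.tolist())
        else:
            blocks.append(s.to_numpy(dtype=float)[:, None])
            names.append(col)
    if not blocks:
        return np.empty((len(df), 0)), []
    return np.column_stack(blocks), names


def hc3_wald_test(y, X_full, test_cols: np.ndarray) -> tuple[float, int, int, float]:
    """Heteroskedasticity-robust (HC3 sandwich) Wald F test of a column block.

    Offered as the robust alternative to the plain partial F; the parametric
    bootstrap remains the reference calibration path.
    """
    import statsmodels.api as sm

    res = sm.OLS(np.asarray(y, float), np.asarray(X_full, float)).fit(cov_type="HC3")
    R = np.zeros((len(test_cols), X_full.shape[1]))
    for i, j in enumerate(test_cols):
        R[i, j] = 1.0
    ft = res.f_test(R)
    return float(ft.fvalue), int(ft.df_num), int(ft.df_denom), float(ft.pvalue)
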