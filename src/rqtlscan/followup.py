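"""Case/control follow-up models.

Two connections from biomarker-level rQTL to disease risk:

* :class:`LogisticRqtlModel` — the logistic analogue of the rQTL model:
  does a variant modify the relationship between case/control status and a
  biomarker? Full model: covariates + biomarker + genotype factor +
  biomarker×genotype; the interaction block is tested by likelihood ratio
  with df equal to retained genotype classes minus one.
* :func:`logistic_association` — a plain additive-coded logistic association
  of a variant with case/control status (Wald p on the dosage coefficient),
  the replication-style single-locus test.

Fitting is delegated to statsmodels' Logit; non-convergence and separation
are flagged rather than raised, and p-values are reported only for converged
fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linear import MISSING, GenotypeFactor, ModelError, SkipVariant, _as_genotype_array, encode_genotype_factor

__all__ = ["LogisticRqtlModel", "LogisticRqtlResults", "logistic_rqtl", "logistic_association"]


def _fit_logit(y, X):
    import statsmodels.api as sm

    with np.errstate(all="ignore"):
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return None, False
    converged = bool(getattr(res.mle_retvals, "get", lambda *_: True)("converged", True))
    if not np.isfinite(res.llf):
        converged = False
    return res, converged


@dataclass
class LogisticRqtlResults:
    """Likelihood-ratio test of the biomarker-by-genotype interaction on status."""

    variant_id: str
    biomarker: str
    df1: int
    lr_statistic: float | None
    p: float | None
    converged: bool
    retained_codes: tuple[int, ...]
    nobs: int

    def summary(self) -> str:
        lines = [
            "logistic rQTL (status ~ biomarker × genotype)",
            "=" * 46,
            f"variant:        {self.variant_id or '(unnamed)'}",
            f"biomarker:      {self.biomarker}",
            f"n used:         {self.nobs}",
            f"classes:        {list(self.retained_codes)}",
        ]
        if self.converged:
            lines += [f"LR({self.df1}) = {self.lr_statistic:.4f}", f"p = {self.p:.4g}"]
        else:
            lines.append("fit did not converge; no p-value reported")
        return "\n".join(lines)


class LogisticRqtlModel:
    """Logistic analogue of the rQTL interaction model."""

    def __init__(
        self,
        status,
        biomarker,
        genotype,
        covariates=None,
        *,
        min_genotype_count: int = 20,
        min_class: int = 20,
        variant_id: str = "",
        biomarker_label: str = "biomarker",
    ):
        status = np.asarray(status, dtype=float)
        biomarker = np.asarray(biomarker, dtype=float)
        g = _as_genotype_array(genotype)
        n = status.shape[0]
        if covariates is None:
            covariates = np.empty((n, 0))
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T

        complete = np.isfinite(status) & np.isfinite(biomarker) & (g != MISSING)
        complete &= np.isfinite(covariates).all(axis=1)
        g_cc = np.where(complete, g, MISSING)
        self.factor: GenotypeFactor = encode_genotype_factor(
            g_cc, min_count=min_genotype_count, variant_id=variant_id
        )
        m = self.factor.sample_mask
        y = status[m]
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ModelError("status must be binary 0/1")
        n_case, n_ctrl = int(y.sum()), int((1 - y).sum())
        if min(n_case, n_ctrl) < min_class:
            raise SkipVariant(f"status_class_below_{min_class}")

        self.variant_id = variant_id
        self.biomarker_label = biomarker_label
        self.status = y
        self.biomarker = biomarker[m]
        self.covariates = covariates[m]
        gdum, gnames = self.factor.indicators(g)
        inter = self.biomarker[:, None] * gdum
        self._x_reduced = np.column_stack([np.ones(m.sum()), self.covariates, self.biomarker, gdum])
        self._x_full = np.column_stack([self._x_reduced, inter])

    def fit(self) -> LogisticRqtlResults:
        full, ok_f = _fit_logit(self.status, self._x_full)
        red, ok_r = _fit_logit(self.status, self._x_reduced)
        df1 = self.factor.n_levels - 1
        if not (ok_f and ok_r):
            return LogisticRqtlResults(
                self.variant_id, self.biomarker_label, df1, None, None, False,
                self.factor.retained_codes, int(self.status.shape[0]),
            )
        lr = 2.0 * (full.llf - red.llf)
        lr = max(lr, 0.0)
        return LogisticRqtlResults(
            self.variant_id, self.biomarker_label, df1, float(lr),
            float(stats.chi2.sf(lr, df1)), True,
            self.factor.retained_codes, int(self.status.shape[0]),
        )


def logistic_rqtl(status, biomarker, genotype, covariates=None, **kwargs) -> LogisticRqtlResults:
    """One-shot wrapper around :class:`LogisticRqtlModel`."""
    return LogisticRqtlModel(status, biomarker, genotype, covariates, **kwargs).fit()


def logistic_association(status, genotype, covariates=None, *, min_class: int = 20):
    """Additive-coded logistic association of one variant with status.

    Returns a dict with the log-odds-ratio scale coefficient for the dosage
    term, its SE, the Wald p-value and a convergence flag.
    """
    status = np.asarray(status, dtype=float)
    g = _as_genotype_array(genotype)
    n = status.shape[0]
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    m = np.isfinite(status) & (g != MISSING) & np.isfinite(covariates).all(axis=1)
    y, gm, cv = status[m], g[m].astype(float), covariates[m]
    if np.unique(gm).size < 2:
        raise SkipVariant("monomorphic")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ModelError("status must be binary 0/1")
    if min(int(y.sum()), int((1 - y).sum())) < min_class:
        raise SkipVariant(f"status_class_below_{min_class}")
    X = np.column_stack([np.ones(m.sum()), cv, gm])
    res, ok = _fit_logit(y, X)
    if not ok:
        return {"coef": np.nan, "se": np.nan, "p": np.nan, "converged": False, "n": int(m.sum())}
    return {
        "coef": float(res.params[-1]),
        "se": float(res.bse[-1]),
        "p": float(res.pvalues[-1]),
        "converged": True,
        "n": int(m.sum()),
    }
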