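"""Synthetic multi-study cohort generator.

Emulates the structure the screens assume: Hardy-Weinberg genotypes at given
allele frequencies, a multi-study cohort with per-study intercept shifts on
log-scale biomarker traits, linear covariate effects, and a bivariate
(tau, abeta42) residual whose correlation can depend on the focal-SNP genotype
(a directly planted rQTL) or whose genotypic means follow a two-locus
interaction pattern differing between traits (differential epistasis, which
induces an rQTL mechanically).

Conventions
-----------
* The first two entries of ``mafs`` are the focal rQTL locus (A) and the
  partner locus (B); any further entries are independent null variants.
* Traits are generated on the standardized log10 scale and emitted as
  pg/mL-like levels ``10**(baseline + value)`` so a cohort round-trips through
  the standardization step of :mod:`rqtlscan.io`.
* One master seed; every stochastic component draws from a stream derived via
  ``numpy.random.SeedSequence(seed, spawn_key=...)`` so any single variant can
  be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as _io
from .io import GenotypeMatrix
from .linear import covariate_design

__all__ = [
    "InvalidDesignError",
    "SyntheticDesign",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_standardized_cohort",
    "plant_differential_epistasis",
]


class InvalidDesignError(ValueError):
    """A SyntheticDesign violates its invariants."""


def _zeros33() -> np.ndarray:
    return np.zeros((3, 3))


@dataclass
class SyntheticDesign:
    """Generative parameters for one synthetic cohort.

    Defaults mirror the scale of a nine-study CSF biomarker consortium:
    n = 3146 samples over 9 studies, log10-scale traits, no planted signal
    (zero mean matrices, genotype-independent residual correlation -0.2).

    mean_matrix_trait1/2 are 3x3 two-locus genotypic means indexed by
    (focal-locus code, partner-locus code) in standardized log10 trait units;
    rho_by_genotype maps the focal-locus code to the residual correlation
    between trait1 (tau) and trait2 (abeta42); noise_sd are residual SDs per
    trait in the same units (log10 CSF levels spread roughly 0.15-0.25 SD
    within a study, hence the 0.25 default).
    """

    n_samples: int = 3146
    n_studies: int = 9
    mafs: tuple[float, ...] = (0.3, 0.3)
    mean_matrix_trait1: np.ndarray = field(default_factory=_zeros33)
    mean_matrix_trait2: np.ndarray = field(default_factory=_zeros33)
    rho_by_genotype: dict[int, float] = field(
        default_factory=lambda: {0: -0.2, 1: -0.2, 2: -0.2}
    )
    covariate_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "age": (0.004, -0.003),
            "sex": (0.05, -0.02),
            "apoe_e2": (-0.02, 0.03),
            "apoe_e4": (0.05, -0.08),
            "pc1": (0.02, 0.02),
            "pc2": (-0.02, 0.02),
        }
    )
    noise_sd: tuple[float, float] = (0.25, 0.25)
    seed: int = 0
    # study-level and secondary-trait structure
    study_shift_sd: float = 0.1
    trait_baseline: tuple[float, float] = (2.0, 2.4)  # log10 pg/mL intercepts
    ptau_loading: float = 0.8
    ptau_noise_sd: float = 0.15
    # case/control generator: logit P(case) = base + slope[g_A] * trait2_signal
    status_base_logodds: float = -0.7
    status_slope: float = -0.8
    status_slope_by_genotype: dict[int, float] | None = None

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_studies < 1:
            raise InvalidDesignError("n_samples and n_studies must be positive")
        if len(self.mafs) < 2:
            raise InvalidDesignError("need at least two loci (focal + partner)")
        for m in self.mafs:
            if not (0.0 < m <= 0.5):
                raise InvalidDesignError(f"maf {m} outside (0, 0.5]")
        for M in (self.mean_matrix_trait1, self.mean_matrix_trait2):
            M = np.asarray(M, dtype=float)
            if M.shape != (3, 3) or not np.isfinite(M).all():
                raise InvalidDesignError("mean matrices must be finite 3x3")
        for g, r in self.rho_by_genotype.items():
            if not (-1.0 < r < 1.0):
                raise InvalidDesignError(f"rho_by_genotype[{g}]={r} not strictly inside (-1, 1)")
        if not all(s > 0 for s in self.noise_sd):
            raise InvalidDesignError("noise_sd must be strictly positive (degenerate residual variance)")
        if self.ptau_noise_sd <= 0 or self.study_shift_sd < 0:
            raise InvalidDesignError("ptau_noise_sd must be > 0 and study_shift_sd >= 0")


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# spawn-key namespaces for the master seed
_VARIANT, _COVAR, _STUDY, _NOISE, _STATUS = 0, 1, 2, 3, 4


def simulate_genotypes(n: int, maf: float, seed: int) -> np.ndarray:
    """Hardy-Weinberg genotype codes: Binomial(2, maf) per sample."""
    if n < 1:
        raise InvalidDesignError(f"sample count {n} must be >= 1")
    if not (0.0 < maf <= 0.5):
        raise InvalidDesignError(f"maf {maf} outside (0, 0.5]")
    return _stream(seed, _VARIANT, 0).binomial(2, maf, size=n).astype(np.int8)


def _variant_positions(k: int) -> tuple[str, int]:
    chrom = str(1 + k % 22)
    pos = 1_000_000 + 2_000_000 * (k // 22)
    return chrom, pos


def simulate_cohort(design: SyntheticDesign) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Generate one cohort (raw pg/mL-like trait levels) and its genotypes.

    Trait construction per sample: covariate effects + two-locus genotypic
    mean + per-study intercept shift + bivariate Gaussian noise whose
    correlation is ``rho_by_genotype`` at the sample's focal-locus code. The
    returned levels are ``10**(baseline + value)``; run them through
    :func:`rqtlscan.io.standardize_cohort` (or use
    :func:`simulate_standardized_cohort`) before analysis.
    """
    design.validate()
    n, seed = design.n_samples, design.seed

    calls = np.empty((n, len(design.mafs)), dtype=np.int8)
    meta = []
    for k, maf in enumerate(design.mafs):
        calls[:, k] = _stream(seed, _VARIANT, k).binomial(2, maf, size=n)
        chrom, pos = _variant_positions(k)
        meta.append({"id": f"snp{k}", "chrom": chrom, "pos": pos, "ref": "A", "alt": "G", "maf": maf})
    gm = GenotypeMatrix([f"s{i}" for i in range(n)], pd.DataFrame(meta), calls).recompute_maf()

    rng_c = _stream(seed, _COVAR)
    covars = pd.DataFrame(
        {
            "age": rng_c.normal(70.0, 9.0, n),
            "sex": rng_c.integers(0, 2, n).astype(float),
            "apoe_e2": rng_c.binomial(2, 0.07, n).astype(float),
            "apoe_e4": rng_c.binomial(2, 0.23, n).astype(float),
            "pc1": rng_c.normal(0.0, 1.0, n),
            "pc2": rng_c.normal(0.0, 1.0, n),
        }
    )

    rng_s = _stream(seed, _STUDY)
    study_idx = rng_s.integers(0, design.n_studies, n)
    shifts = rng_s.normal(0.0, design.study_shift_sd, size=(design.n_studies, 2))

    g_a = calls[:, 0].astype(int)
    g_b = calls[:, 1].astype(int)
    missing_rho = set(np.unique(g_a)) - set(design.rho_by_genotype)
    if missing_rho:
        raise InvalidDesignError(f"rho_by_genotype missing codes present in data: {sorted(missing_rho)}")

    M1 = np.asarray(design.mean_matrix_trait1, dtype=float)
    M2 = np.asarray(design.mean_matrix_trait2, dtype=float)
    mu1 = M1[g_a, g_b]
    mu2 = M2[g_a, g_b]

    eff1 = np.zeros(n)
    eff2 = np.zeros(n)
    for name, (b1, b2) in design.covariate_effects.items():
        x = covars[name].to_numpy()
        if name == "age":
            x = x - 70.0  # centered so age does not dominate the intercept
        eff1 += b1 * x
        eff2 += b2 * x

    rng_e = _stream(seed, _NOISE)
    z1 = rng_e.standard_normal(n)
    z2 = rng_e.standard_normal(n)
    rho = np.array([design.rho_by_genotype[int(g)] for g in g_a])
    sd1, sd2 = design.noise_sd
    e1 = sd1 * z1
    e2 = sd2 * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)

    t1_signal = mu1 + eff1 + e1  # tau, study shift excluded (removed by centering anyway)
    t2_signal = mu2 + eff2 + e2  # abeta42
    tau = t1_signal + shifts[study_idx, 0]
    abeta = t2_signal + shifts[study_idx, 1]

    rng_p = _stream(seed, _NOISE, 1)
    ptau = (
        design.ptau_loading * t1_signal
        + rng_p.normal(0.0, design.ptau_noise_sd, n)
        + rng_p.normal(0.0, design.study_shift_sd or 1e-12, design.n_studies)[study_idx]
    )

    rng_st = _stream(seed, _STATUS)
    slope = np.full(n, design.status_slope)
    if design.status_slope_by_genotype is not None:
        for g, s in design.status_slope_by_genotype.items():
            slope[g_a == g] = s
    eta = design.status_base_logodds + slope * t2_signal
    status = rng_st.random(n) < 1.0 / (1.0 + np.exp(-eta))

    b1, b2 = design.trait_baseline
    cohort = pd.DataFrame(
        {
            "sample": gm.samples,
            "tau": 10.0 ** (b1 + tau),
            "ptau": 10.0 ** (b1 - 0.6 + ptau),
            "abeta42": 10.0 ** (b2 + abeta),
            "status": status.astype(int),
            "study": [f"study{j + 1}" for j in study_idx],
        }
    )
    cohort = pd.concat([cohort, covars], axis=1)[_io.COHORT_COLUMNS]
    return cohort, gm


def simulate_standardized_cohort(design: SyntheticDesign) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Convenience wrapper: simulate, then log10 + per-study mean-center traits."""
    cohort, gm = simulate_cohort(design)
    return _io.standardize_cohort(cohort), gm


def plant_differential_epistasis(
    effect_size: float, maf_pair: tuple[float, float], base_design: SyntheticDesign
) -> SyntheticDesign:
    """Plant a two-locus interaction whose sign flips between the traits.

    The interaction component is ``effect_size * outer((-1,0,1), (-1,0,1))``
    (an additive-by-additive pattern) added to trait 1 and subtracted from
    trait 2. Rows and columns of each component average to zero, so neither
    locus has a marginal genotypic effect on either trait; the focal locus
    nevertheless becomes an rQTL because the within-genotype trait1/trait2
    covariance varies with the focal code.
    """
    if not np.isfinite(effect_size):
        raise InvalidDesignError("effect_size must be finite")
    for m in maf_pair:
        if not (0.0 < m <= 0.5):
            raise InvalidDesignError(f"maf {m} outside (0, 0.5]")
    a = np.array([-1.0, 0.0, 1.0])
    interaction = effect_size * np.outer(a, a)
    mafs = (maf_pair[0], maf_pair[1]) + tuple(base_design.mafs[2:])
    return replace(
        base_design,
        mafs=mafs,
        mean_matrix_trait1=interaction,
        mean_matrix_trait2=-interaction,
    )


def cohort_covariate_matrix(cohort: pd.DataFrame, covariates=None):
    """Numeric covariate design (no intercept) for a cohort frame."""
    return covariate_design(cohort, covariates or _io.DEFAULT_COVARIATES)
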