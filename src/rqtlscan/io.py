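"""Cohort and genotype I/O.

Genotypes travel as a :class:`GenotypeMatrix` (integer calls 0/1/2 counting
the alternate allele, -1 for missing) read from VCFv4.2 via cyvcf2 or built by
the simulator; phenotypes and covariates travel as a pandas DataFrame with a
fixed header (sample, tau, ptau, abeta42, status, study, age, sex, apoe_e2,
apoe_e4, pc1, pc2). Trait standardization follows the analysis convention for
multi-platform biomarker panels: log10-transform, then remove each study's
mean so that per-study means are exactly zero (no variance scaling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linear import MISSING

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "GenotypeMatrix",
    "COHORT_COLUMNS",
    "TRAITS",
    "DEFAULT_COVARIATES",
    "compute_maf",
    "filter_maf",
    "standardize_traits",
    "center_per_study",
    "standardize_cohort",
    "read_vcf",
    "write_vcf",
    "read_cohort",
    "write_cohort",
    "align",
    "write_results",
    "RESULT_COLUMNS",
]

COHORT_COLUMNS = [
    "sample", "tau", "ptau", "abeta42", "status", "study",
    "age", "sex", "apoe_e2", "apoe_e4", "pc1", "pc2",
]
TRAITS = ["tau", "ptau", "abeta42"]
DEFAULT_COVARIATES = ["age", "sex", "study", "apoe_e2", "apoe_e4", "pc1", "pc2"]

RESULT_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "maf", "df1", "df2",
    "statistic", "p_asymptotic", "p_empirical", "n_boot", "retained_classes",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def compute_maf(calls: np.ndarray) -> np.ndarray:
    """Minor allele frequency per variant from integer calls, missing excluded."""
    calls = np.asarray(calls)
    valid = calls != MISSING
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(valid, calls, 0).sum(axis=0) / (2.0 * n)
    alt = np.where(n > 0, alt, np.nan)
    return np.minimum(alt, 1.0 - alt)


@dataclass
class GenotypeMatrix:
    """Sample-by-variant integer genotype calls with per-variant metadata.

    ``variants`` columns: id, chrom, pos (1-based), ref, alt, maf.
    """

    samples: list[str]
    variants: pd.DataFrame
    calls: np.ndarray  # (n_samples, n_variants), int8, -1 missing

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def genotype(self, variant_id: str) -> np.ndarray:
        """Call vector for one variant by id."""
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return self.calls[:, idx[0]].astype(np.int64)

    def recompute_maf(self) -> "GenotypeMatrix":
        v = self.variants.copy()
        v["maf"] = compute_maf(self.calls)
        return GenotypeMatrix(self.samples, v, self.calls)

    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.samples, self.variants.iloc[index], self.calls[:, index])

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.samples[i] for i in index], self.variants, self.calls[index, :]
        )


def filter_maf(gmatrix: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Drop variants with minor allele frequency below ``threshold``.

    The boundary is kept (maf == threshold passes). MAF is recomputed from the
    calls of the analysis sample, not taken from stored metadata.
    """
    maf = compute_maf(gmatrix.calls)
    keep = np.flatnonzero(maf >= threshold)
    if keep.size == 0:
        logger.warning("filter_maf: no variants retained at threshold %g", threshold)
    out = gmatrix.take_variants(keep)
    out.variants["maf"] = maf[keep]
    return out


def standardize_traits(levels, study) -> np.ndarray:
    """log10-transform raw biomarker levels (pg/mL) and mean-center per study."""
    levels = np.asarray(levels, dtype=float)
    study = np.asarray(study)
    bad = ~(levels > 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise DataError(f"nonpositive biomarker level at sample index {i} (value {levels[i]!r})")
    return center_per_study(np.log10(levels), study)


def center_per_study(values, study) -> np.ndarray:
    """Remove each study's mean from already log-scale trait values."""
    s = pd.Series(np.asarray(values, dtype=float))
    return (s - s.groupby(np.asarray(study)).transform("mean")).to_numpy()


def standardize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Apply log10 + per-study centering to all trait columns of a cohort table."""
    out = cohort.copy()
    for t in TRAITS:
        out[t] = standardize_traits(cohort[t].to_numpy(), cohort["study"].to_numpy())
    return out


def read_vcf(path, ds_uncertainty: float = 0.1) -> GenotypeMatrix:
    """Read a VCFv4.2 file into a GenotypeMatrix.

    Hard GT calls are used when present. If the record carries a DS (dosage)
    FORMAT field instead, dosages are converted to best-guess calls, set to
    missing when the dosage is further than ``ds_uncertainty`` from an integer.
    Multiallelic records are skipped with a warning; ``./.`` becomes missing.
    MAF is recomputed from the parsed calls.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise DataError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, meta = [], []
    for rec_no, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            logger.warning(
                "read_vcf: skipping multiallelic record %s:%s (%s)", rec.CHROM, rec.POS, rec.ID
            )
            continue
        gt = np.array(rec.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        calls = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        if (calls == MISSING).all() and "DS" in (rec.FORMAT or []):
            ds = np.asarray(rec.format("DS"), dtype=float).ravel()
            best = np.rint(ds)
            calls = np.where(np.abs(ds - best) <= ds_uncertainty, best, MISSING).astype(int)
        rows.append(calls.astype(np.int8))
        meta.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "maf": np.nan,
            }
        )
    if not rows:
        raise DataError(f"no biallelic records in {path}")
    calls = np.column_stack(rows)
    gm = GenotypeMatrix(samples, pd.DataFrame(meta), calls)
    return gm.recompute_maf()


def write_vcf(gmatrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 file (GT field only, biallelic records)."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gmatrix.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gmatrix.samples) + "\n")
        for j, v in gmatrix.variants.iterrows():
            gts = "\t".join(code_to_gt[int(c)] for c in gmatrix.calls[:, j])
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_cohort(path) -> pd.DataFrame:
    """Read the tab-separated phenotype/covariate table; validates the header."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cohort table missing required columns: {missing}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise DataError(f"duplicated sample identifier: {dup!r}")
    df["sample"] = df["sample"].astype(str)
    df["study"] = df["study"].astype(str)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def align(cohort: pd.DataFrame, gmatrix: GenotypeMatrix) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Put cohort rows and genotype rows in the same sample order.

    The identifier sets must match exactly; a mismatch raises rather than
    silently dropping samples.
    """
    csamples = set(cohort["sample"])
    gsamples = set(gmatrix.samples)
    if csamples != gsamples:
        only_c = sorted(csamples - gsamples)[:5]
        only_g = sorted(gsamples - csamples)[:5]
        raise DataError(
            f"sample mismatch between cohort and genotypes: "
            f"cohort-only {only_c}, genotype-only {only_g}"
        )
    cohort = cohort.set_index("sample", drop=False).loc[gmatrix.samples].reset_index(drop=True)
    return cohort, gmatrix


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as TSV with stable float formatting."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
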