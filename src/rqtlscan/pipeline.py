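"""End-to-end two-stage screening pipeline.

standardize traits → stage-1 rQTL screen per trait pair → unique-location
clustering → per-seed G×G screens at the derived stage-2 threshold →
parametric bootstrap for hits → logistic follow-up → figure data.

Every table is TSV, every figure has an underlying TSV emitted first (so the
numbers a figure shows are testable without parsing images), and the run is
byte-reproducible under a fixed master seed. The run configuration is
serialized verbatim into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import followup as _followup
from . import gxg as _gxg
from . import io as _io
from . import rqtl as _rqtl
from .bootstrap import BootstrapPolicy
from .linear import covariate_design

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_pipeline", "render_rqtl_figure"]


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    vcf: str
    pheno: str
    outdir: str
    trait_pairs: tuple[tuple[str, str], ...] = (("tau", "abeta42"), ("ptau", "abeta42"))
    covariates: tuple[str, ...] = tuple(_io.DEFAULT_COVARIATES)
    min_genotype_count: int = 20
    min_cell: int = 5
    stage1_threshold: float = 5e-8
    clump_window: int = 1_000_000
    maf_threshold: float = 0.01
    boot_max_reps: int = 100_000
    boot_early_stop: int = 10
    seed: int = 13
    standardize: bool = True  # inputs are raw pg/mL levels; log10 + center them
    run_followup: bool = True
    make_figures: bool = True

    def __post_init__(self):
        if min(self.stage1_threshold, self.maf_threshold) <= 0 or self.clump_window <= 0:
            raise ValueError("thresholds and the clump window must be positive")
        self.trait_pairs = tuple(tuple(p) for p in self.trait_pairs)

    def policy(self, stage_seed: int) -> BootstrapPolicy:
        return BootstrapPolicy(
            max_reps=self.boot_max_reps,
            early_stop_exceedances=self.boot_early_stop,
            seed=stage_seed,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**{k: tuple(map(tuple, v)) if k == "trait_pairs" else v for k, v in raw.items()})


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(stage,)).generate_state(1)[0] % (2**31))


def run_full_pipeline(config: RunConfig, cohort=None, gmatrix=None) -> Path:
    """Run the full two-stage analysis; returns the output directory.

    ``cohort``/``gmatrix`` may be passed in memory; otherwise they are read
    from ``config.pheno`` / ``config.vcf``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("rqtlscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out, cohort, gmatrix)
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path, cohort, gmatrix) -> Path:
    if cohort is None:
        cohort = _io.read_cohort(config.pheno)
    if gmatrix is None:
        gmatrix = _io.read_vcf(config.vcf)
    cohort, gmatrix = _io.align(cohort, gmatrix)
    if config.standardize:
        cohort = _io.standardize_cohort(cohort)
    gmatrix = _io.filter_maf(gmatrix, config.maf_threshold)
    logger.info("aligned cohort n=%d, variants after MAF filter=%d", len(cohort), gmatrix.n_variants)

    report: dict = {"n_samples": len(cohort), "n_variants": int(gmatrix.n_variants), "stages": {}}
    cov, _ = covariate_design(cohort, list(config.covariates))

    for stage_no, (response, modifier) in enumerate(config.trait_pairs):
        pair_tag = f"{response}_{modifier}"
        policy = config.policy(_stage_seed(config.seed, stage_no))
        table = _rqtl.screen_genome(
            cohort, gmatrix, response=response, modifier=modifier,
            covariates=list(config.covariates), threshold=config.stage1_threshold,
            min_genotype_count=config.min_genotype_count, boot_policy=policy,
        )
        _io.write_results(table, out / f"rqtl_{pair_tag}.tsv")
        for _, r in table[table["skip_reason"] != ""].iterrows():
            logger.info("skip variant=%s reason=%s", r["variant_id"], r["skip_reason"])

        hits = table[table["p_asymptotic"] <= config.stage1_threshold]
        n_loc = _rqtl.count_unique_locations(hits, window=config.clump_window)
        seeds = _rqtl.select_seed_snps(hits, window=config.clump_window)
        stage2_threshold = _gxg.gxg_threshold(n_loc) if n_loc else None
        report["stages"][pair_tag] = {
            "n_hits": int(len(hits)),
            "n_unique_locations": int(n_loc),
            "stage2_threshold": stage2_threshold,
            "seeds": seeds["variant_id"].tolist() if len(seeds) else [],
        }
        logger.info(
            "stage %s: %d hits, %d unique locations, stage-2 threshold %s",
            pair_tag, len(hits), n_loc, stage2_threshold,
        )

        for si, (_, seed_row) in enumerate(seeds.iterrows()):
            sid = seed_row["variant_id"]
            corr_rng = np.random.default_rng(_stage_seed(config.seed, 100 + stage_no * 10 + si))
            model = _rqtl.RqtlInteractionModel.from_dataframe(
                cohort, gmatrix.genotype(sid), response=response, modifier=modifier,
                covariates=list(config.covariates),
                min_genotype_count=config.min_genotype_count, variant_id=sid,
            )
            corr = model.fit().per_genotype_correlation(rng=corr_rng)
            _io.write_results(corr, out / f"rqtl_corr_{pair_tag}_{sid}.tsv")

            gxg_tables = {}
            for trait in (response, modifier):
                gpolicy = config.policy(_stage_seed(config.seed, 200 + stage_no * 10 + si))
                gtab = _gxg.screen_partners(
                    cohort, gmatrix, sid, trait=trait,
                    covariates=list(config.covariates), threshold=stage2_threshold,
                    min_cell=config.min_cell, boot_policy=gpolicy,
                    flag_window=config.clump_window,
                )
                _io.write_results(gtab, out / f"gxg_{trait}_{sid}.tsv")
                gxg_tables[trait] = gtab

            best = gxg_tables[response]
            best = best[best["skip_reason"] == ""]
            if config.make_figures and len(best):
                partner = best.iloc[0]["variant_id"]
                try:
                    render_rqtl_figure(
                        cohort, gmatrix, sid, partner,
                        response=response, modifier=modifier,
                        covariates=list(config.covariates),
                        out_prefix=out / f"figure_{pair_tag}_{sid}_{partner}",
                        rng=np.random.default_rng(_stage_seed(config.seed, 300 + stage_no * 10 + si)),
                        min_genotype_count=config.min_genotype_count,
                        min_cell=config.min_cell,
                    )
                except ValueError as exc:
                    logger.info("figure skipped for %s: %s", sid, exc)

        if config.run_followup and len(seeds) and cohort["status"].notna().any():
            frows = []
            for sid in seeds["variant_id"]:
                try:
                    fres = _followup.logistic_rqtl(
                        cohort["status"].to_numpy(float),
                        cohort[modifier].to_numpy(float),
                        gmatrix.genotype(sid), cov,
                        min_genotype_count=config.min_genotype_count,
                        variant_id=sid, biomarker_label=modifier,
                    )
                    frows.append(
                        {"variant_id": sid, "biomarker": modifier, "df1": fres.df1,
                         "lr_statistic": fres.lr_statistic, "p": fres.p,
                         "converged": fres.converged, "n": fres.nobs, "skip_reason": ""}
                    )
                except Exception as exc:  # separation / class-size skips
                    frows.append(
                        {"variant_id": sid, "biomarker": modifier, "df1": np.nan,
                         "lr_statistic": np.nan, "p": np.nan, "converged": False,
                         "n": 0, "skip_reason": str(exc)}
                    )
            _io.write_results(pd.DataFrame(frows), out / f"followup_{pair_tag}.tsv")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return out


def render_rqtl_figure(
    cohort: pd.DataFrame,
    gmatrix,
    rqtl_id: str,
    partner_id: str,
    *,
    response: str = "tau",
    modifier: str = "abeta42",
    covariates: list[str] | None = None,
    out_prefix: Path | str = "rqtl_figure",
    rng: np.random.Generator | None = None,
    min_genotype_count: int = 20,
    min_cell: int = 5,
) -> Path:
    """Three-panel rQTL decomposition figure plus its underlying TSVs.

    Top/middle panels: covariate-adjusted two-locus genotypic means of each
    trait against the rQTL genotype (one line per partner genotype); bottom
    panel: covariate-adjusted within-genotype trait correlation with
    bootstrap-SE error bars.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if rng is None:
        rng = np.random.default_rng(0)
    covariates = covariates if covariates is not None else _io.DEFAULT_COVARIATES
    cov, _ = covariate_design(cohort, covariates)
    g_seed = gmatrix.genotype(rqtl_id)
    g_part = gmatrix.genotype(partner_id)
    out_prefix = Path(out_prefix)

    model = _rqtl.RqtlInteractionModel.from_dataframe(
        cohort, g_seed, response=response, modifier=modifier,
        covariates=covariates, min_genotype_count=min_genotype_count, variant_id=rqtl_id,
    )
    if model.factor.n_levels < 2:
        raise ValueError("fewer than two genotype classes after filtering; nothing to plot")
    corr = model.fit().per_genotype_correlation(rng=rng)
    corr.to_csv(f"{out_prefix}_corr.tsv", sep="\t", index=False, float_format="%.10g")

    panels = {}
    for trait in (response, modifier):
        res = _gxg.gxg_test(
            cohort[trait].to_numpy(float), g_seed, g_part, cov,
            min_cell=min_cell, variant_a=rqtl_id, variant_b=partner_id, trait_label=trait,
        )
        means = res.adjusted_cell_means(rng=rng)
        means.to_csv(f"{out_prefix}_means_{trait}.tsv", sep="\t", index=False, float_format="%.10g")
        panels[trait] = means

    fig, axes = plt.subplots(3, 1, figsize=(5, 10), sharex=True)
    for ax, trait in zip(axes[:2], (response, modifier)):
        means = panels[trait]
        for cb, grp in means.groupby("code_b"):
            ax.errorbar(grp["code_a"], grp["mean"], yerr=grp["se"], marker="o",
                        capsize=3, label=f"{partner_id}={cb}")
        ax.set_ylabel(f"adjusted {trait} mean")
        ax.legend(fontsize=7)
    ok = corr[corr["defined"]]
    axes[2].errorbar(ok["genotype"], ok["r"], yerr=ok["se"], marker="s", capsize=3, color="k")
    axes[2].axhline(0.0, lw=0.5, color="grey")
    axes[2].set_ylabel(f"corr({response}, {modifier})")
    axes[2].set_xlabel(f"{rqtl_id} genotype")
    axes[2].set_xticks(sorted(corr["genotype"]))
    fig.tight_layout()
    fig_path = Path(f"{out_prefix}.png")
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)
    return fig_path
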