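# rqtlscan

Screening for **relationship QTL (rQTL)** — loci at which the *correlation*
between two quantitative traits differs by genotype — and for the two-locus
**gene-by-gene (G×G) interactions** that such loci seed. The package was built
for CSF Alzheimer's-biomarker endophenotypes (tau, p-tau181, Aβ42 on the
standardized log10 scale, pooled across a multi-study cohort), but the models
are generic to any pair of quantitative traits with genotype data.

## The models

Stage 1, per variant, with the SNP as a factor (genotype classes with fewer
than 20 carriers dropped):

```
trait = u + covariates + modifier + SNP + modifier × SNP
```

A putative rQTL exists when the `modifier × SNP` block is significant against
the null model without it — a partial F with 2 numerator df for a
three-genotype model or 1 df for two, at the genome-wide cut 5×10⁻⁸. In the
biomarker application the response is tau or p-tau and the modifier is Aβ42;
covariates are age, sex, study, APOE ε2/ε4 allele counts and two ancestry PCs.

Stage 2, for each independent significant rQTL (one per ~1 Mb location), a
genome screen for partners interacting with it on each trait of its pair:

```
full:     trait = u + covariates + TwoLocusGenotypes      (cell means)
reduced:  trait = u + covariates + rQTL + SNP             (single-locus factors)
```

The cell-means full model captures all additive-by-additive / -dominance /
dominance-by- interaction content without explicit contrasts, which become
non-orthogonal or inestimable under unbalanced or missing cells; two-locus
cells with fewer than five samples are excluded, giving 4 numerator df on a
complete 3×3 table. The stage-2 threshold is 5×10⁻⁸ divided by the number of
independent rQTL from that screen.

Because interaction F tests can inflate when residual variance depends on
genotype, empirical p-values come from a **parametric bootstrap**: simulate
responses from the fitted null, refit both models, and report
(exceedances + 1)/(replicates + 1), with `< 1/max_reps` when nothing exceeds
the observed statistic. A genotype-stratified noise option restores
calibration under variance heterogeneity; an HC3 sandwich Wald test is also
available.

Logistic analogues (`status = covariates + biomarker × SNP`, likelihood-ratio
tested; and additive single-SNP association) support case/control follow-up.

## Worked example

```python
import numpy as np
from rqtlscan import (SyntheticDesign, plant_differential_epistasis,
                      simulate_standardized_cohort, RqtlInteractionModel,
                      BootstrapPolicy)

design = plant_differential_epistasis(
    effect_size=0.6, maf_pair=(0.3, 0.3),
    base_design=SyntheticDesign(n_samples=6000, n_studies=4,
                                mafs=(0.3, 0.3, 0.2, 0.4), seed=21))
cohort, genotypes = simulate_standardized_cohort(design)

model = RqtlInteractionModel.from_dataframe(cohort, genotypes.genotype("snp0"),
                                            response="tau", modifier="abeta42",
                                            variant_id="snp0")
results = model.fit()
results.bootstrap(BootstrapPolicy(max_reps=100_000, seed=1))
print(results.summary())
```

```
rQTL interaction test
==============================================
variant:            snp0
trait pair:         tau/abeta42
n used:             6000
genotype classes:   [0, 1, 2] (counts [2926, 2504, 570])
F(2, 5985) = 254.9909
p (asymptotic):     5.309e-107
p (empirical):      < 1e-05  [0 exceedances / 100000 replicates]
```

The planted additive-by-additive pattern (sign-flipped between tau and Aβ42)
makes the within-genotype tau/Aβ42 correlation far more negative in the
homozygote classes of `snp0`, so the interaction F is enormous; no bootstrap
replicate reaches it, hence the bound `< 1/max_reps`.
`results.per_genotype_correlation()` returns the per-genotype adjusted
correlations with bootstrap SEs, and `rqtlscan.gxg.gxg_test` localizes the
interacting partner (`snp1`).

The same flow runs from the shell:

```sh
rqtl-scan simulate --n 3000 --effect-size 1.0 --out-vcf g.vcf --out-pheno p.tsv
rqtl-scan rqtl --vcf g.vcf --pheno p.tsv --response tau --modifier abeta42 --out rqtl.tsv
rqtl-scan gxg  --vcf g.vcf --pheno p.tsv --seed-snp snp0 --trait tau --out gxg.tsv
rqtl-scan all  --vcf g.vcf --pheno p.tsv --outdir run/
```

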