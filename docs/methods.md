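# Methods

## Model and procedure

`rqtlscan` implements a two-stage interaction-screening design for pairs of
quantitative traits measured with genome-wide genotypes.

**Stage 1 (rQTL).** For each variant, the full model is an ANCOVA with the
genotype as a factor and a continuous modifier trait interacting with it:

    response = u + covariates + modifier + G + modifier × G

The null model drops only the interaction block, and the statistic is the
partial F, `F = ((RSS_r − RSS_f)/df1) / (RSS_f/df2)`. Genotype classes with
fewer than `min_genotype_count = 20` carriers in the per-test complete-case
sample are excluded before modelling, so `df1` is the number of retained
classes minus one (2 or 1). Classes are recounted on the complete-case
sample, not the raw calls, so the filter guarantees estimability in the
sample actually fitted. The modifier always enters as a continuous
standardized covariate and is never factorized. The partial F was chosen as
the nested-comparison statistic (a likelihood-ratio test is monotone in it
under Gaussian errors, and the bootstrap calibrates whichever is used); an
HC3 sandwich Wald variant is available behind `fit(robust=True)`.

**Unique locations.** Genome-wide hits (asymptotic p ≤ 5×10⁻⁸) are grouped
by single-linkage clustering within 1 Mb on a chromosome; the cluster count
is the number of independent rQTL, and the most significant SNP of each
cluster seeds stage 2. The 1 Mb window is a package choice: any reasonable
window collapses hits a few tens of kb apart while keeping separate
chromosome arms distinct.

**Stage 2 (G×G).** For each seed and each trait of its pair, every other
variant is tested by comparing a cell-means model (one free parameter per
retained two-locus genotype cell, plus covariates) against an
additive-factors model (covariates + one factor per locus). Cells with fewer
than `min_cell = 5` samples are excluded; single-locus factor levels in the
reduced model are recomputed on the cell-masked sample so both models are
nested on identical observations (the treatment of levels emptied by the
cell filter is a package convention). On a complete 3×3 table
`df1 = (9−1) − 2 − 2 = 4`, the pooled AA/AD/DA/DD interaction content; in
general `df1 = (cells−1) − (levels_A−1) − (levels_B−1)` and the test is
skipped when that is < 1. The stage-2 threshold is 5×10⁻⁸ divided by the
number of independent rQTL from that screen. Partners within 1 Mb of the
seed are tested but flagged (`near_seed`), since local LD can mimic
interaction.

**Trait preparation.** Raw biomarker levels (pg/mL) are log10-transformed
and mean-centered within each study — centering only, no variance scaling —
so per-study means are exactly zero. Variants with MAF < 0.01 (recomputed
from the analysis calls, missing excluded; the boundary is kept) are
removed after sample alignment. Sample alignment between genotype and
phenotype containers requires identical identifier sets and raises on any
mismatch rather than dropping.

## Parametric bootstrap

Empirical p-values simulate responses from the fitted null:
`y* = fitted_null + noise`, refit both models, and count replicates with
`F* ≥ F_obs` (ties count, conservatively). The estimator is
`(k + 1)/(B + 1)`, which cannot be zero; when `k = 0` at the full budget the
result is additionally reported as the bound `< 1/max_reps` (a declared
budget of 2×10⁸ replicates gives the floor 5×10⁻⁹). Published empirical
p-values from comparable screens are not always integer multiples of `1/B`;
the `(k+1)/(B+1)` convention is this package's documented choice and no
equivalence with any other estimator is asserted. Early stopping (default:
stop once 10 exceedances accrue, reporting `(k+1)/(reps+1)`) keeps
genome-scale screens tractable without biasing the decision at thresholds
far below the stopping region.

Noise models:

* `pooled` (default): i.i.d. Gaussian, SD `sqrt(RSS_null/df_null)`. Under a
  correct homoskedastic null this reproduces the exact F distribution.
* `stratified`: Gaussian with per-group SDs estimated from the null
  residuals (grouped on genotype). This is the variant that stays calibrated
  when residual variance differs by genotype — the mechanism behind type-I
  inflation of interaction tests. A pooled-noise bootstrap cannot repair
  that inflation, because it reproduces the same homoskedastic null the
  asymptotic F already assumes; the calibration suite therefore runs the
  stratified variant, and `calibration_suite` records both methods'
  rejection rates.
* `resample`: nonparametric residual resampling (residuals rescaled by
  `sqrt(n/df_null)`).

The Gaussian residual assumption is itself a modelling choice — the traits
are log10-standardized and fitted by OLS, so Gaussian noise matches the
model family — and is the assumption the synthetic generator shares.

Replicates reuse the thin-QR factors of both fixed designs, so each costs
two matrix products; replicates run in vectorized chunks capped at a few
million doubles of buffer.

## Synthetic cohort generator

`SyntheticDesign` emulates the structure the screens assume: a multi-study
cohort (defaults n = 3146, 9 studies) with HWE genotypes at given MAFs, the
first two loci acting as focal (A) and partner (B), the rest as independent
null background; per-study intercept shifts (SD 0.1 log10 units) that the
centering step removes; linear covariate effects (age ~ N(70, 9²), sex ~
Bernoulli(0.5), APOE ε2/ε4 allele counts at frequencies 0.07/0.23, PCs ~
N(0,1) — any linear-effect distributions would do, these are the documented
choice); and a bivariate Gaussian (tau, Aβ42) residual with SD 0.25 per
trait whose correlation is `rho_by_genotype` at the sample's locus-A code.
Two-locus genotypic means come from 3×3 matrices per trait;
`plant_differential_epistasis` fills them with
`±effect × outer((−1,0,1), (−1,0,1))` — an additive-by-additive pattern,
sign-flipped between traits, with exactly zero row/column means, so neither
locus has a marginal effect yet the focal locus is an rQTL. p-tau is a noisy
linear proxy of the tau signal (loading 0.8, extra SD 0.15); case/control
status follows a logistic model on the Aβ42 signal (base log-odds −0.7,
slope −0.8, optionally genotype-dependent). Traits are emitted as
`10**(baseline + value)` pg/mL-like levels so a simulated cohort round-trips
through the standardization code path.

Seeding: one master seed; every component (each variant, covariates, study
assignment, residuals, status) draws from
`SeedSequence(seed, spawn_key=…)` streams, so any single variant can be
regenerated in isolation and identical designs give bit-identical cohorts.

What the generator does **not** emulate: LD between loci, imputation
uncertainty, per-study variance differences, non-Gaussian trait tails,
population stratification beyond the supplied PCs, and genotype–covariate
dependence. Passing tests therefore demonstrate correctness of the
machinery and calibration under the model's own assumptions, not robustness
of the method on real consortium data.

## Numerical choices

* OLS via pivoted QR; exactly aliased columns are dropped (recorded in
  `LinearFit.dropped`; which member of a dependent set is dropped follows
  the pivoting) with fitted values unaffected; rank tolerance
  `max(n,p)·1e-10·|R₀₀|`.
* Degenerate tests (df1 ≤ 0, saturated full model) raise; per-variant
  failures in screens are logged as machine-readable skip reasons, never
  fatal.
* Factor reference level is the most frequent retained genotype; all test
  statistics are invariant to the choice (tested), as they are to allele
  relabelling 0↔2 and to locus order in the two-locus model.
* Per-genotype adjusted correlations need ≥ 3 samples per class (flagged
  undefined below); SEs for correlations and adjusted cell means come from
  nonparametric within-class resampling (default 1000 draws).
* Logistic models (follow-up) are fitted by statsmodels' Newton solver;
  non-convergence or separation flags the result and suppresses the
  p-value. Status classes below 20 in the masked sample are skipped.
* Pipeline determinism: all stage seeds derive from the master seed via
  `SeedSequence`; TSVs are written with `%.10g` formatting so reruns are
  byte-identical.

## Problem sizes used in the checks

The verification suite runs at desk scale by design: null-calibration and
uniformity checks use 500–2000 replicates at n = 200–2000; the calibration
suite uses n = 2000, 2000 replicates per scenario, bootstrap budget 10³ with
early stopping; planted-parameter recovery uses n = 20 000 (recovery of
per-genotype correlations {−0.169, −0.19, −0.414} within ±0.03, Monte-Carlo
power of the rQTL test on the effect-size-1 differential-epistasis design
~1.0 at α = 10⁻⁴); pipelines in tests use n = 2000–2500 with 10–20 variants
and bootstrap budgets ≤ 10³. Production screens would raise `max_reps` (the
headline convention is 1–2×10⁸) and run per-chromosome.

## Known limitations

* No mixed models or GLS; relatedness and repeated measures are out of scope.
* No LD-aware clumping beyond the 1 Mb distance rule, and no conditional
  multi-SNP models.
* The stratified bootstrap estimates per-group SDs with a simple pooled df
  correction; with very small genotype classes those SDs are noisy (the
  count-20 filter keeps classes above that regime).
* Dosage input uses best-guess calls at an uncertainty cutoff of 0.1;
  genuine dosage-aware modelling is not provided.
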