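# Methods

`cismwas` implements a pipeline for predicting CpG methylation from local SNP
genotypes and testing genetically predicted methylation for trait association
using only GWAS summary statistics. This note documents the models, the
numerical choices, and what the synthetic cohorts do and do not establish.

## Per-CpG prediction models

For CpG *c* with beta-values *y* and the dosage matrix *X* of SNPs within a
cis window *w* of the site (inclusive boundaries, |pos − pos_c| ≤ w), the
model is penalised linear regression in the glmnet parameterisation

    (1/2n) Σᵢ (yᵢ − β₀ − xᵢᵀβ)² + λ [ (1−α) ‖β‖₂²/2 + α ‖β‖₁ ],

with mixing α = 0 (ridge), 0.5 (elastic net, the pipeline default) or 1
(lasso). Genotype columns are standardised inside the fit and the reported
weights are mapped back to the dosage scale, so a stored model is applied as
`intercept + Σ wₗ·dosageₗ`.

**Penalty selection.** λ is chosen by k-fold cross-validation (default k = 10,
folds fixed by a caller seed and shared across the path) over a geometric path
of 100 values from λ_max = maxⱼ |xⱼᵀy| / (n·max(α, 0.001)) down to
10⁻⁴·λ_max — the de facto convention of coordinate-descent elastic-net
software. Before the minimum-CV-MSE choice, any λ whose full-data refit
contains no SNPs (all weights exactly zero) is excluded; if every λ is
excluded the CpG receives **no model** rather than a SNP-free one. This
exclusion rule is what guarantees every released model is usable for
imputation. An explicit λ path can be supplied, which is how the rule's
"no model" branch is exercised deterministically in tests.

**Window optimisation.** Candidate windows are 250 kb, 500 kb, 1 Mb, 2 Mb and
3 Mb. Each window's model is trained on the training split and scored by the
signed Pearson correlation R between predicted and observed methylation on
the disjoint test split; the per-CpG optimal window is the argmax of test R,
with ties resolved toward the smaller window (fewer predictors, less noise).
The cap at 3 Mb confines models to cis mQTLs.

**Staging and retention.** Cohorts are split 50/20/30 (train/test/hold-out)
with largest-remainder rounding so group sizes are exact. Models are retained
when R ≥ 0.1 (signed; negative-R models fail naturally) and R ≥ 0.5 marks the
well-predicted subset. Cross-cohort validation applies models to an
independent cohort with per-SNP allele harmonisation: matching effect/other
alleles use the dosage, swapped coding uses 2 − dosage, irreconcilable pairs
are dropped, and missing SNPs contribute 0 while reducing the reported usage
fraction. Strand-ambiguous (A/T, C/G) SNPs are kept by default with a
warning; synthetic panels have no strand issues, and `drop_ambiguous` exists
for real data.

## Window-local heritability

The SNPs in a CpG's optimal window build a standardised GRM,
A_jk = (1/m) Σᵢ (x_ij − 2pᵢ)(x_ik − 2pᵢ) / (2pᵢ(1−pᵢ)), monomorphic variants
excluded. Cis-h² is estimated under y = μ + g + e, g ~ N(0, A σ²_g),
e ~ N(0, I σ²_e) by average-information REML: each AI step is step-halved until it does not
lower the restricted likelihood, with an EM update as the fallback (EM is
monotone but slow near the sigma^2_g = 0 boundary).
Defaults: start at σ²_g = σ²_e = var(y)/2, tolerance 10⁻⁶ on component
changes, at most 100 iterations; components are floored at 10⁻⁸·var(y)
during iteration and reported as 0 at the floor; h² = σ²_g/(σ²_g+σ²_e) is
restricted to [0, 1]. SEs come from the inverse AI matrix with the delta
method for h². One eigendecomposition of A makes each REML iteration O(n),
so many responses can be fitted against a shared GRM cheaply. h² is the
ceiling on squared prediction accuracy, which the test suite checks as
R² ≤ ĥ² + 2·SE for ≥95% of synthetic CpGs.

## Summary-statistic association

Given model weights w, GWAS per-SNP Z-scores Z_l = β̂_l/se_l and a reference
dosage covariance Σ over the model's SNPs, the CpG association statistic is

    Z_c = Σ_l w_l (σ_l/σ_c) Z_l,   σ_l = √Σ_ll,   σ_c = √(wᵀΣw),

with a two-sided normal p-value — the summary-statistic equivalent of
regressing the trait on individually predicted methylation. The covariance
reference is the training-cohort dosage covariance stored alongside the
model DB (no external LD panel). GWAS rows are allele-harmonised (swapped
coding negates Z_l, irreconcilable pairs dropped); SNPs missing from the
GWAS are dropped and w/Σ restricted to the observed subset rather than
imputed. A CpG with no overlapping SNPs, or whose predicted methylation has
zero reference variance, is reported as untestable with the reason, and the
Bonferroni family size is the number of *testable* CpGs. The statistic is
invariant to positive rescaling of the weights and to consistent allele
recoding; its agreement with the individual-level regression Z (|ΔZ| < 0.05
when sumstats and covariance derive from the same samples) is the module's
primary correctness check. That identity is a small-per-feature-effect
approximation: its error grows like |Z|·r²/2 in the trait variance share r²
of a single feature, which is why the generator's phenotype spreads its
heritability across several CpGs (see below).

## Enrichment

Annotation enrichment of a selected CpG set against a background containing
it uses the 2×2 table (selected vs background-only × annotated vs not) with
the sample odds ratio (a·d)/(b·c) and a two-sided Fisher exact p-value. A
Haldane +0.5 correction applies to the odds ratio only when a cell is zero;
the p-value is always the uncorrected exact test. The background is an
explicit argument (all QC-passing CpGs for well-predicted sets; all tested
CpGs for trait-associated sets) — never inferred.

## Synthetic cohorts

The generator emulates clean post-QC cohorts with a sparse cis architecture,
on one synthetic chromosome with CpGs every 500 kb, each owning a region of
50 variants within ±250 kb (regions tile the chromosome, so windows ≥ 500 kb
reach into neighbouring regions and window-sweep behaviour is observable).

* **Genotypes.** Haplotypes are first-order Markov chains per region: the
  alt-allele frequency is drawn once per region from `maf_range`
  (default 0.05–0.5), and each variant copies its left neighbour with
  probability `ld_rho` (default 0.5) or is redrawn. Drawing the frequency
  once per region makes the adjacent-haplotype correlation exactly `ld_rho`
  (a per-variant frequency would force a clamped, biased copy probability).
  Dosage = sum of two independent haplotypes.
* **Methylation.** A fraction `prop_heritable_cpgs` (default 0.8) of CpGs
  receive k (default 2) causal SNPs from their own region with N(0,1)
  effects, rescaled so the genetic variance share equals `h2_cis`
  (default 0.5); the rest are pure noise. Latent traits are mapped affinely
  per CpG into [0.05, 0.95] — Pearson R and the penalised fits are
  affine-equivariant, so evaluation is unaffected, and beta-value range
  constraints hold without a logit transform.
* **Phenotype and GWAS.** A quantitative phenotype takes variance share
  `phenotype_h2` (default 0.1) from `phenotype_causal_cpgs` (default 5)
  heritable CpGs with equal-magnitude, random-sign weights on standardised
  methylation, plus Gaussian noise. Equal shares keep every feature in the
  complex-trait regime where summary-statistic association is derived; a
  single dominating feature would make the summary/individual-level
  agreement degrade by the |Z|·r²/2 term above. Marginal per-SNP summary
  statistics are simple-regression slopes with OLS standard errors and
  t-test p-values; monomorphic variants are dropped with a log record.

Not modelled: trans mQTLs, cell-type heterogeneity, batch and array
measurement error, strand ambiguity, covariates. Passing tests therefore
establish the correctness and calibration of the algorithms under the stated
generative assumptions, not the real-data accuracy attainable on arrays.

## Problem sizes and reproducibility

The study cohort used by the deeper tests and the acceptance script is
n = 2000 samples × 50 CpGs (training on the 50% split at a 250 kb window);
method-ordering runs use n = 1000 × 50 CpGs at cis-h² 0.4; REML recovery uses
50 replicates per h² ∈ {0, 0.3, 0.6} at n = 1000, re-using one panel per
level with fresh LMM responses (standard practice for variance-component
coverage studies; the response, not the GRM, is the random quantity under
the model). Null calibration pools 15 replicate null-phenotype GWAS scans
(~600 Z draws) so the Monte-Carlo error of the variance estimate (~0.06) is
small against the unit-variance check. All randomness flows from explicit integer seeds; identical
seeds give byte-identical outputs.

## Known limitations

* The trainer fits raw beta-values; covariate adjustment or M-value
  transforms can be applied upstream (the fit is a pluggable step).
* v1 rejects multi-allelic VCF records rather than splitting them.
* No MAF filter is applied to candidate SNPs (inputs are assumed QC'd); the
  GRM silently excludes monomorphic variants only.
* The AI-REML SE is asymptotic; its 2-SE interval is slightly
  anti-conservative at n = 1000 (empirical coverage ≈ 93–95%).
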