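# Methods

## Synthetic study design

The generator produces the three ingredients the analysis needs — a genotype
panel, per-trait base GWAS summary statistics, and a phenotyped target
cohort — from one `SimConfig`. Everything is a pure function of the
configuration and its seed.

**Genotypes.** Variants are partitioned into `n_blocks` contiguous LD blocks
laid out on GRCh37-style coordinates (blocks spread over chr1–22, 5 kb
between neighbours, 1 Mb between blocks so clumping windows never straddle
blocks). Each sample is two haplotypes; a haplotype is a latent Gaussian
chain, restarted at block boundaries, dichotomized at the MAF quantile and
summed to a diploid dosage in {0,1,2}. Dichotomizing a Gaussian attenuates
correlation (a latent AR(1) at ρ would give genotype correlations well below
ρ), so the latent correlation of each adjacent pair is *calibrated* — the
bivariate-normal orthant probability is evaluated through Owen's T and
inverted by vectorized bisection — to make the realized adjacent-genotype
correlation equal `ld_rho`. Because two binary variables with very different
margins cannot be highly correlated, MAFs are drawn per block (uniform on
`maf_range`) with ±15% within-block jitter; the calibration caps unattainable
targets at the latent bound.

**Architecture.** Per-variant causal effects for the K traits are drawn
jointly multivariate normal with covariance `(h2/m) · rg` on the
standardized-genotype scale (an infinitesimal model; `rg` is the requested
genetic-correlation matrix, checked PSD with unit diagonal). The APOE-like
major locus is handled separately: each sample gets two APOE haplotypes with
allele frequencies (e2, e3, e4) = (0.08, 0.77, 0.15); the e4 count replaces
the designated variant's panel column (the middle variant of the last
chr19-analogue block), the e2 count lives only in the sample table, as in
real studies where e2/e4 dosages are a genotyped sidecar. Defaults
`major_locus_effect = 0.5` liability units per e4 allele and
`e2_effect = −0.4 × major_locus_effect` per e2 allele give the familiar
risk/protective asymmetry; tying e2 to the major effect means "no major
locus" cleanly means "no APOE signal at all".

**Base GWAS.** The reported per-SNP estimate is the *marginal* per-allele
effect plus sampling noise: within each block, `β_marg = (R u) / sd_j` with
R the empirical block LD matrix, so neighbours of causal SNPs carry inflated
signal and clumping has realistic leakage to remove. Noise uses the
standardized-trait approximation `se = 1/sqrt(2 · n_base · maf(1−maf))`,
with two-sided Wald p-values. For the binary AD trait this approximation is
accepted because only ranks and thresholds of p enter downstream. The base
GWAS shares the target panel (there is no second genotype cohort); this
overlap is a deliberate simplification of the synthetic study, not of the
method.

**Target cohort.** Liability = polygenic value (trait 1) + APOE shifts +
Gaussian noise scaled so the *polygenic* heritability equals `h2`; cases are
the top `prevalence` fraction of empirical liability. Onset age follows a
Weibull proportional-hazards model (shape 4, baseline median 75 y, clipped
to 40–105 y) whose linear predictor is `hazard_per_sd` (default 0.5) per SD
of the *genetic* liability — the noise component carries no onset
information, so a null-heritability cohort has a null C-index by
construction. A `censor_rate` fraction of cases is censored uniformly before
onset; controls carry an age at last visit drawn N(75, 8²). Defaults
(n = 2000 target samples, m = 5000 variants in 100 blocks, 6 traits,
`rg` off-diagonal 0.25, `n_base` = 50 000, h2 = 0.4, prevalence 0.5,
30% censoring) describe a mid-sized ascertained case-control genotyping
study fed by modern public GWAS.

## Quality control

Filter order is fixed and recorded in `QCReport`s: variant filters
(missingness > 5% → MAF < 0.05 → HWE exact p < 1e-6, each removal attributed
to the first rule that fires) → sample filters (call rate < 99%, then
heterozygosity beyond ±3 SD of the mean, with SD = 0 meaning no outliers) →
a variant call-rate re-pass → relatedness pruning. The cascade is
idempotent.

The HWE test is the exact conditional test (probabilities of heterozygote
counts no more probable than observed, given allele counts), computed by a
mode-anchored recurrence; no mid-p correction, matching common toolchain
defaults. When case/control labels exist it is evaluated in controls only
(configurable), since disease association itself distorts case genotype
frequencies.

Relatedness uses the standardized-genotype moment estimator (GRM
off-diagonal ≈ PI-HAT: 1 for duplicates, 0.5 for parent-offspring) on an
LD-thinned subset. Its sampling SD scales as 1/√m, so on panels of a few
thousand markers a plain 0.125 cutoff would flag thousands of unrelated
pairs by chance; a pair is therefore flagged only when its estimate exceeds
both `kin_max` = 0.125 and a Bonferroni-corrected zero-relatedness detection
bound whose scale is estimated robustly (MAD) from the off-diagonal
distribution. With genome-wide marker counts the bound drops below 0.125
and the filter reduces to the plain threshold. Of a flagged pair, the
member with the lower call rate is removed (ties: the later sample).

Harmonization aligns summary statistics to the panel per shared id: exact
allele match kept; swapped alleles recoded (β and EAF flipped); complement
or swapped-complement strand-flipped (with sign flip when also swapped);
anything else dropped as a mismatch. Summary-statistics hygiene removes
non-SNP alleles, all copies of duplicate ids, strand-ambiguous A/T and C/G
SNPs, and MAF < 0.01 where a frequency column exists (rule skipped and
logged otherwise).

Genotype PCs come from the column-standardized dosage matrix (monomorphic
columns excluded, missing calls mean-imputed), via the n×n Gram matrix when
samples are fewer than variants. Each PC's sign is fixed so its
variant-loading vector has a non-negative sum, making scores reproducible
across linear-algebra backends.

## Scoring and PCA-GRS

Clumping is greedy in ascending p (ties: chromosome, position, id); a SNP
is discarded if it lies within 250 kb of an accepted index SNP with
genotypic r² > 0.1, computed in the target panel itself. Both parameters
are configuration; the defaults follow the common C+T convention. Clumping
runs once per trait.

The threshold indicator is strictly `p < t`. Missing dosages are imputed
with twice the effect-allele frequency of the scored sample set (the
standard `--score` behavior). Threshold SNP sets nest by construction and
scoring is linear over sample concatenation; both properties are tested.

The PCA-GRS is PC1 of the 13 standardized threshold scores. Zero-SD columns
(stringent thresholds admitting no SNP) are excluded from the decomposition
and recorded with zero loading. Eigensolver sign is arbitrary, so PC1 is
oriented to correlate non-negatively with the mean standardized score:
higher PCA-GRS always means higher genetic burden, and negating every input
β negates the score exactly. Only PC1 is retained. When the model is
applied to a test cohort the test columns are standardized with the test
cohort's own moments (per-cohort standardization); a switch transfers
training moments instead, since either convention is defensible and the
choice matters when cohorts differ in scale.

## MetaGRS

The combiner solves the glmnet-form objective
`−loglik/n + λ Σ_j pf_j (α|β_j| + (1−α)/2 β_j²)` with penalty factor 1 on
the standardized trait scores and 0 on the intercept and adjustment
covariates (sex, PC1–PC5, optionally APOE e2/e4 dosages) — the covariates
are controls, not selectable features. The solver is an IRLS + coordinate
descent routine written for this package (per-coefficient penalties and a
CV loop over ~10³ fits need millisecond fits); it is validated in the test
suite against statsmodels' elastic-net GLM on the same objective and
against an unpenalized logistic fit in the tiny-λ limit.

Candidates are every α in {0.1, 0.25, 0.5, 0.75, 1} crossed with a
10-point geometric λ path from just above the smallest λ that zeroes all
trait weights down to 10⁻³ of it, warm-started downwards. Stratified
20-fold CV (seeded, shuffled) scores each candidate by mean validation AUC
of the full linear predictor; ties prefer the larger λ, then the smaller α.
The final weights come from a refit on all training samples at the selected
(α, λ) — the usual glmnet convention.

`MetaGRS_i = Σ_k γ_k · standardized PCA-GRS_ik`: covariates and intercept
are *not* part of the score; they re-enter only in the evaluation
regressions. Test-cohort standardization mirrors the PCA-GRS convention.

## Evaluation

Harrell's C counts pairs in which the shorter time carries an event; ties
in time are excluded, ties in risk count ½. The implementation is the
package's own O(n²) routine, tested against an exhaustive pair oracle, and
is used for every reported C-index (computed on the Cox model's full linear
predictor). Cox fits use Efron tie handling via lifelines (Breslow
available through statsmodels PHReg); scores are standardized inside the
fit so the HR is per SD and invariant to affine rescaling. The logistic
model reports the AUC of fitted probabilities (equal to the normalized
rank-sum statistic) and Nagelkerke pseudo-R² (McFadden via config), the
PRS-literature default.

"Adjusting for age" in a model *of* onset age is ambiguous; the Cox fit
uses a distinct baseline-age column (`age_baseline`) when one exists and
otherwise omits the age covariate rather than conditioning the timescale on
itself. The logistic model uses observed age directly.

APOE-e4 carriers are samples with e4 dosage ≥ 1 (e3e4, e4e4, e2e4);
missing dosages are excluded and counted. The APOE-region exclusion removes
SNPs in a half-open [start, end) window, by default
chr19:44,400,000–46,500,000 (GRCh37), spanning the APOE/TOMM40/APOC1
cluster with flanks; inside the synthetic pipeline the window is centred on
the simulated major locus.

The cohort-summary table reports one Fisher exact p per row, constructed as
the 2×2 genotype-class-vs-rest table of cases vs controls — the only
construction consistent with a single p per row. `fisher_exact_2xk`
enumerates the conditional (multivariate hypergeometric) distribution
exactly, with a seeded Monte-Carlo fallback above an enumeration budget;
for 2×2 it reproduces the classical two-sided Fisher test to 1e-12.

## Numerical choices and problem sizes

Tolerances: oracle equivalences are asserted at 1e-12 (scores, HWE, Fisher,
AUC) or 1e-10 (PCA projections); the coordinate-descent solver iterates to
1e-8 on coefficient steps. Degenerate inputs are contracts, not crashes:
empty panels, single-class outcomes, all-degenerate score columns, no
usable survival pairs and rank-deficient PCA all raise informative errors.

The shipped study conditions (2000 × 5000 × 6 traits) run end-to-end in
about half a minute on one CPU. Statistical checks use sizes chosen for the
statistic being tested: Cox log-hazard recovery with 20 seeds at n = 5000;
elastic-net causal-trait identification with 20 seeds at n = 1000 (a
reduced single-α grid, since only the argmax weight is at issue);
Wald-coverage checks with 200 replicates at n = 1000, where Wald intervals
are well calibrated; LD-calibration and GWAS-χ² checks at n = 5000 and
m = 2000 respectively.

## Limitations

The generator is a statistical stand-in, not a population-genetic
simulator: LD is blocked AR(1)-like rather than a human map, there is no
imputation uncertainty, no X chromosome, a single ancestry (a two-subgroup
option exists only to exercise the PC machinery), and the base GWASs share
the target panel rather than coming from external cohorts. Passing tests
therefore demonstrate correctness of the pipeline's statistics under the
assumed structure, not performance on real AD data — the real training and
validation cohorts of this design are access-controlled, and their headline
hazard ratios and C-indexes are not reproducible from synthetic data. The
cross-trait genetic-correlation magnitude among real GWAS traits is
unknown; the default `rg` = 0.25 off-diagonal is a simulation parameter,
not an estimate.
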