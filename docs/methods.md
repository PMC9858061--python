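# Methods

## The model

`blupgwas` analyses a binarised disease status with a linear mixed model in
which **every SNP is fitted simultaneously** as a random effect:

    y = X β + Z g + ε,     g ~ N(0, I σ_g²),     ε ~ N(0, I σ_ε²)

* `y` — 0/1 disease status after binarisation (see below). The model is
  linear, not logistic: the binary response is treated as a quantitative
  trait, which keeps the all-SNP system linear and solvable at genome scale.
* `X` — fixed effects: intercept, age at sampling (years), sex (M=0, F=1).
* `Z` — raw 0/1/2 alternate-allele dosages, one column per SNP. Columns are
  deliberately **not** centred or standardized (a centring flag exists but
  is off by default).
* Variance components are **fixed, not estimated**: σ_g² = 0.3 σ_y² and
  σ_ε² = 0.7 σ_y², where σ_y² is the unbiased sample variance of `y`.
  The ridge parameter is therefore λ = σ_ε²/σ_g² = 7/3 in the default
  "literal" mode, independent of the data.

Assigning the full 30% genetic share to *each* SNP's prior variance is
unconventional for whole-genome regression, where the per-SNP prior is
normally the total genetic variance divided by 2 Σ_j p_j(1−p_j). Both
conventions are implemented: `variance_mode="literal"` (default) uses
σ_g² = 0.3 σ_y² as stated; `variance_mode="scaled"` divides by the dosage
variance mass 2 Σ p_j(1−p_j). The literal mode makes λ tiny relative to the
diagonal of Z′Z, so shrinkage is mild; the scaled mode shrinks strongly.

Estimates solve Henderson's mixed-model equations

    [ X′X   X′Z      ] [β̂]   [X′y]
    [ Z′X   Z′Z + λI ] [ĝ] = [Z′y]

The coefficient matrix is symmetric positive definite whenever `X` has full
column rank (enforced with a named-column error). Two solvers are provided:

* **direct** — dense Cholesky factorisation; default for ≤ 5,000 SNPs.
* **pcg** — Jacobi-preconditioned conjugate gradients on a matrix-free
  operator (the coefficient matrix is never formed), zero start,
  convergence at relative residual ≤ `tol` (default 1e-8). Intended for
  systems too large to factorise.

Both are verified against an independent dense generalized-ridge oracle
(augmented least squares solved by `numpy.linalg.lstsq`) to relative error
1e-8 on random instances, and against each other to 1e-6.

## Hypothesis testing

Each SNP is tested with the Wald-type statistic

    W_i = ĝ_i / σ_g,      p_i = 2 (1 − Φ(|W_i|))

referred to the standard normal. The denominator is the **prior** standard
deviation of SNP effects, not the standard error of ĝ_i. Because BLUP
shrinks ĝ toward zero while σ_g stays fixed, this statistic is conservative
— under a global null the family-wise error rate measured over 500 simulated
replicates is far below the nominal level. That conservatism is a property
of the method as defined, and is documented rather than corrected.

Multiple testing uses the Bonferroni rule: a SNP is significant when
p < α/m with m the number of tested SNPs and α = 0.05 by default (the
family-wise level is configurable; significance is strict `<`).
p-values are floored at the smallest positive double so −log10 p is always
finite.

## Quality control

Variants pass through four filters in a fixed order, each with strict
(`<`) removal semantics so boundary values survive:

1. multi-allelic records removed (never decomposed into bi-allelic parts);
2. call rate < 0.95;
3. exact Hardy–Weinberg equilibrium p < 1e-4;
4. minor allele frequency < 0.001.

A variant is attributed to the *first* filter it fails and is not evaluated
further (later statistics appear as NaN in the QC report). The HWE test is
the exact conditional test: given the allele counts, heterozygote-count
probabilities are built by a two-term recurrence from the modal count
(numerically safe beyond 10⁵ samples) and all counts at most as probable as
the observed one are summed; a mid-p variant is available behind a flag.
By default HWE uses all retained samples jointly (cases and controls); a
sample mask restricts it to controls if desired. Residual missing genotypes
are mean-imputed per SNP before model fitting (the model needs a complete
`Z`; imputation preserves each SNP's mean dosage).

## Phenotype encoding

The cohort carries five categories: control, resistant, benign, mild,
severe. Two binary contrasts are analysed: *severe* (severe = 1, control
rows removed, all else = 0) and *resistant* (resistant = 1, control rows
removed, all else = 0). Sex is coded M=0/F=1 — the reference level is
arbitrary and only flips the sign of the sex effect. Missing age or sex is
a hard error by default; an opt-in flag mean-imputes instead.

## Single-SNP baseline

The comparison scan fits, per SNP, OLS of `y` on (intercept, age, sex,
dosage) and tests the dosage coefficient two-sided against Student's t with
n−4 degrees of freedom (t rather than normal: negligible at cohort size,
correct at small n). The implementation residualises `y` and all dosage
columns on the covariates once (Frisch–Waugh–Lovell) and so is vectorised
over SNPs; it reproduces textbook OLS coefficient/SE/p to 1e-8
(cross-checked against statsmodels in the test suite). SNPs collinear with
the covariates — monomorphic columns in particular — are flagged degenerate
with p = 1. The baseline is linear, like the multi-SNP model, to keep the
multi-vs-single comparison like-for-like.

## Synthetic cohorts

The generator produces data with the structure the analysis assumes, not a
coalescent-accurate population:

* **Genotypes.** SNPs are laid out in LD blocks (default 10 SNPs per
  block). Each haplotype's alleles within a block come from a latent
  equicorrelated Gaussian thresholded at the SNP's allele-frequency
  quantile; two independent haplotypes sum to the dosage. The latent
  correlation is calibrated (bivariate-normal orthant probability, Brent
  root-finding) so the realised *dosage* correlation matches the configured
  `within_block_r` (default 0.5 — moderate LD; real WGS data has longer and
  stronger LD). Blocks are independent; allele frequencies are uniform on
  `maf_range` (default 0.05–0.5, common variants). Blocks are laid
  contiguously across up to 22 chromosomes.
* **Phenotype.** A liability-threshold model: liability = scaled sum of
  standardized causal dosages + Gaussian noise, with the genetic share of
  liability variance equal to `heritability` (empirically rescaled, so
  regression of liability on the true score recovers h² up to sampling
  error). Causal effects are N(0, sd) by default, or equal-magnitude
  random-sign (`causal_effect_dist="equal"`) for large-effect oligogenic
  scenarios. Samples are ranked by liability and cut into the five
  categories at exact counts given by `category_proportions`, ordered
  resistant < control < benign < mild < severe. The default proportions
  yield exactly 306 resistant and 235 severe in a cohort of 1,076, matching
  the cohort structure the pipeline targets; the control/benign/mild split
  (161/216/158) is a free choice, as those group sizes are not pinned down
  externally.
* **Covariates.** Age uniform integer on 18–85, sex Bernoulli(1/2), both
  independent of liability by default; `age_liability_coef` can introduce
  age confounding for robustness experiments. Missingness is off by
  default; `missing_rate` masks genotypes completely at random for QC
  exercises.

What the generator does **not** emulate: population structure, relatedness,
rare-variant site-frequency spectra, genotyping error that correlates with
allele frequency, and realistic genome-scale LD decay. Tests that pass on
this generator therefore validate the *statistical machinery* — solver
accuracy, error control, ranking behaviour under the stated model — not
robustness to confounding or stratification in real cohorts.

## Verification scenarios and problem sizes

The package's end-to-end checks use simulation sizes chosen to make each
property measurable with tight Monte-Carlo error while remaining quick on a
single core:

* solver-oracle equivalence: 100 random instances, n ≤ 200, up to 500 SNPs;
* exact-HWE enumeration: every genotype table with ≤ 50 samples (23,426
  configurations), agreement to 1e-12;
* null family-wise error: 500 replicates of n=300, 1,000 SNPs, h²=0;
* causal-signal ranking: 50 replicates of n=1,076 (the default cohort
  size), 2,000 independent SNPs, 10 equal-magnitude causal SNPs at liability
  h²=0.5, severe contrast. Independent SNPs are used deliberately: under
  within-block LD a causal SNP's rank mass is shared with its correlated
  block-mates (a tagging neighbour may out-rank it), which is expected
  behaviour of a joint model rather than a ranking failure, and the
  multi-vs-single LD comparison is exercised separately;
* baseline calibration: 10,000 null SNPs, Kolmogorov–Smirnov distance to
  uniform;
* determinism: the default synthetic cohort (n=1,076, 5,000 SNPs) run end
  to end twice, association tables compared byte-for-byte.

## Numerical choices

* Dosages are `float64`; missing is NaN.
* Category counts use cumulative rounding of proportions, so proportions
  that are exact k/n fractions produce exactly k samples.
* HWE probability ties are matched with a 1e-10 relative tolerance when
  accumulating the two-sided tail.
* PCG uses a zero start vector and Jacobi (diagonal) preconditioning;
  iteration count and achieved relative residual are reported in the fit.
* Association tables are written with `%.10g` floats and sorted by
  (chrom, pos); rank ties in `rank_hits` break by (chrom, pos) with a
  stable sort. Reruns with the same configuration are byte-identical.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; genotype, phenotype and missingness draws use
  distinct derived streams so toggling one does not perturb the others.

## Known limitations

* Fixed variance components mean no uncertainty in λ is propagated; the
  Wald statistic's conservatism grows with shrinkage (scaled mode).
* The linear model for a binary response ignores variance heterogeneity;
  effect sizes are on the risk-difference scale.
* The QC stage assumes bi-allelic SNPs and does no sample-level QC,
  strand harmonisation or indel handling.
* `read_vcf` materialises the full dosage matrix in memory; genome-scale
  inputs need chunking upstream.
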