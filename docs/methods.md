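# Methods

## The design

The proxy GxE MR design estimates the causal effect of maternal smoking
heaviness in pregnancy on a binary offspring outcome when only offspring
genotypes are available. Offspring dosage G_o at a smoking-heaviness locus
proxies the maternal dosage G_m (corr(G_m, G_o) = 1/2 under random mating),
and the sample is stratified on maternal smoking during pregnancy:

* in the **exposed** stratum the instrument can act through maternal
  heaviness, so the Wald ratio estimates causal effect plus any pleiotropy;
* in the **unexposed** stratum the heaviness path is closed, so the Wald
  ratio estimates pleiotropy alone;
* the **corrected** estimate is their difference.

Identification assumes (i) no assortative mating, (ii) no paternal pathway,
(iii) equal pleiotropic effects in both strata, and (iv) no
genotype–initiation path: if the instrument also affects *whether* the
mother smoked, stratifying on smoking status conditions on a collider and
the correction no longer removes the bias. The generator can violate each
assumption on purpose (`spousal_corr`, `pleiotropy_beta`,
`init_per_allele`), which is how the collider demonstrations work.

## The generative model

For each of `n_pairs` mother–father–offspring trios, per SNP j with
effect-allele frequency p_j:

* parental haplotypes: independent Bernoulli(p_j) alleles (HWE). With
  `spousal_corr = s`, each paternal allele copies the corresponding
  maternal allele with probability s, giving spousal dosage correlation s
  and raising the proxy R² ratio from 1/4 to (1+s)²/(2(2+s));
* transmission: one allele sampled uniformly from each parent per SNP;
  transmitted alleles are retained so Mendelian consistency is checkable;
* smoking initiation:
  `P(smoked) = expit(logit(init_base) + init_per_allele · Σ_j G_mj +
  conf_on_init · U)` with U ~ N(0, confounder_sd²) a latent confounder.
  `init_per_allele` is a per-allele log-odds (the initiation/termination
  collider path); 0 disables it;
* heaviness among smokers:
  `cigs/day = exposure_mean + Σ_j w_j G_mj + N(0, exposure_sd)`, truncated
  at zero; undefined (missing) for non-smokers. The baseline
  `exposure_mean` (default 13 cigarettes/day, a typical heaviness among
  smoking mothers of the study era) is needed so truncation is a negligible
  tail event and the exposure SD is realistic;
* handedness:
  `P(left) = expit(outcome_base_logit + causal_beta · cigs · smoked +
  pleiotropy_beta · Σ_j G_oj + conf_on_outcome · U)`. The causal path acts
  only through cigarettes actually smoked (no preconception/postnatal
  pathway); the pleiotropic path acts through the offspring genome
  regardless of maternal smoking;
* birthweight: `bw_base + bw_theta · cigs · smoked + conf_on_birthweight ·
  U + N(0, bw_sd)`, clipped at 0.2 kg (never binds at realistic values);
* covariates (sex, multiple birth, breastfed, birth year/month, country,
  Townsend z-score) are drawn from UK-Biobank-like marginals — 54.5%
  female, 2.25% multiple births, 71.2% breastfed, birth years uniform
  1937–1965 (mean 1951), country probabilities led by England at 84.2%,
  mean birthweight 3.33 kg — independent of genotype, so they serve as
  negative controls.

Default anchor values: 30.6% smoking mothers, 9.82% left-handed baseline,
effect-allele frequency 0.33, and a single-SNP heaviness effect sized by
`weight_for_r2` to a chosen variance fraction (0.4% reproduces the
rs16969968-scale signal; 0.5% the PRS-scale one). These defaults are the
study conditions, not tuning knobs.

A single standard-normal latent U stands in for all confounders; multiple
confounders are represented by rescaling its path coefficients.

## Estimation

Associations are maximum-likelihood fits via statsmodels (Logit/OLS) with
Wald 95% CIs and two-sided Wald p-values, complete cases only. The Wald
denominator regresses cigarettes/day on the instrument among smoking
mothers in the whole sample and is shared by both strata; with the
offspring proxy both numerator and denominator attenuate by the same
factor 1/2, so the ratio remains consistent for the per-cigarette effect.
Numerator–denominator covariance is ignored in the delta method (different
outcome on overlapping rows; a first-order approximation), and the two
strata are treated as independent for the corrected SE (disjoint
individuals). A first-stage |t| < 3.16 (an F < 10 equivalent) raises a
weak-instrument warning.

Clumping is the standard greedy procedure: sort candidates with p ≤ p_thresh
by ascending p (ties broken by chromosome, position, SNP id, making output
order-invariant), take the best as index, absorb same-chromosome SNPs
within the window (|Δpos| ≤ window_kb·1000, inclusive) whose dosage r²
with the index exceeds r2_thresh, repeat. r² is the squared Pearson
correlation on the supplied panel, so values are panel-dependent.
Zero-variance SNPs are skipped with a warning. Harmonization flips the
beta when the panel counts the other allele and drops strand-ambiguous
(A/T, C/G) or mismatched records with a reason, never fatally. Scores are
Σ w_j · dosage_ij with column-mean imputation of missing dosages; an
unweighted allele count is available behind a flag.

Month of birth enters the observational models as
`cos(pi (m − 6.5) / 3)` — a 6-month period peaking in UK summer and winter
and dipping in spring and autumn. This phase/amplitude is a convention
satisfying the seasonal pattern, not a canonical formula. Townsend scores
are z-scored; country is dummy-coded against England (the modal category);
genetic principal components are accepted as precomputed columns.

## Simulation studies and problem sizes

Power, bias and coverage come from `powersim.run_scenario`: per effect
size (an odds ratio per SD of cigarettes/day, converted to per-cigarette
log-odds with the scenario's analytic exposure SD
`sqrt(Σ w_j² 2p_j(1−p_j) + exposure_sd²)`; truncation ignored), each
replicate simulates a cohort, runs the full pipeline and records rejection
at level alpha, the estimate and CI coverage of the truth. Replicate seeds
derive from the scenario's master seed; failed replicates are counted, not
fatal.

Default desk-scale sizes, chosen so the Monte-Carlo error bands are
informative: 200–500 replicates at n = 20,000 pairs for calibration
studies, 200,000 pairs for single-run demonstrations (attenuation,
collider tables). Full cohort-scale runs (n ≈ 347,000) are configuration
changes, not code changes.

Calibration scenarios (`desk_calibration_params`) use a PRS-like
instrument explaining 2% of maternal heaviness rather than the single-SNP
0.4%. The estimator's sampling distribution depends on instrument strength
through the first-stage F: the full-size cohort sits at F ≈ 90 where the
delta-method normal approximation is accurate, and a 20,000-pair run with
the single-SNP R² would drop F below 10, where *any* ratio estimator is
non-normal. Scaling R² to restore F ≈ 30 preserves the regime being
studied; the weak-instrument regime is deliberately out of the calibration
scope and is flagged at run time instead.

## What the generator does and does not emulate

It reproduces the statistical skeleton the design relies on: HWE,
Mendelian transmission and the 1/4 proxy-attenuation ratio, a minority
exposed stratum, realistic left-handedness prevalence and exposure
variance fractions, pleiotropic and collider paths, and a negative
birthweight control. It does **not** model LD beyond block-copy structure
for clumping tests, imputation uncertainty (hard calls only), the X
chromosome, population stratification, relatedness, self-report
misclassification of maternal smoking, or secular trends in any covariate.
Passing tests therefore show the estimator behaves as designed under its
own assumptions — not that those assumptions hold in any real cohort.

## Numerical choices and degenerate inputs

Normal quantile 1.959964 for all 95% intervals; logistic fits flag
separation/non-convergence on the result instead of failing silently; rank
deficiency raises an error naming the collinear terms; constant variables
give explicit "undefined measure" results; an empty stratum or an empty
complete-case set raises immediately; `n_pairs = 0` yields a valid empty
cohort with intact schema. All randomness flows from
`numpy.random.default_rng(seed)`; identical (params, seed) gives
bit-identical cohorts, and pipeline runs write a manifest (config hash,
seed, versions, per-stage row counts) sufficient to reproduce them.

## Known limitations

The corrected estimator assumes equal pleiotropy across strata and no
genotype–initiation path; when the latter exists the collider bias is
demonstrated but not corrected (no correction exists within this design).
The delta-method SE is anti-conservative at weak instrument strength.
Two-sample summary-statistic estimators (IVW, Egger, weighted median),
within-family MR and mixed-model association are out of scope.
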