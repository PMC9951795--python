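# Methods

This note documents the models, numerical choices and limitations of the
`metagrs` package: what each stage assumes, which knobs matter, and what the
synthetic cohorts do and do not emulate.

## Synthetic cohorts

**Genotypes.** Variants are partitioned into contiguous LD blocks. Each
block carries a latent Gaussian chain; two independent haplotype draws are
thresholded at the allele-frequency quantile and summed to a dosage in
{0, 1, 2}. Thresholding a Gaussian attenuates correlation (the tetrachoric
effect), so the adjacent latent correlations are *calibrated* by bisection
on the bivariate normal CDF until the realized dosage correlation matches
the requested within-block level; the latent profile then only approximates
AR(1). Variants within a block share a base minor-allele frequency (drawn
uniformly from `maf_range`, default 0.05–0.5) with ±0.02 jitter — without
near-equal frequencies, high dosage correlations are unattainable under any
copula. `within_block_r` accepts one value per block; heterogeneous LD
levels matter because LD-score regression is identified by variation in
ℓ_j. A `Population` object (variants, frequencies, latent structure) can be
reused so that training, GWAS and validation cohorts are draws from one
population — allele labels and frequencies stay consistent across cohorts.
Missing dosages are injected completely at random (`missing_rate`), which is
all the scoring missing-policy needs.

**Architecture.** A `causal_fraction` subset of variants (shared across
traits) receives effects drawn jointly multivariate normal so the
cross-trait effect correlation equals the requested genetic-correlation
matrix `rg`; each trait's column is rescaled so its sum of squared
standardized effects equals h² exactly. Phenotypes are genetic value plus
normal noise to unit variance; with LD the realized variance of the genetic
value can exceed h² slightly (effects are not orthogonalized against R), so
heritability-recovery checks use LD-free panels.

**Disease and onset.** Case status is liability-threshold: the disease
trait's liability exceeding Φ⁻¹(1−K), prevalence K = 0.05 by default. Cases
split ASAH : unruptured IA at 0.6 : 0.4 (a population-cohort-like mix, not
calibrated); an optional `uia_detection_prob` reclassifies undetected UIA
cases as controls, reflecting that unruptured aneurysms are usually
incidental findings. ASAH cases draw age at onset from an exponential
(constant-baseline-hazard) model with log-hazard
`onset_log_hazard_per_sd` × standardized genetic liability (default 0.3),
shifted to start at age 18 with baseline rate 1/45 per year and truncated
below 100; controls and UIA cases get an assessment age ~ Uniform(40, 80).
Any proportional-hazards-consistent generator suffices for validating the
Cox stage; the exponential form is the simplest such choice. Systolic blood
pressure and smoking are generated with configurable correlation to the
genetic liability (defaults 0.2 and 0.15), giving the clinical model
genuine but partial overlap with the score.

**Patient characteristics.** The IA-patient table generates binary
characteristics from logistic models with a specified log-odds per SD of the
(internally standardized) score, grouped IA location from a multinomial
logit with per-location score effects, and age at ASAH as a linear shift in
years per SD (baseline 52 ± 12 years, ruptured patients only). Cohort
membership can be made score-dependent (`cohort_score_assortment`) while
cohort offsets shift characteristics, creating exactly the confounding that
the cohort covariate in the association models must absorb. A
`smoking_mediates` term routes an age effect through smoking for mediation
tests.

## Summary statistics

The association scan regresses phenotype on dosage per variant (OLS for
quantitative traits, per-variant Newton logistic for binary), with
per-variant exclusion of samples missing that dosage; p-values are
two-sided normal on β̂/SE. When covariates are supplied, phenotype and
dosages are residualized on them once; with missingness this is approximate
(exact per-variant refitting would be O(n·m·k²)), adequate at MCAR rates
below ~10%. Stratum meta-analysis is fixed-effect inverse-variance:
β = Σβ_i/SE_i² / Σ1/SE_i², with variants present in only some strata
combined over the strata that carry them; the leave-one-stratum-out variant
simply excludes one table. Harmonization aligns allele pairs to a reference
by direct match, effect/other swap (sign flip, EAF complement), strand
complement, or both; palindromic A/T and C/G variants are dropped by
default because strand cannot be verified without frequency matching; a
report counts every drop reason.

## LD-score regression

LD scores use the small-sample-adjusted estimator
ℓ_j = Σ_k [r²_jk − (1 − r²_jk)/(n − 2)] over a ±`window_variants` positional
window (k = j included, contributing exactly 1). Heritability is the slope
of χ²_j on N·ℓ_j/M with a free intercept, weighted by 1/ℓ_j; genetic
covariance is the slope of z_a·z_b on √(N_a N_b)·ℓ_j/M, with sample overlap
absorbed by the free intercept; rg = cov_g/√(h²_a h²_b). Standard errors
come from a delete-one block jackknife over contiguous variant blocks
(default 20 at desk scale). At a few thousand variants the estimator is
noisy; a trait whose h² estimate is non-positive has undefined rg and is
treated as not correlated (excluded) rather than aborting the pipeline. The
P < 0.05 inclusion filter is two-sided.

## Trait-level scores

Clumping breaks ties on smaller p then lexicographic id, and asserts no
retained pair within a block has r² at or above the threshold. The default
grid of nine r² thresholds is {0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.4,
0.6, 0.8}, configurable. SBLUP and SBayesR operate blockwise on the
standardized scale (no cross-block LD) and convert weights back to dosage
units via √(2f(1−f)) when the input effects are per-dosage. SBayesR uses
the four-component mixture γ = (0, 0.01, 0.1, 1) with initial
π = (0.95, 0.02, 0.02, 0.01), σ²_e fixed at 1, π resampled from a Dirichlet
over component counts and σ²_β from its scaled inverse-χ² conditional
(ν₀ = 4, s₀² = 0.01) each sweep; both updates can be frozen, which makes
the single-variant posterior available in closed form for verification.
A divergence guard aborts if any sampled effect exceeds 10 on the
standardized scale. Defaults of 600 sweeps / 150 burn-in are desk-scale
conventions for this sampler family, not tuned values; the end-to-end
studies use 200 / 60 to keep a 10-replicate run in minutes.

Scoring matches variants by id, flips dosage (d → 2−d) when the weight
file's effect allele is the cohort's other allele, and handles missing
dosages by mean imputation with 2·EAF (cohort empirical frequency; default)
or by restricting to observed entries and rescaling by total/observed
weight count.

## The metaGRS model

Candidate selection maximizes Nagelkerke pseudo-R²
(R²_CS/(1 − exp(2ℓ₀/n)), computed without covariates by default; a
covariate option exists), with ties broken by fewer variants then method
order clump < sblup < sbayesr. The elastic net is penalized logistic
regression (scikit-learn saga solver) at l1_ratio 0.5, 5-fold stratified
CV over a 20-point log-spaced penalty grid, selecting the strongest penalty
within one standard error of the minimum CV deviance (the glmnet
convention) — the one-SE rule is what keeps the all-noise panel reliably at
the null model. Score standard deviations s_t are computed on the full
training population (cases + controls). "Traits with an effect" means a
nonzero coefficient at the selected penalty; if every coefficient is zero
the model falls back to the disease's own score. Sex-stratified fits simply
restrict the training samples. The combined weight w_j = Σ_t (γ_t/s_t)
w_{t,j} is recomputable from the stored parts to 1e−12, and complete-data
scores are exactly linear in the constituent trait scores.

## Validation statistics

Cox models use lifelines (Efron tie handling); the score column is
standardized so hazard ratios read per SD; age is never a Cox covariate
(it is the time axis). Logistic models for IA presence include age;
SBP and smoking enter both endpoints as 3-knot restricted cubic splines
with knots at the 0.1/0.5/0.9 quantiles (linear beyond the boundary knots,
basis normalized by (t_k − t_1)²). Harrell's C counts pairs (i, j) with
time_i < time_j and event_i = 1; its CI is a seeded bootstrap (default 200
replicates; `n_boot=0` skips the CI, used inside replicated studies). AUC
is the Mann–Whitney estimate with DeLong structural-components variance;
the paired DeLong test compares correlated AUCs. NRI/IDI for survival use
inverse-probability-of-censoring weights at horizon t₀ (default the 90th
percentile of follow-up; the censoring distribution from a Kaplan–Meier
fit), category-free definitions, and inference by exponential-weight
perturbation resampling (default 300 replicates); with no censoring before
t₀ both reduce exactly to the binary closed forms. Absolute risks at t₀ for
the NRI/IDI comparisons come from a Breslow baseline hazard. Separation in
logistic fits falls back to a small ridge penalty and is flagged.

## Patient-characteristic associations

Continuous characteristics (age at ASAH, size at rupture) are modelled as
characteristic ~ score + covariates, so effects read in natural units per
SD of score; binary characteristics use logistic regression (log-OR per
SD). This "characteristic-on-score for continuous" direction is a design
choice — the per-year β direction (score ~ age) is obtainable by swapping
arguments, and the years-earlier computation uses the per-SD form. Location
associations are one-versus-rest per grouped location (ICA including
ophthalmic and cavernous; posterior communicating; anterior cerebral
including A1, anterior communicating and A2; middle cerebral; posterior
circulation/vertebrobasilar), restricted to single-IA patients, with
`other` locations excluded. Sex and cohort are default covariates (sex
dropped when it is the outcome); the multivariate adjustment adds smoking
and hypertension. Bonferroni control uses 0.05/11 for the eleven primary
phenotypes; p-values between the corrected and nominal thresholds are
labelled `nominal`. The score is re-standardized within each analysis set,
making every association invariant to affine rescaling of the raw score.

## Problem sizes and reproducibility

The bundled studies run at desk scale by design: end-to-end replicates use
400 variants in 40 blocks, 5 000–6 000 samples per cohort and 10 seeds;
genetic-correlation recovery uses 2 000 variants and 5 000 samples;
coverage checks use 100 seeds of cheap univariate fits. Every stochastic
component takes an explicit seed, and identical configuration plus seeds
reproduces byte-identical weight files. Because the synthetic architecture
concentrates heritability in hundreds of variants rather than millions,
absolute effect sizes (validation HR ≈ 2–3 per SD, C-index gains of ~0.2)
are far larger than real-cohort values; the studies therefore check
directions, orderings, coverage and calibration — not magnitudes. Passing
tests show the estimators are correct under the generators' assumptions
(hard-call genotypes, blockwise LD, MCAR missingness, proportional
hazards, no population structure or relatedness); they do not certify
performance on real biobank data.
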