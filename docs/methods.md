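# Methods

## Problem and design

Reproductive traits (age at menarche, parity, age at natural menopause)
are hypothesised to shape the adult metabolic profile. No single
observational method identifies these effects: regression is exposed to
confounding, MR to pleiotropy and weak instruments, and any analysis of
menopause age to selection (the trait is only observed in women who have
completed a natural menopause). The package therefore implements a
triangulation: multivariable regression, a male negative control for
parity, and one- and two-sample MR, with the expectation that agreement
across methods with different bias structures strengthens causal
inference — and that disagreement is itself informative and should be
traced to a mechanism (here: chronological-age effect modification plus
sample selection).

All analyses express effects in SD units of the
rank-inverse-normal-transformed metabolite per exposure unit (years or
children), so the arms are directly comparable.

## Synthetic cohort generator

The generator is first-class code: it encodes the study conditions, and
every downstream claim is tested against it.

**Covariates.** Baseline age ~ truncated normal (mean 56.4, SD 8, range
38–73); education (4 levels), childhood body size (thinner/average/
plumper), smoking and alcohol are categorical draws with realistic
marginal frequencies. Confounder effects act through the standardized
scores of the *observed* categories, so the model-2 adjustment set can
block them exactly; residual confounding from latent-vs-observed
discrepancies, present in real data, is deliberately absent (see
Limitations).

**Genotypes and exposures.** Each exposure gets an independent block of
Hardy–Weinberg SNPs (MAF uniform on (0.05, 0.45)), equal per-allele
effects scaled so the score explains a configured R² — defaults 7.4%
(menarche), 0.2% (parity), 8.2% (menopause) of phenotypic variance.
Exposures are genetic score + confounder contributions + Gaussian noise
on their natural scales (menarche 13.0 ± 1.6 y; parity latent 1.83 ± 1.4
rounded and clipped to counts; menopause 49.7 ± 5.1 y).

**Menarche–adiposity structure.** Childhood body size lowers menarche age
and raises adult BMI; menarche age additionally shifts adult BMI (−0.5
kg/m² per year), and BMI shifts the lipid-related metabolites. The bulk
of the default menarche→metabolite signature is therefore BMI-mediated,
and adjusting for BMI (regression model 3, or multivariable IVW with BMI
as co-exposure) attenuates it — the attenuation signature. Direct
(BMI-independent) menarche effects are kept for glutamine and glycine.

**Metabolite panel.** 40 metabolites driven by 18 latent factors. The
loading matrix is an equal-norm harmonic tight frame: every metabolite
has factor-variance share 0.97 and the 18 population factor eigenvalues
are equal, so correlation-matrix PCA needs exactly 18 components to reach
95% of variance (17 give ~92.9%). This is a deliberate construction: the
variance decomposition of real NMR panels beyond "18 components, ≥95%"
is not pinned down, so the generator realises the simplest structure
consistent with that count.

**Menopause observation model.** A latent menopause-timing liability
exists for every woman and drives metabolites in everyone (this is what
full-sample MR estimates). Observed menopause age equals the liability
only for women with status "natural". The premenopausal stratum (24.5%)
is assigned to the women with the lowest age-plus-noise score (noise SD 5
years), tying missingness to younger age; surgical menopause (12%) is
assigned at random among the rest. Status assignment is independent of
the liability itself — a simplification (in reality a 45-year-old cannot
report a menopause at 50).

**Age modification.** The menopause→LDL_C effect per year is
`base + slope × (age − 56.4)` with base −0.0085 and slope 0.0012 SD/year
per year of age. These two numbers are calibrated so the stratum effects
are ≈ −0.019 SD/year at ages ≤50 and ≈ +0.005 SD/year above 63, the
pattern the age-stratified analysis is designed to recover, and they also
generate the selected-vs-full discrepancy: the selected (natural
menopause) sample skews old, so its average effect sits above the
full-sample average.

**Males.** Males share the confounder and BMI machinery and receive a
children count from the same structural equation as female parity, but no
causal path from children count to their metabolites — the negative
control's premise.

**Pleiotropy.** A configurable fraction of each exposure's SNPs can carry
direct SNP→metabolite effects, balanced (mean 0) or directional.

## Transformation

Rank-based inverse normal transformation with the Blom offset 3/8
(exposed as a parameter): value with tie-averaged rank r among n maps to
Φ⁻¹((r − 3/8)/(n + 1/4)). Missing entries stay missing; the transform is
computed on observed values only, matching complete-case analysis
downstream. The transform is invariant to monotone re-expressions of the
input and idempotent.

## Regression stage

Model 1 is unadjusted; model 2 adjusts education, baseline age and
childhood body size (the preferred causal model — these precede the
exposures); model 3 adds baseline BMI, smoking and alcohol, which may be
mediators, so model-2→model-3 attenuation is read as mediation rather
than confounding removal. Complete-case rows per
exposure/outcome/model triple; categorical covariates enter as indicator
contrasts; CIs use the normal 1.96 multiplier (all intended n are large).
Collinear designs raise an error naming the offending columns.

Categorisation uses the study cut-points (menarche <13 / 13–14 / >14
years; menopause <49 / 49–50 / 51–53 / >53; parity 0/1/2/3+). The
non-linearity test compares category indicators against a single
linear-in-scores term by Gaussian likelihood ratio on k−2 df; scores are
the integer category codes (recorded in the output, since median-based
scores are an equally defensible choice). Restricted cubic splines use
the truncated-power natural-spline basis with knots at Harrell's
percentiles (3 knots: 10/50/90; 4: 5/35/65/95; 5: 5/27.5/50/72.5/95); the
basis is linear beyond the boundary knots by construction, and the fit
reports AIC/BIC/RMSE alongside the linear comparator plus an LRT p-value
for the non-linear terms.

A note on parsimony checks: under an exactly linear truth, AIC prefers
the linear model with probability P(χ²_{k−2} < 2(k−2)) — 84.3% for 3
knots, not more — because AIC's penalty of 2 per parameter is not a test
at conventional levels. BIC, whose penalty grows with log n, prefers the
linear model essentially always at these sample sizes. The test suite
asserts the exact chi-square rate for AIC and the parsimony property for
BIC.

## Negative control

Children-count associations are fitted separately by sex with identical
covariate sets. A metabolite is classified **bias-suggestive** when the
sexes agree in direction with overlapping 95% CIs, **causal-suggestive**
when the female association passes the threshold while the male one is
null or oppositely signed, and **inconclusive** otherwise; a z-test for
the female−male difference is reported alongside so users can apply a
quantitative rule instead. The classification is meaningful only for
associations the adjustment has *not* removed: the packaged study runs
model 1 so that the education-driven confounding remains visible to the
control. A metabolite carrying both a real female effect and a strong
shared confounded association is correctly inconclusive — the design
cannot separate the two for the same outcome — so the study generator
routes confounding and causal effects to different metabolites.

## Mendelian randomization

**Harmonization** aligns outcome effects to the exposure's effect allele,
recognising direct and strand-complement label matches; palindromic SNPs
are oriented by allele-frequency concordance only when both EAFs are
outside 0.5 ± 0.08 and dropped otherwise; irreconcilable alleles are
dropped. Every drop and flip is logged.

**Estimators.** IVW is weighted least squares through the origin; the
default SE is multiplicative random effects, i.e. the fixed-effect SE
scaled by √max(1, Q/(k−1)) — conservative under heterogeneity, identical
to fixed-effect when Q ≤ k−1. MR-Egger orients all exposure effects
positive, fits a free intercept, and applies the same dispersion rule on
k−2 df. The weighted median orders per-SNP ratios, interpolates the
weighted CDF at 0.5 (midpoint convention), and takes its SE from a seeded
parametric bootstrap that resamples the per-SNP estimates from their
standard errors with weights held at observed values. Multivariable IVW
regresses outcome effects on two exposure-effect columns without
intercept; an identically-zero column reduces it to univariable IVW, and
collinear non-zero columns are an error. Instrument strength uses
R²ⱼ = 2pⱼ(1−pⱼ)βⱼ²/Var(X) and Fⱼ = R²ⱼ(nⱼ−2)/(1−R²ⱼ); these formulas are
a package choice (the convention is not universal) and the trait variance
is an explicit argument.

**Calibration studies.** Replicated two-sample datasets share a
heavy-tailed (lognormal) per-SNP effect-size architecture, as in real
instrument sets where a few loci dominate. Coverage is assessed in
summary mode — estimates drawn from the exact large-sample sampling
distributions implied by n = 50,000 per sample — because that is the
model whose 95% intervals the estimators promise; on individual-level
data the formula SEs are mildly conservative (shared-sample correlations
across SNPs shrink the true sampling variance), which the individual mode
exposes. The robustness study uses individual-level data with 40% of
SNPs carrying directional pleiotropy whose ratio offsets are ~3–4× the
causal effect ("large"): the weighted median stays within 3 of its SEs of
the truth and is closer to the truth than IVW in the large majority of
replicates, while the IVW interval excludes the truth. This scenario sits
near the median's 50%-weight breakdown point by design; with still larger
contamination weight the median's finite-sample bias (the weighted ~83rd
percentile of the valid ratio cloud) grows in proportion to per-SNP ratio
noise, a property of the estimator, not of the implementation.

**One-sample MR.** The PGS is a weighted allele-count score with
harmonization-style allele resolution; 2SLS uses the standard IV variance
formula with residuals from the observed exposure (homoskedastic version;
robust/clustered variants are out of scope) and reports the first-stage
partial F, warning below 10. The PGS-ratio estimator divides
covariate-adjusted PGS–outcome by PGS–exposure coefficients (two-term
delta SE, coefficients treated as independent) and accepts different
samples for numerator and denominator — on identical samples and
covariates it equals 2SLS exactly (Frisch–Waugh), which is tested. The
"genotyping array and 40 ancestry PCs" of a real analysis are represented
by generic covariate columns; the count is configurable.

## Multiplicity

Correlation-matrix PCA on the transformed panel (complete rows by
default; pairwise-complete behind a flag with a warning when eigenvalues
go negative). The effective test count is the smallest m whose top-m
eigenvalues reach 95% of the trace; the threshold is 0.05/(3 × m). On the
default panel m = 18, giving 54 tests and 0.05/54 ≈ 0.00093.

## Triangulation report

Per exposure–metabolite pair, estimates are classified **concordant**
(all CIs overlap, signs agree), **discordant** (sign conflict with
disjoint CIs), **mr-uninformative** (MR CI wider than 5× the regression
CI — the parity situation, where instruments explain 0.2% of variance),
else **partial**. The 5× multiple and the threshold α are explicit
configuration, and raw estimates are always emitted so the classification
is auditable.

## Problem sizes

The packaged studies use: coverage 500 replicates at n = 50,000 and 100
SNPs; robustness 200 replicates at the same sizes; attenuation 100 seeds
at n = 50,000 females; negative control 100 seeds at 5,000 per sex;
menopause signature n = 120,000 females (3–5 seeds); instrument-strength
recovery at the GWAS-scale sample sizes (329,345 / 496,000 / 496,151)
simulated at the summary level, where they cost nothing. All randomness
flows from explicit seeds through `numpy` `SeedSequence` spawning.

## What passing tests do and do not show

The generator realises the assumed causal structure exactly: confounders
act through observed covariates, instruments are independent SNPs with no
linkage disequilibrium, pleiotropy is injected only where configured, and
metabolite correlation follows an exact factor model. Passing tests
therefore demonstrate that the estimators and the pipeline recover truth
*under their assumptions* and reproduce the designed bias patterns — not
that real cohort data satisfy those assumptions. In particular: residual
confounding via mismeasured covariates, LD between instruments,
population stratification, assortative mating, non-MCAR missingness
within strata, and heteroskedastic or clustered errors are all absent by
construction.

## Known limitations

- Per-SNP associations use ordinary least squares, not mixed models; no
  relatedness or array structure is simulated.
- The weighted-median bootstrap SE is mildly conservative on
  individual-level data (see calibration notes).
- The parity count is a rounded, clipped Gaussian latent; its genetic R²
  on the count scale is attenuated by a few percent relative to the
  configured latent R².
- Selection into the premenopausal/surgical strata ignores the logical
  constraint between current age and reportable menopause age.
- `statin_flag`/`hrt_flag` are independent Bernoulli draws: the
  medication-exclusion filters are exercised, but medication-induced
  collider or treatment effects are not modelled.
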