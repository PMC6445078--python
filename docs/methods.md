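# Methods

## Scope and shape

The package implements a one-sample Mendelian-randomization analysis of the
effect of HbA1c (%) on serum lipids, with a weighted genetic risk score (GRS)
as the instrument and a summary-statistic sensitivity suite, plus a seeded
synthetic cohort generator that reproduces the statistical structure the
analysis assumes. Score construction and the summary-statistic estimators are
presented as sklearn-style estimators (`fit` + trailing-underscore
attributes, `get_params`/`set_params`); the module-level functions documented
below are thin wrappers over them.

## Synthetic cohort generator

Genotypes are drawn independently per SNP from Hardy-Weinberg proportions
(q², 2pq, p² for risk-allele dosage 0/1/2). A per-SNP distortion coefficient
`f` implements an inbreeding-style departure: heterozygote probability
2pq(1−f), with the deficit split between the homozygotes so the allele
frequency is preserved; `f < 0` (heterozygote excess) is accepted as long as
all three probabilities stay non-negative.

The exposure is

    HbA1c_i = μ_A + λ Σ_j w_j (g_ij − 2p_j) + Σ_c γ_c z_ci + ε_i

with λ chosen so the genetic component explains exactly the target share
(default R² = 0.03) of the *theoretical* exposure variance σ_A² (default
μ_A = 5.98%, σ_A = 1.06%, matching the emulated cohort's descriptives).
Using theoretical rather than realized variances keeps the truth record
exact: regressing simulated HbA1c on the true rescaled score has slope 1 in
expectation, which the tests verify at n = 10⁵. Confounders (age and BMI by
default) act on both exposure and outcomes through standardized covariates
z_c, giving the adjustment models something real to remove; exposure noise
variance is set to σ_A²(1−R²) − Σγ_c², so the total variance matches σ_A².

Each outcome adds the causal effect of the *realized* standardized exposure,
per-allele pleiotropic leakage, confounding, and Gaussian noise:

    Y_ki = μ_k + β_k (HbA1c_i − μ_A)/σ_A + Σ_j α_jk g_ij + Σ_c δ_ck σ_k z_ci + e_ki

Default causal effects per SD HbA1c are 0.19 (log-TG), 0.42 mmol/L (TC),
0.33 mmol/L (LDL-C) and 0 (HDL-C); outcome means and total SDs default to the
emulated cohort's Table-of-descriptives values (e.g. TC 4.94 ± 1.18 mmol/L).
Residual variance is σ_k² − β_k² − Σ(δσ_k)², so under no pleiotropy total
outcome variance matches σ_k²; pleiotropy adds on top. Triglycerides are
generated on the log scale and exponentiated, so the pipeline's log transform
is exercised; the stored `log_tg` column is recomputed as `log(exp(x))` so
derived columns round-trip bit-exactly from raw columns. Fasting glucose,
2-hour glucose and fasting insulin are generated with plausible correlation
to the exposure (FPG = 6.0 + 0.9·z_A + noise, clipped at 0.5 mmol/L;
insulin log-normal around 8 mIU/L); the diabetes flag is HbA1c ≥ 6.5% or
FPG ≥ 7.0 mmol/L (standard diagnostic thresholds; configurable). Genotype
missingness is completely at random at a configurable rate (default 1%), and
masked dosages are flagged, never altered.

What the generator does *not* emulate: linkage disequilibrium between SNPs
(the emulated panel was reported LD-free), assortative mating or population
stratification, selection effects, treatment feedback (e.g. lipid-lowering
therapy), non-Gaussian noise, or longitudinal structure. Passing tests
therefore demonstrate correctness of the estimators under the stated model,
not robustness to those real-data complications.

## Instrument panel

The shipped annotation lists the 17 HbA1c loci of the emulated study with
*placeholder* weights (0.019–0.052 % per allele) and frequencies — the
source effect sizes are not bundled — plus eligibility flags: reported
pleiotropy (8 SNPs), Hardy-Weinberg failure at P < 10⁻⁴ (3), in-sample
non-significance (4), and East Asian identification (all but two). The
conservative sub-panel keeps SNPs with no reported pleiotropy, HWE pass, and
either in-sample significance or East Asian identification; under the shipped
flags that yields exactly 6 SNPs. The G6PC2/ABCB11 locus appears in the
literature under two rsids (rs552976 / rs3755157); the shipped annotation
keeps one entry carrying that locus's HWE-failure and non-significance flags,
and membership is fully configurable through the annotation file.

## Scores and missingness policy

Scores are additive in risk-allele dosage, weighted by the annotation (unit
weights for the unweighted variant). Individuals missing more than two subset
SNPs are excluded; for one or two missing SNPs the default policy replaces
each missing term by that SNP's mean weighted contribution among non-missing
individuals (per-SNP mean imputation). The cited description of the policy is
ambiguous between per-SNP and whole-score mean substitution; per-SNP is the
default because it preserves the information in the observed SNPs, and the
whole-score reading is available via `impute="whole_score"`. Per-SNP mean
imputation shifts all affected individuals' scores by a constant, so
downstream association coefficients among them are unchanged (tested).
Quartiles use inclusive linear-interpolation percentiles at 25/50/75 with
boundary ties assigned to the lower quartile — deterministic and
rank-invariant under positive affine transforms.

## Association models

Ordinary least squares with listwise deletion. Model 1 adjusts age, sex,
BMI; Model 2 adds systolic/diastolic blood pressure, smoking, drinking and
physical activity; Model 3 adds the diabetes flag. The reported R² for a
predictor is its added-last increment in model R²; the instrument F statistic
is the squared t value. Note that diabetes is a deterministic function of the
exposure here, so Model-3-adjusted gene–exposure R² understates instrument
strength; instrument-strength metrics are best read from the unadjusted or
Model-1 fits (the acceptance script reports the unadjusted R²). Per-SNP
summary statistics use a compact numpy OLS (cross-checked against statsmodels
to 10⁻¹⁰ in the tests); monomorphic SNPs are skipped with a warning. The
Hardy-Weinberg screen is the 1-df chi-square (not the exact test) at the
10⁻⁴ flag threshold, appropriate at cohort sample sizes. Quartile trends use
OLS on the integer quartile score for continuous traits and the
Cochran-Armitage 1-df chi-square for proportions (score choice 0–3 vs 1–4 is
immaterial; verified, and the chi-square p agrees with a label-permutation
oracle within Monte-Carlo error).

## Causal estimators

*GRS ratio.* β_MR = β_GY/β_GX with delta-method SE
√(se_GY²/β_GX² + β_GY²·se_GX²/β_GX⁴), z-based two-sided p. Identical to
two-stage least squares with the score as single instrument and the same
covariates (verified to 10⁻⁸ relative against an independent 2SLS oracle).
Instruments with |β_GX| below 10⁻¹⁰ are rejected as degenerate.

*Wald ratios and IVW.* Per-SNP ratios use first-order SEs (sy/|bx|) by
default, which makes ratio-form IVW algebraically identical to the
zero-intercept weighted regression of by on bx with weights 1/sy²
(both forms implemented; equality tested to 10⁻¹⁰). The second-order
delta SE is available behind `order=2`. Fixed-effect pooling is the default,
mirroring an analysis that found no significant heterogeneity; a
multiplicative random-effects option inflates the SE by √(Q/df) when
Q/df > 1.

*Weighted median.* Ratios are ordered; normalized inverse-variance weights
give cumulative midpoints p_j = cumsum(w)_j − w_j/2; the estimate linearly
interpolates the ordered ratios at p = 0.5. The SE is a parametric bootstrap
(resampling bx ~ N(bx, sx), by ~ N(by, sy); default 1,000 replicates,
seeded; the source method's replicate count is unstated).

*MR-Egger.* SNPs are pre-oriented to bx > 0; weighted least squares of by on
bx with free intercept and weights 1/sy². SEs use the multiplicative
random-effects convention (residual variance factor floored at 1), inference
is t on J−2 df, matching the method's source convention; z-based inference is
used for the other estimators. With the intercept constrained to zero the fit
reproduces regression-form IVW exactly.

*Pleiotropy residual diagnostics (MR-PRESSO style).* The observed statistic
is RSS = Σ_j w_j (by_j − β̂₋j·bx_j)² with w_j = 1/sy_j² and β̂₋j the
leave-one-out regression-form IVW. The null distribution redraws
by*_j ~ N(β̂₋j·bx_j, sy_j) and (by default) bx*_j ~ N(bx_j, sx_j), recomputing
the leave-one-out expectations per replicate; a by-only perturbation variant
exists behind a flag. Monte-Carlo p-values use the add-one rule (granularity
1/(n_sim+1), never exactly 0; default n_sim = 1,000, seeded). The outlier
test compares each SNP's observed weighted squared residual with its own
simulated distribution, Bonferroni-controlled at α = 0.05 by default (FDR
optional). The distortion statistic is 100·(raw − corrected)/|corrected| with
a two-sided Monte-Carlo p from removing equally many random non-outlier SNPs.
Raw and corrected causal estimates use the weighted no-intercept regression
with residual-variance-scaled SE and t statistics on J−1 df (t for this
procedure, z elsewhere, per the emulated analysis). The reported estimate is
the outlier-corrected one when outliers are flagged, otherwise the raw one.
Agreement with the original tool is distributional, not bitwise — no attempt
is made to reproduce its random-number stream.

*Power.* Two-sided normal-approximation power for the IV test of a continuous
outcome: z* = √(n·R²_GX)·β_std; power = 1 − Φ(z_{1−α/2} − z*) +
Φ(−z_{1−α/2} − z*). Several variants of this calculation circulate; this
closed form is the implemented and test-pinned one, an approximation to the
online calculator it replaces. At n = 11,473, R² = 0.03, β_std = 0.1,
α = 0.05 it gives 0.458.

## Validation experiments and problem sizes

The statistical guarantees run as tests with these (package-chosen) sizes:

- *Oracle equivalence*: 20 cohorts, n = 2,000 — GRS ratio vs 2SLS to 10⁻⁸.
- *Recovery*: 200 cohorts, n = 2,000, J = 17, true β = 0.3 per SD exposure,
  valid instruments — mean bias of IVW, weighted median and GRS ratio within
  3 Monte-Carlo SEs of zero; IVW and GRS-ratio 95% CI coverage in
  [0.90, 0.98].
- *Robustness ordering*: 200 cohorts, n = 10,000, with 7 of 17 instruments
  carrying a constant directional per-allele effect of 0.06 outcome units
  (roughly twice the typical per-allele effect through the exposure pathway).
  The contaminated subset is chosen to minimize the weighted covariance
  between pleiotropy status and instrument strength, i.e. the InSIDE
  condition holds by construction; under it the weighted median and the
  Egger slope are each closer to the truth than IVW in ≥80% of replicates.
  With contamination assigned at random instead, Egger's per-replicate
  advantage over IVW is not guaranteed at this panel's weight spread — its
  slope dispersion scales inversely with the spread of the gene–exposure
  effects — which is why the InSIDE-exact construction is the tested
  scenario; one-sample estimation error in bx additionally attenuates Egger
  (the known NOME sensitivity).
- *Global-test calibration*: 200 replicates at n_sim = 500 under a
  no-pleiotropy two-sample null with a precisely estimated gene–exposure side
  (discovery n = 150,000), matching the test's own parametric model;
  rejection counts must fall inside the exact binomial 95% interval around
  5%. A +10·SE contaminated SNP must be flagged in ≥95% of replicates.

## Numerical and degenerate-input choices

Listwise deletion throughout; rank-deficient designs are rejected naming the
offending column. HOMA-β is undefined (NaN, excluded from log transforms)
when FPG ≤ 3.5 mmol/L rather than raising. Degenerate trend tables (no or
all cases) return statistic 0 with a warning. Allele frequencies within 10⁻⁸
of 0 or 1 are rejected as effectively monomorphic. Quartile ties go to the
lower quartile; an all-equal score vector puts everyone in quartile 1.
Report tables serialize floats at %.17g so parsing recovers estimates
bit-exactly; display rounding (2 decimals for β/SE, 2 significant figures
for p, two-level significance stars at 0.05/0.01) is a separate formatting
step. All randomness flows through explicit integer seeds via numpy
Generators; identical inputs and seeds give identical outputs everywhere,
including the bootstrap and Monte-Carlo procedures.

## Known limitations

One-sample weak-instrument behavior is only partially characterized: at the
default instrument strength (R² = 0.03 over 17 SNPs) per-SNP F statistics
are small at n = 2,000, and while the recovery tests show the pooled
estimators remain essentially unbiased under valid instruments, MR-Egger is
materially attenuated in that regime. No multivariable MR, no correlated
instruments (LD), no CAUSE/contamination-mixture estimators, and no
generalized linear models for binary outcomes — the emulated analysis needs
none of these. The shipped panel's weights are placeholders; analyses of real
data must substitute literature values in the annotation file.
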