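# Methods

## Scores and APOE handling

Each polygenic score is an unweighted risk-allele count: dosages in
{0, 1, 2} summed over the score's markers. The LDL score spans five SNPs
(maximum 10), the HDL score four HDL-lowering SNPs (maximum 8; higher score
→ lower HDL), and the TG score five SNPs plus one extra additive component,
the APOE ε2 haplotype dosage (maximum 12). rs3916027 appears in both the
HDL and TG scores.

APOE ε genotypes are inferred from unphased rs429358/rs7412 C-allele
dosages under the no-ε1 assumption (ε4 = C,C; ε3 = T,C; ε2 = T,T). This
makes the ε2 count equal to the rs7412 T dosage for every input, and
resolves the double heterozygote (1, 1) as ε2/ε4 with an `ambiguous` flag.
Dosage pairs impossible without ε1 (e.g. rs429358 CC with rs7412 TT) can
only arise from genotyping error; the caller keeps the rs7412-derived ε2
count, caps the ε4 count, and flags the call rather than failing, so
downstream scoring never sees a partial call.

Missing genotypes are handled by one of two policies. The default,
`mean_impute`, replaces a missing dosage with twice the cohort allele
frequency at that marker: with 96–98% call rates, complete-case scoring
over five markers would drop roughly 10–15% of subjects, whereas mean
imputation keeps the full sample and — because the imputed value is the
conditional mean given no information — leaves regression slopes on the
score unbiased. `complete_case` is available and reported per subject.

## Quality control

Per variant: call rate (non-missing fraction), risk-allele frequency
computed by default on the disease-free subset (matching how published
panel frequencies are defined), and a Hardy–Weinberg exact conditional
test. The exact test conditions on the sample size and minor-allele count
and sums the probabilities of all heterozygote counts no more probable
than the observed one (probability-ordering two-sided rule). An exact test
is used rather than the one-df chi-square because the panel includes
frequencies as extreme as 0.94 (rs328), where expected rare-homozygote
counts are small; the chi-square version is kept as an option. The HWE
pass threshold defaults to the Bonferroni value 0.05/13 ≈ 3.85 × 10⁻³,
and the call-rate floor to 0.95.

## Lipid arithmetic

All lipids are mmol/L internally. LDL, when not measured, is estimated by
Friedewald (TC − HDL − TG/2.2, the mmol/L form of TG/5) strictly below
TG = 3.9 mmol/L; at or above that the apoB-based linear estimator is used
when apoB is available, else LDL is left missing and the subject is logged.
The apoB estimator is deliberately pluggable (slope/intercept); the shipped
defaults (2.70 mmol/L per g/L, −0.30) are a synthetic calibration chosen
only to map physiologic apoB (0.6–1.8 g/L) into a physiologic LDL range —
they are not fitted to any assay, and sites should substitute locally
validated constants. The synthetic cohort caps TG below 3.9 mmol/L by
default (high-TG subjects are rare, ~1–2%, in the emulated population), so
the Friedewald branch is exercised uniformly; disabling the cap exercises
the apoB branch.

Unit conversions use 38.67 mg/dL per mmol/L for cholesterol species and
88.57 for triglycerides; these reproduce the standard printed mmol↔mg
pairings within rounding and are fixed, not configurable. Log transforms
are natural logarithms throughout: a log-scale per-allele coefficient β is
interpreted as a 100·(e^β − 1) percent change, or mean·(e^β − 1) mmol/L
at a given mean level.

## Association models

Lipid-level models are OLS of the (log-)lipid on the score treated as a
continuous allele count (not standardized), excluding subjects on
lipid-lowering therapy and/or with CAD. Reported per model: per-allele β
with Wald 95% CI and p, the r² of the exposure-only fit, and the r² of the
fully adjusted fit — the unadjusted/adjusted "explained variability" pair.
Covariate sets: LDL — sex, age, BMI, diabetes, smoking; HDL — sex, age,
BMI, diabetes, alcohol; TG — those plus hypertension; CAD — age, sex,
hypertension, diabetes, smoking. Analyses are complete-case per model with
n_used always reported; subjects whose hypertension flag is undeterminable
(no blood pressure, no medication record) drop only from models that use
it, with a logged count.

Logistic models (guideline threshold categories, CAD) report the
per-allele OR = e^coefficient with a Wald CI on the log-odds scale —
symmetric after exponentiation, matching how such ORs are customarily
printed. Perfect separation is detected and reported as a flagged
no-estimate result rather than a spurious number. Tertile contrasts
restrict to the extreme bins and fit a single indicator; quartile
contrasts keep all bins and read each OR against the lowest bin from one
joint model. Bin cutpoints are empirical quantiles of the discrete score;
a value tied with a cutpoint goes entirely to the lower bin, which is why
bin shares can be far from 1/k (a "top quartile" can hold ~10% of
subjects). No multiple-testing correction is applied across the
threshold-by-model grid.

## Discrimination

AUC is the Mann–Whitney probability that a random case outscores a random
control, ties counted half; its variance and CI come from DeLong's
structural components. Nested CAD models (risk factors vs risk factors +
score) are compared with the paired DeLong normal test on the AUC
difference, computed on the common complete-case subjects from in-sample
predicted probabilities (no cross-validation — matching the descriptive,
same-sample use of ROC here). A degenerate variance (identical
predictions) returns p = 1 with a flag. A seeded bootstrap would be a
reasonable alternative; DeLong is the default because it is the standard
for correlated ROC curves.

## Synthetic cohort generator

The generator emulates the cross-sectional structure the models assume:

- **Genotypes.** Non-APOE variants are independent Hardy–Weinberg draws
  (two Bernoulli(RAF) alleles per subject) at the study-sample risk-allele
  frequencies (0.16–0.94 across the panel). APOE is drawn at the haplotype
  level — two haplotypes per subject from (ε2, ε3, ε4) = (0.09, 0.67,
  0.24) — and converted to rs429358/rs7412 dosages. This induces the
  structural dependence between the two APOE SNPs (no-ε1), which matters:
  treating them as independent SNPs would misstate the LDL-score variance
  and hence the variance it explains. The (0.09, 0.67, 0.24) triple is the
  one consistent with both published SNP frequencies (rs429358-C 0.24,
  rs7412-C 0.91). An optional haplotype-correlation parameter adds LD
  between the two CETP SNPs (off by default). Per-call missingness (3%
  default) emulates 96–98% call rates.
- **Lipids.** LDL = 3.08 + 0.144·(LDL-PRS − E[PRS]) + modest covariate
  terms + Gaussian residual, with the residual variance solved so the
  marginal SD is 0.89 — descriptive statistics are matched by
  construction, not by tuning. log-HDL and log-TG are analogous on the
  natural-log scale with lognormal moment matching to means/SDs 1.36/0.48
  and 1.11/0.73 (per-allele effects −0.021 and +0.018). TC = LDL + HDL +
  TG/2.2 + N(0, 0.05) so Friedewald approximately round-trips. Covariate
  effects on lipids are not published for the emulated cohort; the
  defaults (e.g. +0.008 mmol/L LDL per year of age, +0.11 log-TG for men)
  are modest, orthogonal to genotype, and nothing in the acceptance
  machinery depends on them.
- **Covariates.** Age ~ N(53.71, 14.02²), male 49.4%, BMI ~ N(27.06,
  5.46²), hypertension 40.6%, diabetes 17.3%, smoking 19.7%, regular
  alcohol 18.5%. Blood pressure and medication indicators are drawn so the
  derived hypertension flag equals the drawn one.
- **CAD.** Logistic liability: logit P = α + log(1.27)·LDL-PRS + effects
  of age, sex, hypertension, diabetes, smoking; α is solved numerically
  (Brent) so the cohort-average probability equals the 27.2% target.
  Lipid-lowering therapy is drawn at 75% among cases and 7.8% among
  non-cases, chosen so the subset free of CAD and therapy averages ≈ 473
  of 705 subjects — the sample the lipid-level models see.

What the generator does **not** emulate: admixture and population
structure, relatedness, genotyping batch effects, treatment effects on
lipid levels, non-lognormal lipid tails, and covariate–covariate
correlations beyond those induced by the liability model. Passing
recovery tests therefore demonstrates that the estimators are correct
under the stated generative model, not that the pipeline is robust to
real-data pathologies such as confounding by ancestry.

## Determinism and problem sizes

Every stochastic call flows from a single integer seed through
`numpy.random.default_rng`; replicate seeds are spawned via
`SeedSequence.generate_state` and kept below 2³¹. Identical seeds give
byte-identical outputs. Monte Carlo checks use 200 replicates at the
emulated sample sizes (n = 473 for lipid models, 705 for CAD models) —
enough for Monte Carlo SEs of ~0.13 percentage points on the mean
explained variance and ~1.5 points on CI coverage — and large-n checks
(10⁵) for calibration of frequencies, moments and prevalence.

Analytic cross-check used in the tests: the population r² of LDL on the
LDL score is β²·Var(PRS)/σ², with Var(PRS) = Σ 2p(1−p) over the three
independent SNPs (1.131) plus the two-haplotype APOE component (0.615),
giving 0.144²·1.746/0.89² ≈ 4.57%; the mean sample r² at n = 473 sits
~0.2 points above it (finite-sample inflation of order (1−ρ²)/n).

## Known limitations

- The apoB→LDL default constants are synthetic (see above).
- The exact HWE test enumerates heterozygote counts; it is exact but
  conditional, hence conservative at tiny minor-allele counts.
- Quartile contrasts on heavily tied integer scores can produce empty
  intermediate bins at small n; the contrast then fails loudly rather than
  silently re-binning.
- Weighted scores are deliberately out of scope; the score API would
  accept weights, but nothing validates them against published effects.
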