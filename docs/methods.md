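# Methods

## Problem and approach

`pocdiag` diagnoses the likely missingness mechanism of partially observed
confounders (POCs) in a patient-level cohort with a binary exposure and a
continuous, binary, or time-to-event outcome. The mechanism taxonomy is
the standard one: MCAR (missingness independent of everything), MAR
(explained by observed covariates), MNAR-value (depends on the missing
value itself), and MNAR-unmeasured (depends on unobserved covariates).
Three groups of diagnostics probe complementary implications of each
mechanism; a rule matrix then reads the combined pattern.

All diagnostics condition on complete exposure and outcome data; rows with
missing exposure or outcome are rejected at validation rather than
silently dropped, because every diagnostic conditions on them. Other POCs
always enter a diagnostic for a given POC through their missingness
*indicators*, never their values — using the values would force case
deletion and entangle the diagnostics of different POCs.

## Group 1 — distributional imbalance

For POC `p` with indicator `M`, the comparison set is the exposure
(configurable), every fully observed covariate (categoricals expanded to
one-hot columns), and the other POCs' indicators.

- **ASMD**: continuous `|x̄₁ − x̄₀| / √((s₁² + s₀²)/2)` (sample variances,
  ddof 1); binary `|p̂₁ − p̂₀| / √((p̂₁(1−p̂₁) + p̂₀(1−p̂₀))/2)`. Multi-level
  categoricals get one-vs-rest per-level ASMDs summarized by the level
  maximum — simple and conservative; a pooled Mahalanobis variant was the
  road not taken because it changes the scale against the conventional 0.1
  threshold. The aggregate is the median across covariates (mean by flag)
  with the min/max range. A stratum with n < 2 makes a continuous ASMD
  undefined; the covariate is flagged and excluded from the aggregate.
- **Hotelling T²**: two-sample `T² = (n₀n₁/(n₀+n₁)) d′S_pooled⁻¹d`, with
  `F = (n₀+n₁−k−1)/(k(n₀+n₁−2)) · T²` on `(k, n₀+n₁−k−1)` df. The design
  here drops one reference level per categorical so `S_pooled` stays full
  rank; condition numbers above 1e12 raise an error advising covariate
  reduction rather than returning a garbage inverse.
- **Little's MCAR test**: the variable vector is the POC values plus the
  fully observed covariates (categoricals one-hot minus reference level;
  exposure excluded by default). The mean and covariance are ML estimates
  from EM under multivariate normality (pattern-grouped E-step;
  convergence when the parameter sup-norm change drops below 1e-6, max 500
  iterations, ridge 1e-8 on the covariance diagonal). The statistic is
  `d² = Σⱼ nⱼ (ȳ_obs,j − μ̂_obs,j)′ Σ̂_obs,j⁻¹ (ȳ_obs,j − μ̂_obs,j)` over
  distinct missingness patterns with `df = Σⱼ pⱼ − p`, referred to χ²_df.
  Normality is approximate for binary variables; pattern means are still
  asymptotically normal, and the simulated type-I error at the default
  study size is close to nominal (see the acceptance suite). A dataset
  with a single missingness pattern has df = 0 and is flagged
  inapplicable. No multiple-testing adjustment is applied across POCs;
  raw p-values are reported.

## Group 2 — predictability

A random forest (scikit-learn, `ntree` default 1000, `mtry = √k`,
stratified 70/30 train/test split) predicts `M` from exposure, outcome
(event flag and follow-up time as separate columns for survival data),
covariates, and the other POCs' indicators. Reported: held-out AUC
(midrank convention), out-of-bag error, and permutation importance
labelled "mean decrease in accuracy" (10 shuffles per predictor by
default). Importance is computed on the held-out split: training-split
permutation rewards memorized noise and can assign large importance to
predictors that generalize nothing. AUC > 0.9 triggers an alert naming the
top predictor; when that predictor is another POC's indicator, a monotone
pattern is the likely cause and independent per-POC runs are recommended.
"Meaningfully above 0.5" is operationalized as AUC ≥ 0.55 for the
automated verdicts — a documented package choice, configurable, since the
literature leaves it qualitative.

## Group 3 — outcome association

`M` enters the outcome model twice: univariate, and adjusted for exposure,
all fully observed covariates, and the other POCs' indicators ("all other
covariates" is read this way to avoid case deletion; exposure inclusion is
a flag). Models: OLS, GLM (binomial-logit default), or Cox proportional
hazards (lifelines, Efron tie handling). Estimates are reported on the
coefficient scale (log-HR, log-odds, identity) with Wald 95% CIs
(`β ± 1.96·SE`) — symmetric intervals matching conventional software
output rather than profile likelihood.

## Interpretation matrix

With thresholds (ASMD 0.1 — the conventional imbalance cut-off; AUC 0.55;
α 0.05): *imbalance* = median ASMD > 0.1 or Hotelling p < α;
*predictable* = AUC ≥ 0.55; *associations* = 95% CI excludes 0.

| signature | verdict |
|---|---|
| no imbalance ∧ ¬predictable ∧ no association either model | ~MCAR |
| imbalance ∧ predictable ∧ univariate only | ~MAR |
| no imbalance ∧ ¬predictable ∧ adjusted association | ~MNAR-value |
| anything else, or any failed cell | indeterminate |

MNAR-unmeasured is never positively claimed: on these diagnostics it is
observationally indistinguishable from MCAR, so the MCAR verdict carries
that caveat in its trace. Because the MCAR verdict is a conjunction of
several independent ~5%-level checks, its per-cohort recovery rate is
bounded near `0.95² × P(AUC < 0.55) ≈ 0.85–0.90` even when the mechanism
truly is MCAR — a structural property of stacking unadjusted tests, not an
implementation artifact. Users wanting a higher MCAR hit rate can lower α
or raise the AUC threshold at the cost of power against MAR.

## Synthetic cohort generator

The generator emulates an oncology cohort: age ~ N(63, 9²); female ~
Bern(0.55); smoking ~ Bern(0.40); histology (adeno/squamous/other:
0.60/0.25/0.15); three ordered SES levels (0.30/0.40/0.30); ECOG ≥ 1 with
a logit linear in age and smoking; EGFR mutation at 20% prevalence,
enriched in never-smokers; PD-L1 percent ~ Beta(2,2)×100. Treatment
assignment is logit-linear in age, ECOG, and histology (45% treated).
Event times follow a Weibull proportional-hazards model (shape 1.3,
baseline median 2.5 years) with exposure log-HR −0.3 and covariate
effects of conventional epidemiologic size (age 0.30/SD, ECOG 0.40,
PD-L1 0.35/SD, ...), administratively censored at 5 years (~80% events).
A zero censoring horizon is a supported boundary: follow-up is floored at
1e-12 so the resulting all-censored table still validates.

Amputation: each POC's missingness is Bernoulli with a logit-linear
model — constant for MCAR; weights on observed covariates for MAR (default
weights on age, sex, smoking, histology, SES, and exposure, sized so the
MAR POC is clearly predictable and imbalanced at n = 2500); the POC's own
standardized value for MNAR-value (self-weight 0.8/SD, so high PD-L1
values go unrecorded); a standard-normal latent draw for MNAR-unmeasured,
never written to the table. The intercept is solved by bisection on the
logit scale so the expected missingness equals the 35% target exactly
(analytic intercepts do not exist for covariate-dependent mechanisms); an
optional monotone-coupling flag forces one POC missing wherever its parent
is. All randomness uses numpy's PCG64; a seed fixes the cohort
byte-for-byte.

What the generator does **not** emulate: measurement error, informative
censoring, time-varying covariates, correlated lab panels, or multi-row
longitudinal structure. Passing diagnostics on this cohort demonstrate the
machinery recovers *cleanly generated* mechanisms; real EHR missingness is
usually a mixture, and verdicts there should be read as evidence, not
classification.

## Problem sizes and numerics

Default study conditions are n = 2500 with 35% missingness per POC —
large enough that the mechanism signatures separate and the asymptotic
reference distributions hold, small enough for quick iteration. The
replication-based checks in the acceptance suite use 500 replicates for
type-I calibration (Hotelling and Little under all-MCAR), 20 replicates
for the MCAR AUC/ASMD values, and 100 replicates for mechanism recovery
(forest size 200 there; AUC differences between 200 and 1000 trees are
well inside the sampling noise of a 750-patient test split). Deterministic
tie-breaks: pattern rows sort by descending frequency then
lexicographically by bits; monotone search is exhaustive to 8 POCs and
greedy-with-verification above; binary columns code the larger sorted
value as 1.

## Round-trip guarantee

`write_cohort` ∘ `load_cohort` preserves cell values, missingness
positions (empty string on disk, "NA" also read by default), and column
order; a second write is byte-identical to the first. Byte identity with
arbitrary third-party files is not promised (e.g. `1.20` re-serializes
as `1.2`).

## Known limitations

- Verdicts are advisory pattern matches; a true mechanism is never
  identifiable from observed data, and MNAR-unmeasured mimics MCAR.
- Little's test and Hotelling assume approximate multivariate normality
  of pattern/stratum means; heavy one-hot expansion of rare levels can
  stress that approximation.
- Single-row-per-patient data only; no database connectors; no
  imputation or downstream fixing — this package diagnoses.
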