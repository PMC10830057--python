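# Methods

This note documents the statistical procedures `cvdval` implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Cohort model and filters

The unit of analysis is a participant followed from a baseline health
examination for up to 10 years. Records carry the engine covariates (age,
total cholesterol, HDL, systolic blood pressure, blood-pressure-treatment,
smoking and diabetes flags), the additional candidate predictors (LDL,
triglycerides, fasting glucose, BMI), and the 10-year outcome: a composite
CVD event defined by ICD-10 category prefix over
{I20, I21, I46, I48, I50, I60–I64, G45} (subcodes such as I21.4 map to their
3-character category). Non-events are administratively censored at exactly
10 years; this "alive at 10 years" design is why all discrimination and
calibration statistics can treat the outcome as a plain binary label.

Study-entry filters: age ≥ 30, no prior CVD, and outlier caps
(TC > 300 mg/dL, HDL > 100 mg/dL, BMI > 100 kg/m², LDL > 1,000 mg/dL,
TG > 1,500 mg/dL). A record violating several rules is attributed to the
first violated rule in that fixed order, making the exclusion log
deterministic; no convention for multi-rule violators is published, so this
is a package choice. Engine eligibility windows default to the equations'
development ranges (Framingham 30–74, ASCVD 40–79 years) and are
overridable.

Incidence rates are events per 100,000 person-years with the exact-Poisson
(chi-square-quantile) confidence interval; the two-sample rate comparison is
the exact conditional binomial test (conditioning on total events, group-a
events are binomial with success probability proportional to its
person-years). Both are documented choices — the source tables state
neither their CI method nor their test.

## Risk engines

Both engines are instances of one data-driven form: an ordered list of
terms (covariate(s), transform ∈ {ln, identity, ln², ln×ln,
ln×indicator}, optional treated/untreated condition, coefficient), a mean
linear predictor `mean_lp`, and a 10-year baseline survival `S0`. Scoring is
`risk = 1 − S0^exp(Σβf − mean_lp)`. Coefficients are transcribed from the
engines' source publications into per-engine/sex CSV tables (provenance in
`data/coefficients/README.md`); the ASCVD tables use the White/other race
stratum, the published form for populations without a dedicated stratum.
Out-of-range covariates are scored as-is with a logged warning — the
equations publish no truncation rule, and silent truncation would hide
exactly the distribution shift this package exists to study.

The coefficient-transfer experiment is a pure relabeling: `transfer_spec`
keeps terms, `mean_lp` and `S0` and changes only the sex tag, so a female
cohort is scored by the male equation unchanged.

## Discrimination and calibration

AUC is the Mann–Whitney probability (ties ½) via midranks; its variance
uses the DeLong structural components (per-positive and per-negative
placement values), and the paired DeLong test compares two engines scored
on the same subjects with the structural-component covariance. Since the
two engines' age windows differ, the pipeline computes the paired test on
the subjects eligible for both.

Hosmer–Lemeshow: records are sorted by predicted risk and cut into 10
near-equal groups, tied predictions staying together in the lower group
(tie handling is unpublished; this rule makes the statistic
order-invariant). The statistic is Σ (O−E)²/[E(1−E/n)] with df = g − 2; the
plain Pearson Σ(O−E)²/E form is available by option. With g = 2 the df
vanish and the p-value degenerates to 1 (χ²=0) or 0. A bin with zero
expected-event variance but observed events yields an infinite χ² with a
warning. The operating point maximizes Youden's J over observed thresholds,
ties broken toward higher sensitivity — the published
sensitivity/specificity pairs state no threshold rule, so one had to be
fixed.

## Data-driven model search

Cox proportional-hazards fits maximize the Breslow-ties partial likelihood
(Efron by option) through statsmodels' `PHReg`; the 10-year baseline
survival is the Breslow cumulative-hazard estimate evaluated at the mean
linear predictor, so a fit converts directly into the same
`1 − S0^exp(L − mean_lp)` risk form as the packaged engines. Zero-variance
design columns carry no information and are fixed at coefficient 0.

The subset search enumerates all 2^p − 1 non-empty subsets of a candidate
pool (default: the engine terms plus ln BMI, ln LDL, ln TG, ln glucose and
ln-age-squared; the treated/untreated SBP pair enters and leaves together).
Folds are event-stratified and seeded. The selection statistic is the AUC
of pooled out-of-fold predictions (per-fold averaging by option — which of
the two the original analysis used is unstated); ties prefer smaller
subsets, then lexicographic order. Pools above 20 entries are refused
unless forced.

Variance importance of term j is `100·[Var(L) − Var(L₋ⱼ)]/Var(L)` with
coefficients held fixed, one row per term (interactions and each SBP
condition separately). This leave-one-term-out reading of "relative
proportion of variances" is this package's documented interpretation of an
underspecified statistic; under correlated covariates shares can be
negative and do not sum to 100, and they are reported as computed.

## Synthetic cohort generator

Covariates come from a Gaussian copula: correlated standard-normal latents
are mapped affinely to each continuous covariate's target mean/SD and
thresholded at the prevalence quantile for each binary flag. The packaged
`table1_male`/`table1_female` parameter sets transcribe the study
population's published per-sex means, SDs and prevalences; since treatment
prevalence is unpublished, `bp_treated` uses the published hypertension
prevalence (6.2% men, 7.1% women) as a stand-in. The latent correlation
matrix is explicitly invented (no correlation data are published): modest
positive couplings among BMI/SBP/TG/glucose, strong glucose–diabetes and
SBP–treatment links, TC–LDL collinearity, negative HDL–TG; it is packaged,
documented, and fully overridable.

Positivity: records require strictly positive continuous values, so draws
are floored at 1.0 unit. For most covariates the floor is >5 SD below the
mean and inert; for triglycerides (149 ± 97 mg/dL in men) an unfloored
normal puts ~6% of mass below zero and naive clipping would bias the mean
by +2.6 mg/dL. The generator therefore solves the closed-form moments of
the floored normal for a (location, scale) pair such that the clipped
marginal matches the target mean and SD exactly.

Outcomes: in `engine_true_risk` mode a risk-equation spec is the ground
truth — events are Bernoulli in each record's true 10-year risk, event
times uniform on (0, 10] (timing is immaterial to the binary-label
evaluation, only to Cox fitting), and ICD subtype codes are sampled from
the sex's published event mix. In `subtype_hazards` mode each subtype gets
a constant competing exponential hazard; because events-per-person-year
equals the hazard exactly under administrative censoring, calibration to
the published incidence rates is simply `rate / 100,000`
(`table2_subtype_hazards`). `generate_raw_cohort` plants exact fractions of
under-age, prior-CVD and outlier records into a base draw clamped inside
all thresholds, so the filter cascade's counts are known by construction.

What the generator does *not* model: claims-coding noise, secular trends,
competing non-CVD mortality, non-Gaussian marginal shapes (beyond the
positivity clip), or the real joint distribution beyond first/second
moments and the invented correlation. Passing tests therefore establish
that the pipeline's statistics are computed correctly and that the
generator hits its calibration targets — not that the engines' real-data
AUC or calibration values would be reproduced.

## Numerical choices and problem sizes

Determinism: every stochastic routine takes an explicit seed; the pipeline
derives per-stage seeds from one root seed and records them in the run log.
CSV floats are written with pandas' shortest-repr formatting, which
round-trips doubles exactly. Risk is clamped to [0, 1] only against
floating-point spill. Cox convergence is declared when the per-record score
norm falls below 1e-6; non-convergence is flagged, not raised.

Test and demonstration problem sizes are chosen so the whole suite runs in
a few minutes on one core: generator-fidelity checks at n = 20,000–50,619,
Cox parameter recovery at n = 20,000 × 100 replicates, transfer experiment
at n = 20,000, subset-search checks at n ≤ 5,000, bootstrap oracle at
n = 30 × 10,000 resamples.

## Known limitations

- The Hosmer–Lemeshow variant, operating-threshold rule, CV-AUC pooling
  rule and variance-importance formula are each one documented reading of
  an underspecified description; alternates are provided where feasible.
- The generator's correlation structure is invented; importance statistics
  computed on synthetic cohorts reflect that structure, not the real
  population's.
- Cox fitting inherits statsmodels' behavior for near-collinear designs
  (singular-matrix errors rather than automatic dropping of redundant
  columns).
- No competing-risk handling: subjects are assumed alive (or at least
  observable) through year 10 unless they have a CVD event, matching the
  study's evaluation design but not general claims data.
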