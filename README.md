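# cvdval

Validation, recalibration and data-driven benchmarking of 10-year
cardiovascular disease (CVD) risk equations on synthetic claims-style
cohorts.

Western 10-year CVD risk equations — the Framingham general-CVD score (FRS)
and the AHA/ACC pooled cohort equations (ASCVD) — are routinely applied to
East-Asian populations whose baseline risk and covariate distributions
differ from the derivation cohorts, and they can miscalibrate badly,
especially in women. `cvdval` packages the full external-validation workflow
for this question: risk-engine scoring from auditable coefficient tables,
discrimination (AUC, paired DeLong test) and calibration (Hosmer–Lemeshow
deciles), the cross-sex *coefficient-transfer* experiment (scoring a female
cohort with the male equation), an exhaustive cross-validated Cox
proportional-hazards covariate-subset search as a data-driven benchmark, and
a leave-one-term-out variance-importance statistic. Because the underlying
national claims data are restricted, the package ships a calibrated
synthetic-cohort generator that emulates the study population's published
baseline characteristics and outcome incidence, so every stage runs and is
testable end-to-end.

It is aimed at biostatisticians and epidemiologists studying risk-model
transportability, and at anyone who needs a reproducible harness for
"does this risk equation fit my population?" experiments.

## The model

Both engines share one functional form. For a participant with covariates
$x$,

$$L = \sum_k \beta_k f_k(x) - \bar{L}, \qquad
  \text{risk}_{10} = 1 - S_0(10)^{\exp(L)}$$

where the $f_k$ are log-transformed covariates (ln age, ln total
cholesterol, ln HDL, ln SBP split into treated/untreated terms, smoking and
diabetes indicators; the ASCVD equations add $(\ln\text{age})^2$ and
age-interaction terms), $\bar{L}$ is the derivation cohort's mean linear
predictor, and $S_0(10)$ the 10-year baseline survival. Coefficients live in
versioned CSV tables under `src/cvdval/data/coefficients/` (provenance in
the adjacent README).

Evaluation treats the outcome as a binary 10-year label (the study design
administratively censors all non-events at exactly 10 years): AUC with
DeLong structural-component variance, paired DeLong z-test between engines,
Hosmer–Lemeshow $\chi^2 = \sum_g (O_g-E_g)^2 / [E_g(1-E_g/n_g)]$ over risk
deciles with $g-2$ df, and the Youden-optimal sensitivity/specificity point.
The data-driven benchmark fits Cox models over all $2^p - 1$ covariate
subsets under seeded, event-stratified 5-fold cross-validation and keeps the
subset with the highest out-of-fold AUC. Covariate importance is
$100\,[\mathrm{Var}(L) - \mathrm{Var}(L_{-j})]/\mathrm{Var}(L)$, the share
of linear-predictor variance lost when term $j$'s contribution is removed.

## Worked example

Score one man with the Framingham equation, then run the coefficient-transfer
experiment on a synthetic female cohort whose true outcome model is the
*male* equation:

```python
from cvdval import (ParticipantRecord, builtin_spec, predict_risk, transfer_spec,
                    generate_covariates, simulate_outcomes, score_cohort,
                    table1_female, OutcomeSpec, roc_auc, hosmer_lemeshow)

me = ParticipantRecord(
    id="example", sex="male", age=55, total_cholesterol=213, hdl=50,
    ldl=120, triglycerides=150, fasting_glucose=90, bmi=24, sbp=120,
    bp_treated=False, smoker=False, diabetes=False, prior_cvd=False,
    event=False, followup_years=10,
)
pred = predict_risk(me, builtin_spec("framingham", "male"))
print(f"linear predictor L = {pred.linear_predictor:.4f}")
print(f"10-year CVD risk   = {pred.risk:.1%}")

male = builtin_spec("framingham", "male")
women = simulate_outcomes(
    generate_covariates(table1_female(), 20_000, seed=7),
    OutcomeSpec("engine_true_risk", engine_spec=male), seed=8,
)
labels = women.df["event"].to_numpy(bool)
for name, spec in [("female coefficients", builtin_spec("framingham", "female")),
                   ("male coefficients  ", transfer_spec(male, "female"))]:
    risk = score_cohort(women, spec)["risk"].to_numpy()
    roc, hl = roc_auc(risk, labels), hosmer_lemeshow(risk, labels)
    print(f"{name}: AUC {roc.auc:.3f} ({roc.ci_low:.3f}-{roc.ci_high:.3f}), "
          f"HL chi2 {hl.chi_square:7.1f}, p {hl.p_value:.3f}")
```

prints

```
linear predictor L = -0.0827
10-year CVD risk   = 10.2%
female coefficients: AUC 0.711 (0.696-0.725), HL chi2   345.5, p 0.000
male coefficients  : AUC 0.715 (0.701-0.730), HL chi2     8.1, p 0.425
```

The first two lines are the risk equation itself: this profile sits slightly
below the derivation cohort's mean ($L < 0$), giving a 10.2% 10-year risk.
The experiment below shows the transfer effect: both coefficient sets rank
subjects almost identically (AUC 0.711 vs 0.715 — discrimination is
insensitive to monotone rescaling), but the female equation is grossly
miscalibrated against male-equation-generated outcomes (Hosmer–Lemeshow
p < 0.001) while the transferred male coefficients calibrate (p = 0.425).

A full pipeline run — filters, both engines, both sexes, DeLong comparisons,
calibration deciles, the transfer experiment, subset search and importance
tables — is one command:

```sh
cvdval run --seed 1 --outdir results/run1
```

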