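# Packaged risk-equation coefficient tables

One CSV per engine/sex. Columns: `term` (row label), `covariates`
(`|`-separated record field names), `transform`
(`ln`, `identity`, `ln_square`, `product_of_lns`, `ln_times_identity`),
`condition` (`bp_treated`, `not_bp_treated`, or empty), `beta`.
Footer rows `mean_lp` (the mean linear predictor subtracted before
exponentiation) and `baseline_survival` (10-year event-free probability at
the mean profile) carry `transform=meta`.

Provenance:

- `framingham_*`: general cardiovascular disease 10-year risk functions,
  D'Agostino RB Sr et al., "General cardiovascular risk profile for use in
  primary care: the Framingham Heart Study", Circulation 2008;117:743-753,
  Table (Cox model coefficients, sex-specific).
- `ascvd_*`: Pooled Cohort Equations, White/other race stratum,
  Goff DC Jr et al., "2013 ACC/AHA guideline on the assessment of
  cardiovascular risk", Circulation 2014;129:S49-S73, Appendix 7 Table A.
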