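term,covariates,transform,condition,beta
ln_age,age,ln,,3.06117
ln_total_cholesterol,total_cholesterol,ln,,1.12370
ln_hdl,hdl,ln,,-0.93263
ln_sbp_treated,sbp,ln,bp_treated,1.99881
ln_sbp_untreated,sbp,ln,not_bp_treated,1.93303
smoker,smoker,identity,,0.65451
diabetes,diabetes,identity,,0.57367
mean_lp,,meta,,23.9802
baseline_survival,,meta,,0.88936
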