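term,covariates,transform,condition,beta
ln_age,age,ln,,2.32888
ln_total_cholesterol,total_cholesterol,ln,,1.20904
ln_hdl,hdl,ln,,-0.70833
ln_sbp_treated,sbp,ln,bp_treated,2.82263
ln_sbp_untreated,sbp,ln,not_bp_treated,2.76157
smoker,smoker,identity,,0.52873
diabetes,diabetes,identity,,0.69154
mean_lp,,meta,,26.1931
baseline_survival,,meta,,0.95012
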