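term,covariates,transform,condition,beta
ln_age,age,ln,,-29.799
ln_age_square,age,ln_square,,4.884
ln_total_cholesterol,total_cholesterol,ln,,13.540
ln_age_x_ln_total_cholesterol,age|total_cholesterol,product_of_lns,,-3.114
ln_hdl,hdl,ln,,-13.578
ln_age_x_ln_hdl,age|hdl,product_of_lns,,3.149
ln_sbp_treated,sbp,ln,bp_treated,2.019
ln_sbp_untreated,sbp,ln,not_bp_treated,1.957
smoker,smoker,identity,,7.574
ln_age_x_smoker,age|smoker,ln_times_identity,,-1.665
diabetes,diabetes,identity,,0.661
mean_lp,,meta,,-29.18
baseline_survival,,meta,,0.9665
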