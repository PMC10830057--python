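term,covariates,transform,condition,beta
ln_age,age,ln,,12.344
ln_total_cholesterol,total_cholesterol,ln,,11.853
ln_age_x_ln_total_cholesterol,age|total_cholesterol,product_of_lns,,-2.664
ln_hdl,hdl,ln,,-7.990
ln_age_x_ln_hdl,age|hdl,product_of_lns,,1.769
ln_sbp_treated,sbp,ln,bp_treated,1.797
ln_sbp_untreated,sbp,ln,not_bp_treated,1.764
smoker,smoker,identity,,7.837
ln_age_x_smoker,age|smoker,ln_times_identity,,-1.795
diabetes,diabetes,identity,,0.658
mean_lp,,meta,,61.18
baseline_survival,,meta,,0.9144
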