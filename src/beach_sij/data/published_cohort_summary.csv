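# Printed summary statistics of the published 30-patient axSpA biologic-therapy
# cohort: per-metric pre/post means, 95% CI of the mean change, and the printed
# standardized response mean (SRM). change_sign records the improvement
# convention: pre_minus_post for scores that fall with treatment, post_minus_pre
# for PDFF and structural fat scores, which rise.
# CI bounds are transcribed as ordered numbers (ci_low < ci_high). Where the
# printed lower bound's sign is inconsistent with the printed means and SRM
# under the paired-t model, the sign-resolved reading is stored and the note
# column records the printed form. Rows for which no reading is internally
# consistent keep the printed numbers and carry a note; they are excluded from
# numeric reconstruction checks.
metric,mean_pre,mean_post,p_printed,ci_low,ci_high,srm_printed,n,change_sign,note
basdai,6.88,4.91,<0.001,1.15,2.97,0.89,30,pre_minus_post,inconsistent: CI midpoint 2.06 disagrees with printed mean change 1.97
spinal_vas,6.90,4.76,<0.001,1.19,3.07,0.85,30,pre_minus_post,
asdas_crp,3.32,2.40,<0.001,0.53,1.32,0.88,30,pre_minus_post,printed lower bound -0.53; positive reading reproduces printed SRM
asdas_esr,3.19,2.29,<0.001,0.56,1.24,0.98,30,pre_minus_post,
crp,5.35,1.99,0.020,0.5798,6.134,0.45,30,pre_minus_post,printed lower bound -0.5798; positive reading reproduces printed SRM
sparcc_bme,15.18,10.60,0.008,1.317,7.850,0.52,30,pre_minus_post,printed lower bound -1.317; positive reading reproduces printed SRM
sparcc_sss_fat,17.73,19.63,0.161,0.7982,4.598,0.26,30,post_minus_pre,inconsistent: no sign reading reproduces printed SRM
adc_mean,291.22,277.16,0.056,0.37,28.49,0.37,30,pre_minus_post,
adc_median,195.21,170.52,0.012,5.83,43.53,0.50,30,pre_minus_post,
adc_p25,8.59,4.09,0.159,-1.87,10.83,0.27,30,pre_minus_post,negative lower bound consistent with non-significant p
adc_p75,476.4,457.2,0.078,-2.35,40.62,0.34,30,pre_minus_post,negative lower bound consistent with non-significant p
adc_p90,585.3,573.9,0.170,-8.56,46.31,0.26,30,pre_minus_post,inconsistent: no sign reading reproduces printed SRM
pdff_mean,57.39,59.54,0.098,-0.426,4.73,0.31,30,post_minus_pre,negative lower bound consistent with non-significant p
pdff_median,56.79,58.76,0.161,-0.83,4.78,0.27,30,post_minus_pre,negative lower bound consistent with non-significant p
pdff_p25,47.84,50.26,0.127,-0.73,5.57,0.29,30,post_minus_pre,negative lower bound consistent with non-significant p
pdff_p75,66.84,68.92,0.100,-0.43,4.57,0.31,30,post_minus_pre,negative lower bound consistent with non-significant p
pdff_p90,51.21,50.53,0.132,-0.54,3.90,0.28,30,post_minus_pre,inconsistent: printed change is negative under this convention
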