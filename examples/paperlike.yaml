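# Default study conditions for the matched hypertension case-control
# simulator: 342 sex/age-matched pairs aged 28-87, control-group-like
# population margins, log-odds exposure effects equal to the study's
# reported per-category odds ratios, and the interaction term calibrated
# (by root-finding) so the theoretical crude-table RERI equals 5.674.
#
#   addinter simulate --config examples/paperlike.yaml --out sim/ --seed 1

n_pairs: 342
seed: 0
p_fh: 0.617                 # family-history prevalence
bmi_mean: 23.46             # kg/m^2, continuous population BMI
bmi_sd: 3.18
beta0: -2.9444389791664403  # logit(0.05): baseline disease odds
beta_fh: 1.606633985101366  # log(4.986)
beta_low: 0.42395969074432877   # log(1.528)
beta_over: 1.2038727993256026   # log(3.333)
beta_obese: 1.989516834151849   # log(7.312)
age_mean: 62.0
age_sd: 10.7
age_range: [28.0, 87.0]
height_mean:
  male: 168.0
  female: 158.5
height_sd: 6.0
wc_mean: 83.7               # waist circumference, cm
wc_sd: 9.96
hc_mean: 92.8               # hip circumference, cm
hc_sd: 9.26
bmi_anthro_corr: 0.8        # correlation of BMI with waist/hip
fh_bmi_association: 1.0     # odds-scale FH<->abnormal-BMI association
target_reri: 5.674          # beta_int is root-found to hit this RERI
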