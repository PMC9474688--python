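# Calibration of the statistical cohort generator: per-method anteversion
# moments and their correlation with postoperative stem anteversion (PSA),
# as reported for the 28-hip DDH reference cohort.  diff_* are the printed
# (method - PSA) difference moments, carried for the worked-example checks.
psa:
  mean: 29.8
  sd: 17.7
methods:
  am_ct_5:  {method: AM-CT, height_mm: 5,  mean: 31.8, sd: 15.3, r: 0.86, diff_mean: 1.9,   diff_sd: 8.8}
  am_ct_10: {method: AM-CT, height_mm: 10, mean: 26.8, sd: 14.9, r: 0.92, diff_mean: -3.0,  diff_sd: 7.1}
  am_3d_5:  {method: AM-3D, height_mm: 5,  mean: 18.3, sd: 12.5, r: 0.71, diff_mean: -11.6, diff_sd: 12.5}
  am_3d_10: {method: AM-3D, height_mm: 10, mean: 16.9, sd: 12.3, r: 0.61, diff_mean: -12.9, diff_sd: 14.2}
  at_3d_5:  {method: AT-3D, height_mm: 5,  mean: 45.2, sd: 17.5, r: 0.56, diff_mean: 15.4,  diff_sd: 16.5}
  at_3d_10: {method: AT-3D, height_mm: 10, mean: 37.6, sd: 15.2, r: 0.57, diff_mean: 7.8,   diff_sd: 15.5}
cohort:
  n: 28
generator:
  stem_noise_sd_deg: 5.0
  nfa_bounds_deg: [-10.0, 70.0]
  rater_noise_sd_deg: 2.0
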