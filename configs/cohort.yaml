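# Synthetic cohort generator: study conditions (baseline grade mix and
# covariate distributions per grade stratum; missingness fractions).
n_patients: 5000
follow_up_years_range: [0.0, 18.0]
visit_spacing_months: 12
baseline_grade_probs: [0.938, 0.051, 0.011]
male_fraction: 0.539
hba1c_mean_sd: {0: [55.7, 17.1], 1: [60.9, 19.7], 2: [70.4, 19.4]}
sbp_mean_sd: {0: [142.5, 20.1], 1: [145.2, 22.3], 2: [149.1, 20.5]}
age_mean_sd: {0: [60.3, 10.8], 1: [61.2, 10.8], 2: [60.0, 9.9]}
duration_median_iqr: {0: [0.8, [0.2, 2.9]], 1: [2.11, [0.3, 7.1]], 2: [5.8, [1.5, 13.6]]}
missing_grade_nonstr: 0.122
str_gap_fraction: 0.22
missing_hba1c: 0.017
missing_sbp: 0.020
missing_duration: 0.010
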