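# Personalised screening-interval model: Weibull proportional-hazards
# cumulative incidence of sight-threatening retinopathy, time in months.
# F(t|x) = 1 - exp(-exp(beta'x) * t^shape); covariates on the log scale.
# Default calibration shipped with retiscreen (see docs/methods.md).
shape: 1.6
coefficients:
  intercept: -23.0
  male: 0.15
  log_duration: 0.35
  log_hba1c: 1.8
  log_sbp: 1.3
  retinopathy_present: 1.2
min_interval_months: 6
max_interval_months: 60
snap_to_menu: false
menu_months: [6, 12, 24, 36, 48, 60]
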