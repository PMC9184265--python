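# Example model-registry configuration.
#
# group_risks attach development-study positivity rates to categorical
# model groups, enabling their calibration metrics.  The numbers below are
# SYNTHETIC placeholders shaped like development-study tables; replace them
# with the rates reported by each model's source study.
group_risks:
  gnanapragasam: {1: 0.01, 2: 0.03, 3: 0.08, 4: 0.20, 5: 0.45}
  isup: {1: 0.01, 2: 0.04, 3: 0.10, 4: 0.22, 5: 0.40}
  lai: {0: 0.02, 1: 0.10, 2: 0.25, 3: 0.60}

# Synthetic PSA -> probability lookup standing in for the Chybowski curve.
chybowski_curve:
  - [2.0, 0.005]
  - [10.0, 0.03]
  - [20.0, 0.10]
  - [50.0, 0.40]
  - [100.0, 0.75]

# Logistic coefficients for the Ho model's continuous form (synthetic
# placeholder; the published equation is not reproduced here).
ho_coefficients:
  intercept: -3.0
  ln_psa: 0.9
  n_stage_positive: 2.0

# Follow the published Wang rule direction (scan when D < 0); set true to
# invert it.
wang_invert: false
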