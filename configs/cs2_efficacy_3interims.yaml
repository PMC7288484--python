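# Binary case study: BALTI-2 redesign, efficacy-only stopping (P_curr > 0.99)
# with three evenly spaced interims (334, 667, 1001 of 1334 patients) and a
# final success bar Pr(theta_int < theta_ctrl | data) > 0.98.
design:
  endpoint: binary
  n_max: 1334
  n_interims: 3
  efficacy_threshold: 0.99
  futility_threshold: null
  final_success_threshold: 0.98
  accrual_rate: 2.0
  n_imputations: 500
scenarios:
  - {label: "null", control_rate: 0.44, intervention_rate: 0.44}
  - {label: "target", control_rate: 0.44, intervention_rate: 0.35}
n_sims: 10000
seed: 0
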