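# Binary case study: futility-only stopping (P_max < 0.10) with three evenly
# spaced interims.
design:
  endpoint: binary
  n_max: 1334
  n_interims: 3
  efficacy_threshold: null
  futility_threshold: 0.10
  final_success_threshold: 0.98
  accrual_rate: 2.0
  n_imputations: 500
scenarios:
  - {label: "null", control_rate: 0.44, intervention_rate: 0.44}
  - {label: "target", control_rate: 0.44, intervention_rate: 0.35}
n_sims: 10000
seed: 0
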