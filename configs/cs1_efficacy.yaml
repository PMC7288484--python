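# Time-to-event case study: one interim at 100 of 200 events that may stop
# early for efficacy; success requires Pr(HR < 1 | data) > 0.9 at either look.
design:
  endpoint: tte
  total_events: 200
  interim_events: 100
  interim_rule: efficacy
  final_success_threshold: 0.9
scenarios:
  - {label: null_hr, hr: 1.0}
  - {label: hr09, hr: 0.9}
  - {label: hr08, hr: 0.8}
  - {label: target_hr, hr: 0.7}
n_sims: 1000000
seed: 0
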