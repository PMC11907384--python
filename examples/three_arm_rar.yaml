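spec_version: 1
name: example-3arm-rar
comparison: all_vs_all
direction: lower_better
arms:
- name: A
  is_control: false
  initial_allocation: 0.3333333333333333
- name: B
  is_control: false
  initial_allocation: 0.3333333333333333
- name: C
  is_control: false
  initial_allocation: 0.3333333333333333
stopping:
  superiority_threshold: 0.9902
  inferiority_threshold: 0.0098
  equivalence_margin: 0.05
  equivalence_prob_threshold: 0.9
  futility_margin: null
  futility_prob_threshold: null
  equivalence_vs_promoted_controls: false
allocation:
  mode: rar
  softening_gamma: 0.5
  min_allocation: 0.1
  max_allocation: 1.0
first_look_n: 500
look_interval_n: 300
max_n: 8000
followup_days: 30.0
data_verification_days: 15.0
prior_alpha: 1.0
prior_beta: 1.0
scenarios:
- label: 'null'
  true_event_probs:
  - 0.25
  - 0.25
  - 0.25
  accrual_rate: 10.0
- label: one-better
  true_event_probs:
  - 0.25
  - 0.25
  - 0.18
  accrual_rate: 10.0
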