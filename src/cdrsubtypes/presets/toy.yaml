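n_patients: 300
subtypes:
- name: healthy
  targets:
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  sd: 0.05
- name: mild
  targets:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  sd: 0.05
- name: severe
  targets:
  - 3.0
  - 3.0
  - 3.0
  - 3.0
  - 3.0
  - 3.0
  sd: 0.05
mixing:
- 0.4
- 0.35
- 0.25
markov:
- - 0.65
  - 0.26249999999999996
  - 0.0875
- - 0.05
  - 0.6875
  - 0.26249999999999996
- - 0.0
  - 0.05
  - 0.95
visit_count_dist:
  1: 0.5
  2: 0.3
  3: 0.1
  4: 0.06
  5: 0.04
interval_mean_months: 8.8
interval_sd_months: 3.6
component_missingness: 0.0
cognitive_missingness: 0.0
cognitive_model:
  boston_naming:
    intercept: 15.0
    slope: -6.0
    sd: 1.5
  mmse:
    intercept: 29.0
    slope: -16.0
    sd: 2.5
  short_blessed:
    intercept: 2.0
    slope: 22.0
    sd: 3.0
  word_list_memory:
    intercept: 18.0
    slope: -10.0
    sd: 2.0
  verbal_fluency:
    intercept: 15.0
    slope: -8.0
    sd: 2.0
first_visit: '2014-06-01'
enrollment_window_days: 1095
seed: 0
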