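n_patients: 1845
subtypes:
- name: C2
  targets:
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  sd: 0.35
- name: C9
  targets:
  - 0.5
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  sd: 0.3
- name: C4
  targets:
  - 0.5
  - 0.5
  - 0.5
  - 0.5
  - 0.5
  - 0.0
  sd: 0.3
- name: C7
  targets:
  - 1.0
  - 1.0
  - 0.5
  - 0.5
  - 0.5
  - 0.0
  sd: 0.35
- name: C5
  targets:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 0.5
  sd: 0.35
- name: C8
  targets:
  - 1.0
  - 1.0
  - 2.0
  - 2.0
  - 2.0
  - 0.5
  sd: 0.3
- name: C6
  targets:
  - 1.5
  - 1.5
  - 2.0
  - 2.0
  - 2.0
  - 1.0
  sd: 0.4
- name: C10
  targets:
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 1.0
  sd: 0.35
- name: C3
  targets:
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  sd: 0.3
- name: C1
  targets:
  - 3.0
  - 3.0
  - 3.0
  - 3.0
  - 3.0
  - 2.5
  sd: 0.4
mixing:
- 0.105149
- 0.210298
- 0.152304
- 0.158808
- 0.163144
- 0.025474
- 0.027642
- 0.039566
- 0.085637
- 0.031978
markov:
- - 0.47000000000000003
  - 0.159
  - 0.1855
  - 0.1855
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.07
  - 0.4
  - 0.159
  - 0.1855
  - 0.1855
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.07
  - 0.4
  - 0.159
  - 0.1855
  - 0.1855
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.07
  - 0.4
  - 0.159
  - 0.1855
  - 0.1855
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.07
  - 0.4
  - 0.159
  - 0.1855
  - 0.1855
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.07
  - 0.4
  - 0.159
  - 0.1855
  - 0.1855
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.07
  - 0.4
  - 0.159
  - 0.1855
  - 0.1855
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.07
  - 0.5855
  - 0.159
  - 0.1855
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.07
  - 0.771
  - 0.159
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.07
  - 0.93
visit_count_dist:
  1: 0.5166
  2: 0.4592
  3: 0.0145
  4: 0.0063
  5: 0.0034
interval_mean_months: 8.8
interval_sd_months: 3.6
component_missingness: 0.01
cognitive_missingness: 0.04
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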