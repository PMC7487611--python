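factors:
- lipids
- anthropometric
- risky_behaviour
- comorbidities
- quality_of_life
- healthy_lifestyle
indicators:
- name: hdl
  factor: lipids
  scale: continuous
  loading_fixed: 1.0
- name: ldl
  factor: lipids
  scale: continuous
- name: tg
  factor: lipids
  scale: continuous
- name: tcho
  factor: lipids
  scale: continuous
- name: hc
  factor: anthropometric
  scale: continuous
  loading_fixed: 1.0
- name: wc
  factor: anthropometric
  scale: continuous
- name: bmi
  factor: anthropometric
  scale: continuous
- name: smoking
  factor: risky_behaviour
  scale: binary
  loading_fixed: 1.0
- name: depression_anxiety
  factor: risky_behaviour
  scale: continuous
- name: unhealthy_diet
  factor: risky_behaviour
  scale: continuous
- name: dm
  factor: comorbidities
  scale: binary
  loading_fixed: 1.0
- name: bp
  factor: comorbidities
  scale: binary
- name: qol_environmental
  factor: quality_of_life
  scale: continuous
  loading_fixed: 1.0
- name: qol_social
  factor: quality_of_life
  scale: continuous
- name: qol_mental
  factor: quality_of_life
  scale: continuous
- name: qol_physical
  factor: quality_of_life
  scale: continuous
- name: physical_activity
  factor: healthy_lifestyle
  scale: continuous
  loading_fixed: 1.0
- name: healthy_diet
  factor: healthy_lifestyle
  scale: continuous
covariates:
- name: age
  scale: continuous
- name: sex
  scale: binary
- name: family_history
  scale: binary
outcome: total_cvd
outcome_label: total_cvd
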