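funnel:
  base_population: 6795374
  stages:
  - - angina_pectoris
    - 0.036167398586155815
  - - refractory_angina
    - 0.12
  - - eligible_for_reducer
    - 0.6
current_mix:
  device_share_year1: 0.01
  annual_increment: 0.0
  years: 5
revised_mix:
  device_share_year1: 0.015
  annual_increment: 0.0035
  years: 5
costs:
  reducer_implant: 7000.0
  elective_pci: 6434.0
  hospitalization: 1870.0
  outpatient_visit: 88.06
  ed_admission: 193.0
  coronarography: 2142.0
drugs:
- name: beta_blockers
  annual_cost: 27.29
  usage_rate: 0.782
- name: calcium_channel_blockers
  annual_cost: 114.04
  usage_rate: 0.545
- name: nitrates
  annual_cost: 37.41
  usage_rate: 0.665
- name: ivabradine
  annual_cost: 78.19
  usage_rate: 0.181
- name: ranolazine
  annual_cost: 827.32
  usage_rate: 0.319
hru:
  reducer:
    hospitalizations: 1.0
    ed_admissions: 0.1
    coronarographies: 0.2
    outpatient_visits: 0.7
    pci: 0.1
    distribution_family: normal
  soc:
    hospitalizations: 3.4
    ed_admissions: 0.2
    coronarographies: 1.0
    outpatient_visits: 2.1
    pci: 0.3
    distribution_family: normal
tree:
  cohort_size: 10000
  p_success: 0.9451
  utility_success: 0.594
  utility_soc: 0.456
  annual_survival_reducer:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  annual_survival_soc:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  annual_cost_reducer_year1: 15702.0
  annual_cost_reducer_later: 2550.0
  annual_cost_soc: 6988.0
  distribution_family_probabilities: beta
  distribution_family_costs: normal
discount:
  rate: 0.035
  apply_to_costs: true
  apply_to_outcomes: true
  first_year_discounted: false
uncertainty:
  relative_sd: 0.15
  n_draws: 1000
  seed: 12345
  dsa_delta: 0.15
horizon_years: 5
annual_incident_eligible: 0.0
annual_mortality: 0.0
drug_reduction_on_reducer: 0.0
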