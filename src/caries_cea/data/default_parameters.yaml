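# Default parameter set for the school-based caries-prevention CEA.
# Costs in ZAR per learner per year at constant 2022 prices; effectiveness
# as percent DMFT reduction. Missing annual_cost_sd values are filled with
# 10% of the mean at load time.
model:
  cohort_size: 10000
  start_age: 5
  exit_age: 15
  discount_rate: 0.05
  prob_untreated: 0.7
  prob_recurrence: 0.188
  dmft_growth: 0.0059
  sugar_slope: 0.0128
  sugar_reduction: 30.0
  screening_cost: 525.61
  wtp: 38500.0
  sugar_mechanism: offset
  effect_mechanism: flow
  exit_first: true
interventions:
  - name: apf_gel
    annual_cost_mean: 193.73
    effect_mean: 21.0
    effect_sd: 4.0
    requires_screening: true
  - name: fissure_sealant
    annual_cost_mean: 59.71
    effect_mean: 50.0
    effect_sd: 8.0
    requires_screening: true
  - name: art
    annual_cost_mean: 89.24
    effect_mean: 72.0
    effect_sd: 25.0
    requires_screening: true
  - name: tooth_brushing
    annual_cost_mean: 548.33
    annual_cost_sd: 544.29
    effect_mean: 60.0
    effect_sd: 47.0
    requires_screening: true
  - name: sugar_reduction
    annual_cost_mean: 1.25
    effect_mean: 31.89
    effect_sd: 0.18
    requires_screening: false
    is_sugar_policy: true
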