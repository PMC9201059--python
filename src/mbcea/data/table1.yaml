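# Base-case parameter set for the recurrent pediatric medulloblastoma
# cost-effectiveness model: triplet temozolomide + irinotecan + bevacizumab
# (tib) versus doublet temozolomide + irinotecan (ti).
# All monetary values in USD (converted at 6.437 CNY per USD, March 2022).

economic:
  annual_discount_rate: 0.03        # fraction/year, applied to costs and QALYs
  wtp_threshold: 38136.26           # USD/QALY, 3x China's per-capita GDP
  exchange_rate: 6.437              # CNY per USD
  cycle_length: 1                   # months
  horizon_cycles: 120               # 10 years of monthly cycles
  termination_fraction: 0.99        # stop once 99% of the cohort has died
  psa_iterations: 1000

arms:
  tib:
    name: "T+I+B"
    median_efs: 9                   # months
    median_os: 19                   # months
    drug_components:                # USD per 28-day course
      tmz: 343.75
      irt: 576.15
      bev: 1883.83
    drug_cost_per_cycle: 2803.73    # component sum; printed total
    second_line_cost_per_cycle: 233.11
    hospitalization_cost_per_cycle: 43.96
    ae_cost_per_cycle: 10.09        # grade 3-4 adverse event management
    tests_cost_per_cycle: 185.63    # MRI, biochemistry, etc.
    max_treatment_cycles: 12
  ti:
    name: "T+I"
    median_efs: 6
    median_os: 13
    drug_components:
      tmz: 343.75
      irt: 576.15
    drug_cost_per_cycle: 919.90
    second_line_cost_per_cycle: 305.67
    hospitalization_cost_per_cycle: 43.96
    ae_cost_per_cycle: 13.87
    tests_cost_per_cycle: 176.56
    max_treatment_cycles: 12

utilities:                          # annual QALY weights
  u_efs: 0.89
  u_pd: 0.73
  u_death: 0.0

dosing:                             # triplet schedule per 28-day course
  tmz_dose: 50                      # mg/m^2/day
  tmz_days: 5
  irt_dose: 50                      # mg/m^2/day
  irt_days: 5
  bev_dose: 10                      # mg/kg/administration, days 1 and 15
  bev_administrations_per_cycle: 2

patient_weight_kg: 40.0             # illustrative dosing weight
survival_shape: 1.0                 # Weibull shape; 1 = exponential base case
structural_mode: transition         # 3-state transition model; or "partitioned"
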