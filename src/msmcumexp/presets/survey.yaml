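# Full-realism six-wave survey scenario (the generator defaults, spelled out):
# 2,690 entrants, interior attrition matching the motivating cohort's pattern,
# 7% covariate item non-response, baseline-user and outcome-non-response
# exclusions, continuous frequency outcomes.
n: 2690
waves: [1, 2, 3, 6, 8, 9]
primary_practice: short_sleep
cutoffs: {short_sleep: 8.0, social_jetlag: 1.0, disturbance: 0.0}
p_baseline: 0.5
p_l0: 0.3
conf_intercept: 0.2
conf_autocorr: 0.25
conf_feedback: 0.25
exp_intercepts: [-0.45, -0.10, 0.22, -0.78, -0.91]
exp_on_lag: 0.5
exp_on_confounder: 1.3
exp_on_baseline: 0.3
exp_on_others: 0.0
outcomes:
  cigarette: {intercept: 0.0, slope: 0.30, confounder: 1.5, baseline: 0.25, sd: 1.4}
  alcohol: {intercept: 0.3, slope: 0.12, confounder: 1.0, baseline: 0.20, sd: 1.45}
ordinal_outcome: false
attrition:
  base_logit: [6.05, 4.95, 1.56, 1.79]
  on_lag_exposure: -0.2
  on_lag_confounder: -0.4
  on_baseline: 0.0
  monotone: true
miss_rate: 0.07
baseline_use_rate: 0.0766
outcome_missing_rate: 0.2996
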