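# Same marginal dropout levels as attrition_informative but independent of
# every covariate: attrition weighting should then change nothing beyond
# Monte-Carlo noise.
n: 2000
primary_practice: short_sleep
p_baseline: 0.5
p_l0: 0.3
conf_intercept: 0.2
conf_autocorr: 0.25
conf_feedback: 0.25
exp_intercepts: [-0.45, -0.10, 0.22, -0.78, -0.91]
exp_on_lag: 0.5
exp_on_confounder: 1.3
exp_on_baseline: 0.3
outcomes:
  cigarette: {intercept: 0.0, slope: 0.30, confounder: 1.5, baseline: 0.25, sd: 1.4}
  alcohol: {intercept: 0.3, slope: 0.12, confounder: 1.0, baseline: 0.20, sd: 1.45}
attrition:
  base_logit: [8.0, 8.0, 1.0, 1.1]
  on_lag_exposure: 0.0
  on_lag_confounder: 0.0
  on_baseline: 0.0
  monotone: true
miss_rate: 0.0
baseline_use_rate: 0.0
outcome_missing_rate: 0.0
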