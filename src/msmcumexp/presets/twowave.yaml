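# Small two-exposure-wave scenario with hand-set coefficients, used for
# exact oracle-equivalence checks (the full counterfactual table has only
# four regimes and the g-formula enumerates a handful of branches).
n: 2000
waves: [1, 2, 3]
primary_practice: short_sleep
cutoffs: {short_sleep: 8.0, social_jetlag: 1.0, disturbance: 0.0}
p_baseline: 0.5
p_l0: 0.4
conf_intercept: 0.3
conf_autocorr: 0.2
conf_feedback: 0.3
exp_intercepts: [0.0, -0.2]
exp_on_lag: 0.4
exp_on_confounder: 0.8
exp_on_baseline: 0.3
other_intercepts:
  social_jetlag: [0.2, -0.3]
  disturbance: [-0.4, -0.3]
outcomes:
  cigarette: {intercept: 0.5, slope: 0.25, confounder: 0.9, baseline: 0.2, sd: 1.0}
  alcohol: {intercept: 0.3, slope: 0.10, confounder: 0.5, baseline: 0.2, sd: 1.2}
attrition: null
miss_rate: 0.0
baseline_use_rate: 0.0
outcome_missing_rate: 0.0
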