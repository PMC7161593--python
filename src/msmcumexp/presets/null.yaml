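# Null scenario: no causal effect, no exposure-confounder feedback, and no
# confounder effect on exposure — exposure is independent of the confounder
# path, so both the conventional fit and the MSM are unbiased for zero.
n: 1000
primary_practice: short_sleep
p_baseline: 0.5
p_l0: 0.3
conf_intercept: 0.2
conf_autocorr: 0.25
conf_feedback: 0.0
exp_intercepts: [-0.2, 0.0, 0.2, -0.4, -0.5]
exp_on_lag: 0.5
exp_on_confounder: 0.0
exp_on_baseline: 0.3
outcomes:
  cigarette: {intercept: 0.0, slope: 0.0, confounder: 0.8, baseline: 0.25, sd: 1.4}
  alcohol: {intercept: 0.3, slope: 0.0, confounder: 0.6, baseline: 0.20, sd: 1.45}
attrition: null
miss_rate: 0.0
baseline_use_rate: 0.0
outcome_missing_rate: 0.0
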