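# Published base-case inputs for the outpatient vs. inpatient total shoulder
# arthroplasty cost-utility model (costs in 2024 USD; ranges are the published
# plausible ranges, treated as 95% intervals by the sensitivity analyses).
#
# The `run` block records the model conventions selected by calibrating the
# documented convention toggles against the published base-case outcomes
# (see tsacea.calibration and docs/methods.md).
outpatient:
  start_age: {base: 66, low: 61, high: 71}
  c_primary: {base: 16941, low: 13553, high: 20329}
  c_readmission: {base: 4237, low: 3390, high: 5084}
  c_revision: {base: 46942, low: 33588, high: 50382}
  p_readmission_90d: {base: 0.036, low: 0.028, high: 0.046}
  p_revision_total: {base: 0.036, low: 0.023, high: 0.038}
inpatient:
  start_age: {base: 70, low: 65, high: 75}
  c_primary: {base: 20584, low: 16467, high: 24701}
  c_readmission: {base: 4237, low: 3390, high: 5084}
  c_revision: {base: 46942, low: 33588, high: 50382}
  p_readmission_90d: {base: 0.052, low: 0.046, high: 0.069}
  p_revision_total: {base: 0.051, low: 0.038, high: 0.057}
utilities:
  u_well: {base: 0.87, low: 0.78, high: 0.96}
  u_post_revision: {base: 0.75, low: 0.68, high: 0.83}
  u_acute_event: {base: 0.52, low: 0.46, high: 0.60}
run:
  horizon_years: 20
  discount_rate_annual: 0.03
  wtp: 100000
  periop_window_cycles: 3
  revision_spread_mode: annual_window
  revision_window_years: 2
  half_cycle_correction: true
  cycle0_utility: true
  common_cohort_age: 66
  psa_iterations: 5000
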