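"""One-way deterministic sensitivity analysis (tornado diagram).

Each cost, probability and utility is moved to the ends of its published
range (shared parameters in both arms at once) while everything else stays at
base, and the swing in incremental net monetary benefit is recorded.
"""

import tsacea

arms, utilities, cfg = tsacea.load_published_parameters()
lt = tsacea.us2021_synthetic()

tor = tsacea.run_tornado(arms, utilities, cfg, lt)

print(f"base-case INMB: ${tor.base_inmb:,.0f} at ${tor.wtp:,.0f}/QALY\n")
print(tor.table[["parameter", "low", "high", "inmb_low", "inmb_high", "swing"]]
      .to_string(index=False))
# A primary-surgery cost enters only as an undiscounted cycle-0 charge of one
# arm, so its INMB swing equals its range width exactly — a built-in analytic
# check.  INMB staying positive at both ends of every bar means the outpatient
# strategy stays cost-effective across all one-way scenarios.
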