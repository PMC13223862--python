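"""Deterministic base case: run both cohorts and compare.

Loads the packaged published parameter table and the packaged synthetic
2021-US-like life table, pushes each strategy's cohort through 240 monthly
cycles, and prints discounted totals and the incremental comparison.
"""

import tsacea

arms, utilities, cfg = tsacea.load_published_parameters()
lt = tsacea.us2021_synthetic()

res = tsacea.compare_arms(arms, utilities, cfg, lt)

print(f"{'':<14}{'cost (USD)':>12}{'QALYs':>10}")
print(f"{res.label_A:<14}{res.cost_A:>12,.0f}{res.qaly_A:>10.3f}")
print(f"{res.label_B:<14}{res.cost_B:>12,.0f}{res.qaly_B:>10.3f}")
print(f"incremental  {res.delta_cost:>12,.0f}{res.delta_qaly:>10.4f}")
print(f"ICER: {res.icer}   INMB at ${res.wtp:,.0f}/QALY: ${res.inmb:,.0f}")
print(f"verdict: {res.verdict}")
# A negative incremental cost with a positive QALY gain means the outpatient
# strategy is cheaper AND more effective (dominant), so no ICER ratio applies.

for off, r in tsacea.age_scenarios(arms, utilities, cfg, lt, offsets=[-5, 0, 5]):
    print(f"age offset {off:+d}y: dCost {r.delta_cost:>8,.0f}  dQALY {r.delta_qaly:.4f}"
          f"  ({r.verdict})")
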