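"""Probabilistic sensitivity analysis: 5,000 Monte Carlo parameter draws.

Probabilities and utilities get Beta distributions, costs get Gamma, each fit
by method of moments to the published point estimate and range (treated as a
95% interval).  Shared inputs (utilities, readmission and revision costs) are
drawn once per iteration for both arms; arm-specific inputs independently.
"""

import tsacea

arms, utilities, cfg = tsacea.load_published_parameters()
lt = tsacea.us2021_synthetic()

psa = tsacea.run_psa(arms, utilities, cfg, lt, n_iterations=5000, seed=1)

print(f"{psa.n_iterations} iterations, seed {psa.seed}")
print(f"mean incremental cost : ${psa.mean_delta_cost:,.0f} "
      f"(95% UI {psa.ui_delta_cost[0]:,.0f} to {psa.ui_delta_cost[1]:,.0f})")
print(f"mean incremental QALYs: {psa.mean_delta_qaly:.4f} "
      f"(95% UI {psa.ui_delta_qaly[0]:.4f} to {psa.ui_delta_qaly[1]:.4f})")
print(f"cost-effective at ${psa.wtp:,.0f}/QALY: "
      f"{100 * psa.proportion_cost_effective:.1f}% of draws")
print(f"dominant (cheaper and more effective): "
      f"{100 * psa.proportion_dominant:.1f}% of draws")
print("CE-plane quadrants:", psa.quadrant_counts)
# The SE quadrant (more QALYs, lower cost) holding most of the mass is what
# "economically dominant" looks like on the cost-effectiveness plane.

curve = tsacea.ceac(psa, [0, 25_000, 50_000, 100_000, 150_000, 200_000])
print("\nacceptability curve (P(INMB>0) by willingness-to-pay):")
print(curve.to_string(index=False))
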