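"""Synthetic inputs with known answers: engine validation end to end.

A constant-hazard life table makes the discounted QALY total a geometric
series with a closed form; a Gompertz table mimics adult mortality curvature;
a perturbed copy of the published parameter table exercises validation; and
the recovery harness checks that the probabilistic analysis recovers the
deterministic truth.
"""

import tsacea

cfg = tsacea.load_published_parameters()[2]

flat = tsacea.make_life_table(
    tsacea.SyntheticMortalityLaw(law="constant_hazard", qx=0.02, age_min=40, age_max=130)
)
arms, utilities, flags = tsacea.make_parameter_set(seed=7, perturbation_scale=0.0)
quiet = arms[0].model_copy(
    update={
        "p_readmission_90d": tsacea.Ranged.point(0.0),
        "p_revision_total": tsacea.Ranged.point(0.0),
    }
)
trace = tsacea.run_cohort(quiet, utilities, cfg, flat)
oracle = tsacea.constant_hazard_qale(
    0.02, utilities.u_well.base, cfg.horizon_years, cfg.discount_rate_annual,
    half_cycle=cfg.half_cycle_correction, cycle0_utility=cfg.cycle0_utility,
)
print(f"engine QALYs {trace.total_qalys:.9f} vs closed form {oracle:.9f} "
      f"(diff {abs(trace.total_qalys - oracle):.2e})")

gomp = tsacea.make_life_table(
    tsacea.SyntheticMortalityLaw(law="gompertz", a=1e-4, b=0.09, age_min=50, age_max=100)
)
print(f"gompertz qx at 66: {gomp.annual_qx(66):.4f}, at 86: {gomp.annual_qx(86):.4f} "
      "(rises with age, as adult mortality does)")

report = tsacea.recovery_harness(arms, utilities, cfg, tsacea.us2021_synthetic(),
                                 n_psa=500, seed=3)
for k, v in report.items():
    print(f"{k}: {v}")
# mean_within_3se: the PSA mean incremental cost sits within Monte-Carlo noise
# of the deterministic base case; dominance_recovered: shrinking every range
# 100-fold collapses the PSA onto the dominant truth in every draw.
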