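# Methods

## Model structure and assumptions

The model is a discrete-time cohort state-transition (Markov) model with
monthly cycles over a 20-year horizon (240 cycles, truncated exactly).
States: WELL, READMIT_TUNNEL, REVISION_TUNNEL (tunnels: maximum occupancy
one cycle), POST_REVISION (permanent), DEATH (absorbing). Assumptions:

- Background mortality only, from an age-indexed life table; the monthly
  death probability at exact age *a* is `1 − (1 − qx(⌊a⌋))^(1/12)`
  (constant hazard within each year of age). Ages beyond the table's last
  row die with certainty within the year (terminal closure, enforced by the
  loader). Age advances continuously, `start_age + cycle/12`.
- Event risks are conditional on surviving the cycle: the death probability
  is applied first, then readmission and revision hazards compete
  independently on the surviving fraction, with the joint mass assigned to
  revision (the costlier path; the product term is O(10⁻⁴)).
- Readmission leaves no lasting effect: tunnel survivors return to WELL.
  Acute-revision survivors move to POST_REVISION and stay (no re-revision
  state). Neither implant type nor patient covariates are modeled.
- No revision or readmission risk originates outside WELL.

## Accounting

The primary procedure cost is charged undiscounted at cycle 0. One-time
event costs are charged at the cycle of tunnel entry, weighted by entering
probability mass, discounted at `(1 + r)^(−t/12)` with r = 0.03/yr. QALYs
accrue per cycle as occupancy·utility/12, discounted the same way. Two
toggles cover conventions decision-modeling tools differ on: a half-cycle
correction (average adjacent occupancies) and cycle-0 utility accrual (one
month of well-state utility at t = 0). Totals are accumulated in cycle
order; the batch (vectorized) and single-cohort code paths share one
implementation and agree bit-for-bit.

## Parameters

All inputs live in `data/params_published.yaml` (2024 USD): primary surgery
$16,941 (OP) / $20,584 (IP); readmission $4,237 and revision $46,942 (shared
by both arms); 90-day readmission probability 3.6% / 5.2%; total revision
probability 3.6% / 5.1%; utilities 0.87 (well), 0.75 (post-revision), 0.52
(acute tunnel month), 0 (death); starting ages 66 / 70; WTP $100,000/QALY.
Each value carries its published plausible range. The two published tunnel
utilities are identical with the same source and are modeled as one shared
parameter.

The 90-day readmission probability is spread over the 3 perioperative
cycles via `1 − (1 − p)^(1/3)`. For revision, the published total's time
reference is not stated, so three spread modes are exposed:
`horizon_constant_hazard` (cumulative over the horizon → constant monthly
hazard via `1 − (1 − p)^(1/240)`), `annual` (an annual probability applied
every year), and `annual_window` (an annual probability applied only during
the first W post-operative years — motivated by the short follow-up of the
comparative evidence the estimates come from, after the first two modes
proved unable to reproduce the published cost side; see Calibration).

## Uncertainty analysis

Ranges are treated as 95% intervals, SE = (high − low)/3.92. Probabilities
and utilities get method-of-moments Beta fits (`ν = m(1−m)/var − 1`), costs
get Gamma (`shape = (m/SE)², scale = SE²/m`); zero-width ranges become point
masses. Per PSA iteration one joint draw is taken: utilities and the shared
event costs once for both arms; each arm's primary cost and probabilities
independently. Ages are not varied in the PSA (they are handled by the
explicit ±5-year scenario analysis). Draws use `numpy.random.default_rng`
with a fixed draw order, so a seed pins the full output. Uncertainty
intervals are empirical 2.5/97.5 percentiles. The tornado analysis moves one
inventory parameter at a time to its range ends (shared parameters in both
arms simultaneously) and reports the absolute INMB swing, descending; the
INMB sign convention is outpatient-positive.

## Calibration of unstated conventions

The published analysis was built in commercial software and does not state
its revision spreading, half-cycle, or cycle-0 conventions; additionally its
reported QALY pair (10.436 vs. 10.427) differs by only 0.009 despite per-arm
starting ages of 66/70 — a spread no monotone life table can produce, which
only a shared cohort age can. `calibrate_conventions` therefore grids over
{spread mode × window years × half-cycle × cycle-0 × cohort-age choice} and
scores each candidate by a tolerance-normalized discrepancy over the six
published base-case quantities (|error|/3% for the three cost quantities,
|error|/0.05 QALYs for the three QALY quantities). The winner — annual
revision probability over a 2-year window, half-cycle on, cycle-0 accrual
on, shared cohort age 66 — is frozen in the packaged run config.

What reproduces and what does not: the incremental quantities land close
(ΔC −$4,989 vs. −$5,027; ΔE 0.038 vs. 0.009, within 0.05), and the two
primary-cost tornado swings are exact by construction ($8,234 / $6,776). The
arm-level costs and QALYs do not: the published arm costs imply ≈0.134
expected discounted revisions per outpatient (≈4.5× what the published ΔE
and revision-swing figures imply), and the published QALY level needs a
discounted 20-year QALE of ≈12.0 life-years at age 66, more than the 2021
all-population life table yields even with zero events (≈11.6). These two
internal tensions cannot be closed simultaneously by any convention here;
the package reports its honestly computed values instead.

## Synthetic data

The synthetic module emulates (a) the mortality input — a constant-hazard
law, under which the engine's discounted QALY total is a geometric series
with closed form (`constant_hazard_qale`, the analytic oracle), and a
Gompertz law (`qx(age) = 1 − exp(−a·e^{b·age}(e^b−1)/b)`) mimicking adult
mortality curvature — and (b) perturbed copies of the published parameter
table (one lognormal factor per parameter triple, deterministic per seed,
out-of-bound values clipped with flags). The packaged "2021-US-like" table
is itself synthetic (log-linear interpolation between remembered 5-year
anchors). Synthetic inputs pass the same validators as real ones. Passing
tests therefore demonstrate internal correctness of the engine and analyses,
not fidelity of any synthetic table to actual U.S. mortality — exact
reproduction of mortality-dependent levels requires a genuine life-table
CSV.

## Numerical choices and sizes

Row sums of transition matrices hold to 1e−12 and occupancy conservation to
1e−10; the geometric oracle is checked at 1e−9 relative. INMB = 0 is
declared a tie; a dominated/dominant ΔC–ΔE sign pattern reports a sentinel
instead of a negative ICER, and ΔE = 0 reports "undefined". Default sizes:
240 cycles per cohort (<10 ms), 5,000 PSA iterations (vectorized across
draws, ≈0.1 s), 10⁵ walkers in the individual-level cross-check (≈1 s),
calibration grid ≈1,400 cohort runs (≈4 s).

## Known limitations

- Results at the published parameter values depend on the synthetic life
  table's fidelity; swap in a genuine table for serious use.
- No re-revision pathway, implant stratification, perioperative mortality
  differential, or covariate heterogeneity.
- PSA correlation structure (shared vs. independent draws) follows the
  published inputs' sharing pattern but is not verifiable from the source;
  the reported PSA spread is accordingly tighter than the published one.
- Exactly two strategies; no multi-strategy efficiency frontier.
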