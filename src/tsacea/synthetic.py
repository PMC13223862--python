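"""Synthetic inputs with known structure, for testing every pipeline stage.

Two mortality laws generate life tables that pass the same validators as real
ones: a constant annual hazard (which makes the engine's discounted totals a
geometric series with a closed form, used as an analytic oracle) and a
Gompertz law (hazard ``a * exp(b * age)``), which mimics the curvature of
adult human mortality.  ``make_parameter_set`` produces perturbed copies of
the published parameter table, and ``recovery_harness`` runs the whole
pipeline on synthetic inputs and checks that the probabilistic analysis
recovers the deterministic truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cea import compare_arms
from .life_tables import LifeTable
from .parameters import Ranged, RunConfig, StrategyParams, UtilitySet
from .uncertainty import run_psa

__all__ = [
    "SyntheticMortalityLaw",
    "make_life_table",
    "constant_hazard_qale",
    "make_parameter_set",
    "recovery_harness",
]


@dataclass(frozen=True)
class SyntheticMortalityLaw:
    """Parametric annual mortality: ``constant`` qx or Gompertz.

    Gompertz: with hazard ``a * exp(b * age)``, the annual death probability
    is ``qx(age) = 1 - exp(-a * exp(b*age) * (exp(b) - 1) / b)``.
    """

    law: str  # "constant_hazard" | "gompertz"
    age_min: int
    age_max: int
    qx: Optional[float] = None  # constant law
    a: Optional[float] = None  # gompertz baseline
    b: Optional[float] = None  # gompertz slope

    def annual_qx(self, age: np.ndarray) -> np.ndarray:
        if self.law == "constant_hazard":
            if self.qx is None or not (0.0 <= self.qx <= 1.0):
                raise ValueError("constant_hazard law needs qx in [0, 1]")
            return np.full_like(np.asarray(age, dtype=float), self.qx)
        if self.law == "gompertz":
            if self.a is None or self.b is None or self.a <= 0 or self.b <= 0:
                raise ValueError("gompertz law needs a > 0 and b > 0")
            age = np.asarray(age, dtype=float)
            cum = self.a * np.exp(self.b * age) * (math.exp(self.b) - 1.0) / self.b
            return 1.0 - np.exp(-cum)
        raise ValueError(f"unknown law {self.law!r}")


def make_life_table(law: SyntheticMortalityLaw) -> LifeTable:
    """Tabulate a synthetic law as a LifeTable (terminal row closed at qx=1)."""
    if law.age_max <= law.age_min:
        raise ValueError("age_max must exceed age_min")
    ages = np.arange(law.age_min, law.age_max + 1)
    qx = law.annual_qx(ages)
    if np.any((qx < 0) | (qx > 1)):
        raise ValueError("law produced qx outside [0, 1] before terminal age")
    qx = qx.copy()
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def constant_hazard_qale(
    qx: float, utility: float, horizon_years: int, annual_rate: float,
    half_cycle: bool = False, cycle0_utility: bool = False,
) -> float:
    """Closed-form discounted QALY total for an event-free cohort under a
    constant annual death probability (geometric-series oracle).

    Monthly survival ``s = (1-qx)**(1/12)`` and discount ``x = (1+r)**(-1/12)``
    give end-of-cycle occupancy ``s**t``, so the total is
    ``(u/12) * sum_t (s*x)**t`` plus the optional cycle-0 and half-cycle terms.
    """
    s = (1.0 - qx) ** (1.0 / 12.0)
    x = (1.0 + annual_rate) ** (-1.0 / 12.0)
    g = s * x
    T = horizon_years * 12
    if g == 1.0:
        tail = float(T)
    else:
        tail = g * (1.0 - g**T) / (1.0 - g)
    total = utility / 12.0 * tail
    if half_cycle:
        # average of adjacent occupancies: (s^(t-1) + s^t)/2 discounted at t
        if g == 1.0:
            prev_tail = float(T)
        else:
            prev_tail = x * (1.0 - g**T) / (1.0 - g)
        total = utility / 12.0 * 0.5 * (tail + prev_tail)
    if cycle0_utility:
        total += utility / 12.0
    return total


_PUBLISHED_BASE = {
    "outpatient": dict(
        start_age=(66.0, 61.0, 71.0),
        c_primary=(16941.0, 13553.0, 20329.0),
        c_readmission=(4237.0, 3390.0, 5084.0),
        c_revision=(46942.0, 33588.0, 50382.0),
        p_readmission_90d=(0.036, 0.028, 0.046),
        p_revision_total=(0.036, 0.023, 0.038),
    ),
    "inpatient": dict(
        start_age=(70.0, 65.0, 75.0),
        c_primary=(20584.0, 16467.0, 24701.0),
        c_readmission=(4237.0, 3390.0, 5084.0),
        c_revision=(46942.0, 33588.0, 50382.0),
        p_readmission_90d=(0.052, 0.046, 0.069),
        p_revision_total=(0.051, 0.038, 0.057),
    ),
}
_PUBLISHED_UTILITIES = dict(
    u_well=(0.87, 0.78, 0.96),
    u_post_revision=(0.75, 0.68, 0.83),
    u_acute_event=(0.52, 0.46, 0.60),
)
_PROBABILITY_FIELDS = {"p_readmission_90d", "p_revision_total"}


def make_parameter_set(
    seed: int, perturbation_scale: float
) -> tuple[tuple[StrategyParams, StrategyParams], UtilitySet, list[str]]:
    """A published-table-shaped parameter set, multiplicatively perturbed.

    Each parameter's (base, low, high) triple is multiplied by one lognormal
    factor ``exp(scale * z)`` (preserving the ordering); probabilities and
    utilities whose perturbed values exceed 1 are clipped and flagged.  Scale
    0 returns the published values exactly.  Returns ``(arms, utilities,
    clipped_flags)``.
    """
    if perturbation_scale < 0:
        raise ValueError("perturbation_scale must be >= 0")
    rng = np.random.default_rng(seed)
    flags: list[str] = []

    def perturb(name: str, triple, bounded: bool) -> Ranged:
        factor = float(np.exp(perturbation_scale * rng.standard_normal()))
        base, low, high = (v * factor for v in triple)
        if bounded and high > 1.0:
            flags.append(name)
            base, low, high = min(base, 1.0), min(low, 1.0), 1.0
        return Ranged(base=base, low=low, high=high)

    arms = []
    for label, fields in _PUBLISHED_BASE.items():
        built = {}
        for fname, triple in fields.items():
            if fname == "start_age":
                built[fname] = Ranged(base=triple[0], low=triple[1], high=triple[2])
                continue
            built[fname] = perturb(
                f"{label}.{fname}", triple, bounded=fname in _PROBABILITY_FIELDS
            )
        arms.append(StrategyParams(label=label, **built))
    utilities = UtilitySet(
        **{
            fname: perturb(f"utilities.{fname}", triple, bounded=True)
            for fname, triple in _PUBLISHED_UTILITIES.items()
        }
    )
    return (arms[0], arms[1]), utilities, flags


def _shrink(r: Ranged, factor: float) -> Ranged:
    half_low = (r.base - r.low) * factor
    half_high = (r.high - r.base) * factor
    return Ranged(base=r.base, low=r.base - half_low, high=r.base + half_high)


def shrink_ranges(
    arms: tuple[StrategyParams, StrategyParams], utilities: UtilitySet, factor: float
) -> tuple[tuple[StrategyParams, StrategyParams], UtilitySet]:
    """Scale every plausible range toward its point estimate by ``factor``."""
    new_arms = []
    for arm in arms:
        updates = {
            f: _shrink(getattr(arm, f), factor)
            for f in (
                "c_primary",
                "c_readmission",
                "c_revision",
                "p_readmission_90d",
                "p_revision_total",
            )
        }
        new_arms.append(arm.model_copy(update=updates))
    utilities = utilities.model_copy(
        update={
            f: _shrink(getattr(utilities, f), factor)
            for f in ("u_well", "u_post_revision", "u_acute_event")
        }
    )
    return (new_arms[0], new_arms[1]), utilities


def recovery_harness(
    arms: tuple[StrategyParams, StrategyParams],
    utilities: UtilitySet,
    cfg: RunConfig,
    lt: LifeTable,
    n_psa: int = 500,
    seed: int = 0,
) -> dict:
    """Run base case + PSA on a known truth and check internal consistency.

    Checks: (1) the PSA mean incremental cost lies within 3 Monte-Carlo
    standard errors of the deterministic base-case incremental cost; (2) with
    every range shrunk 100-fold, a strictly dominant truth yields
    ``proportion_dominant == 1``.
    """
    base = compare_arms(arms, utilities, cfg, lt)
    psa = run_psa(arms, utilities, cfg, lt, n_iterations=n_psa, seed=seed)
    dc = psa.draws["delta_cost"].to_numpy()
    se = float(dc.std(ddof=1) / np.sqrt(len(dc)))
    mean_ok = abs(psa.mean_delta_cost - base.delta_cost) <= 3.0 * se

    report = {
        "base_delta_cost": base.delta_cost,
        "psa_mean_delta_cost": psa.mean_delta_cost,
        "mc_se_delta_cost": se,
        "mean_within_3se": bool(mean_ok),
        "base_verdict": base.verdict,
    }
    if base.verdict == "A_dominant":
        tight_arms, tight_util = shrink_ranges(arms, utilities, 0.01)
        tight = run_psa(tight_arms, tight_util, cfg, lt, n_iterations=n_psa, seed=seed)
        report["shrunk_proportion_dominant"] = tight.proportion_dominant
        report["dominance_recovered"] = tight.proportion_dominant == 1.0
    return report
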