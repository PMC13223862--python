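"""Probabilistic and one-way deterministic sensitivity analysis.

Distribution calibration follows standard health-economic practice: Beta
distributions for probabilities and utilities, Gamma for costs, both fit by
method of moments to the point estimate (mean) and the plausible range
treated as a 95% interval, so ``SE = (high - low) / 3.92``.  A zero-width
range yields a deterministic point mass.

The Monte Carlo PSA draws, per iteration, one joint parameter set: utilities
and the shared event costs (readmission, revision) are drawn once and applied
to both arms; each arm's primary cost and event probabilities are drawn
independently.  Both cohorts are then run and the incremental cost, QALYs and
net monetary benefit recorded.  The one-way tornado analysis instead moves
one parameter at a time to the ends of its range (in both arms at once for
shared parameters) and records the INMB swing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cea import compare_arms
from .life_tables import LifeTable
from .markov import run_cohort_batch
from .parameters import (
    RunConfig,
    SensitivityParameter,
    StrategyParams,
    UtilitySet,
    apply_override,
    parameter_inventory,
)

__all__ = [
    "CalibratedDistribution",
    "beta_from_mean_range",
    "gamma_from_mean_range",
    "PSAResult",
    "run_psa",
    "ceac",
    "TornadoResult",
    "run_tornado",
]

#: 95% interval width in standard-error units
_Z95_WIDTH = 3.92


@dataclass(frozen=True)
class CalibratedDistribution:
    """A sampling distribution fit to a point estimate and 95% range.

    ``kind`` is ``"beta"``, ``"gamma"`` or ``"point"`` (degenerate).  For
    beta, ``a``/``b`` are the shape parameters; for gamma, ``a`` is the shape
    and ``b`` the scale.
    """

    kind: str
    mean: float
    low: float
    high: float
    a: float = field(default=np.nan)
    b: float = field(default=np.nan)

    @property
    def sd(self) -> float:
        if self.kind == "point":
            return 0.0
        if self.kind == "beta":
            return float(np.sqrt(self.a * self.b / ((self.a + self.b) ** 2 * (self.a + self.b + 1))))
        return float(np.sqrt(self.a) * self.b)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, self.mean)
        if self.kind == "beta":
            return rng.beta(self.a, self.b, size=n)
        return rng.gamma(shape=self.a, scale=self.b, size=n)


def beta_from_mean_range(mean: float, low: float, high: float) -> CalibratedDistribution:
    """Method-of-moments Beta fit: variance ``((high-low)/3.92)**2``.

    ``nu = mean(1-mean)/var - 1``, ``a = mean*nu``, ``b = (1-mean)*nu``.
    """
    if not (low <= mean <= high):
        raise ValueError("need low <= mean <= high")
    if low == high:
        return CalibratedDistribution(kind="point", mean=mean, low=low, high=high)
    if not (0.0 < mean < 1.0):
        raise ValueError("beta calibration needs 0 < mean < 1")
    var = ((high - low) / _Z95_WIDTH) ** 2
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"range ({low}, {high}) too wide for a beta with mean {mean}; "
            "review the interval"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return CalibratedDistribution(
        kind="beta", mean=mean, low=low, high=high, a=mean * nu, b=(1.0 - mean) * nu
    )


def gamma_from_mean_range(mean: float, low: float, high: float) -> CalibratedDistribution:
    """Method-of-moments Gamma fit: ``shape=(mean/SE)**2``, ``scale=SE**2/mean``."""
    if not (low <= mean <= high):
        raise ValueError("need low <= mean <= high")
    if low == high:
        return CalibratedDistribution(kind="point", mean=mean, low=low, high=high)
    if mean <= 0:
        raise ValueError("gamma calibration needs mean > 0")
    se = (high - low) / _Z95_WIDTH
    return CalibratedDistribution(
        kind="gamma", mean=mean, low=low, high=high, a=(mean / se) ** 2, b=se**2 / mean
    )


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration incremental draws and their summaries.

    ``draws`` has columns ``iter, delta_cost, delta_qaly, inmb, quadrant,
    dominant, cost_effective`` (quadrants of the cost-effectiveness plane by
    the signs of the QALY and cost differences).
    """

    draws: pd.DataFrame
    wtp: float
    seed: int
    n_iterations: int
    mean_delta_cost: float
    mean_delta_qaly: float
    ui_delta_cost: tuple[float, float]  # 2.5/97.5 percentiles
    ui_delta_qaly: tuple[float, float]
    proportion_cost_effective: float
    proportion_dominant: float
    quadrant_counts: dict

    def summary(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "wtp": self.wtp,
            "mean_delta_cost": self.mean_delta_cost,
            "ui_delta_cost": list(self.ui_delta_cost),
            "mean_delta_qaly": self.mean_delta_qaly,
            "ui_delta_qaly": list(self.ui_delta_qaly),
            "proportion_cost_effective": self.proportion_cost_effective,
            "proportion_dominant": self.proportion_dominant,
            "quadrant_counts": dict(self.quadrant_counts),
        }


def _distributions(arm: StrategyParams):
    return {
        "c_primary": gamma_from_mean_range(
            arm.c_primary.base, arm.c_primary.low, arm.c_primary.high
        ),
        "p_readmission": beta_from_mean_range(
            arm.p_readmission_90d.base,
            arm.p_readmission_90d.low,
            arm.p_readmission_90d.high,
        ),
        "p_revision": beta_from_mean_range(
            arm.p_revision_total.base,
            arm.p_revision_total.low,
            arm.p_revision_total.high,
        ),
    }


def run_psa(
    arms: tuple[StrategyParams, StrategyParams],
    utilities: UtilitySet,
    cfg: RunConfig,
    lt: LifeTable,
    n_iterations: Optional[int] = None,
    seed: Optional[int] = None,
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Draw order is fixed (shared utilities, shared event costs, then each
    arm's primary cost and probabilities), so a given seed yields
    bit-identical results.
    """
    n = n_iterations if n_iterations is not None else cfg.psa_iterations
    if n < 1:
        raise ValueError("n_iterations must be >= 1")
    sd = seed if seed is not None else cfg.seed
    rng = np.random.default_rng(sd)

    u = utilities
    shared = {
        "u_well": beta_from_mean_range(u.u_well.base, u.u_well.low, u.u_well.high),
        "u_post": beta_from_mean_range(
            u.u_post_revision.base, u.u_post_revision.low, u.u_post_revision.high
        ),
        "u_acute": beta_from_mean_range(
            u.u_acute_event.base, u.u_acute_event.low, u.u_acute_event.high
        ),
        "c_readmission": gamma_from_mean_range(
            arms[0].c_readmission.base,
            arms[0].c_readmission.low,
            arms[0].c_readmission.high,
        ),
        "c_revision": gamma_from_mean_range(
            arms[0].c_revision.base, arms[0].c_revision.low, arms[0].c_revision.high
        ),
    }
    shared_draws = {k: d.sample(rng, n) for k, d in shared.items()}
    totals = {}
    for arm in arms:
        dists = _distributions(arm)
        draws = {k: d.sample(rng, n) for k, d in dists.items()}
        totals[arm.label] = run_cohort_batch(
            arm,
            cfg,
            lt,
            c_primary=draws["c_primary"],
            c_readmission=shared_draws["c_readmission"],
            c_revision=shared_draws["c_revision"],
            p_readmission=draws["p_readmission"],
            p_revision=draws["p_revision"],
            u_well=shared_draws["u_well"],
            u_post=shared_draws["u_post"],
            u_acute=shared_draws["u_acute"],
        )
    (cost_a, qaly_a), (cost_b, qaly_b) = totals[arms[0].label], totals[arms[1].label]
    dc = cost_a - cost_b
    dq = qaly_a - qaly_b
    inmb = cfg.wtp * dq - dc
    dominant = (dc < 0) & (dq > 0)
    cost_effective = inmb > 0
    quadrant = np.where(
        dq > 0,
        np.where(dc > 0, "NE", "SE"),
        np.where(dc > 0, "NW", "SW"),
    )
    draws_df = pd.DataFrame(
        {
            "iter": np.arange(n),
            "delta_cost": dc,
            "delta_qaly": dq,
            "inmb": inmb,
            "quadrant": quadrant,
            "dominant": dominant,
            "cost_effective": cost_effective,
        }
    )
    counts = draws_df["quadrant"].value_counts().to_dict()
    return PSAResult(
        draws=draws_df,
        wtp=cfg.wtp,
        seed=sd,
        n_iterations=n,
        mean_delta_cost=float(dc.mean()),
        mean_delta_qaly=float(dq.mean()),
        ui_delta_cost=(float(np.percentile(dc, 2.5)), float(np.percentile(dc, 97.5))),
        ui_delta_qaly=(float(np.percentile(dq, 2.5)), float(np.percentile(dq, 97.5))),
        proportion_cost_effective=float(cost_effective.mean()),
        proportion_dominant=float(dominant.mean()),
        quadrant_counts={q: int(counts.get(q, 0)) for q in ("NE", "SE", "NW", "SW")},
    )


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: P(INMB > 0) over a WTP grid."""
    wtps = np.asarray(list(wtp_grid), dtype=float)
    dc = psa.draws["delta_cost"].to_numpy()
    dq = psa.draws["delta_qaly"].to_numpy()
    probs = [float(((w * dq - dc) > 0).mean()) for w in wtps]
    return pd.DataFrame({"wtp": wtps, "probability_cost_effective": probs})


@dataclass(frozen=True)
class TornadoResult:
    """One-way sensitivity results, sorted by descending INMB swing.

    ``table`` columns: ``parameter, arm, low, high, inmb_low, inmb_high,
    swing, rank``.
    """

    table: pd.DataFrame
    base_inmb: float
    wtp: float


def run_tornado(
    arms: tuple[StrategyParams, StrategyParams],
    utilities: UtilitySet,
    cfg: RunConfig,
    lt: LifeTable,
    inventory: Optional[list[SensitivityParameter]] = None,
) -> TornadoResult:
    """Move each inventory parameter to its range ends, all else at base.

    Shared parameters move in both arms simultaneously.  The INMB sign
    convention follows :func:`tsacea.cea.compare`: positive favors the first
    (outpatient) arm.
    """
    if inventory is None:
        inventory = parameter_inventory(arms, utilities)
    base = compare_arms(arms, utilities, cfg, lt)
    rows = []
    for param in inventory:
        inmbs = {}
        for end, value in (("low", param.low), ("high", param.high)):
            arms2, util2 = apply_override(arms, utilities, param, value)
            inmbs[end] = compare_arms(arms2, util2, cfg, lt).inmb
        rows.append(
            {
                "parameter": param.name,
                "arm": param.arm,
                "low": param.low,
                "high": param.high,
                "inmb_low": inmbs["low"],
                "inmb_high": inmbs["high"],
                "swing": abs(inmbs["high"] - inmbs["low"]),
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values("swing", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return TornadoResult(table=table, base_inmb=base.inmb, wtp=cfg.wtp)
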