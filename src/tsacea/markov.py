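"""Cohort state-transition engine.

Five compartments: WELL, a one-cycle readmission tunnel, a one-cycle acute
revision tunnel, a permanent post-revision state, and absorbing DEATH.  The
cohort starts fully WELL, is charged the primary procedure cost at cycle 0,
and is pushed through monthly transition matrices for the configured horizon.
Background mortality comes from the life table at the cohort's current exact
age and is applied first each cycle; event risks act on the surviving
fraction (risks conditional on survival).  Readmission risk is active only
during the perioperative window; revision risk is spread per the configured
mode.  One-time event costs are charged, discounted, at the cycle of state
entry; utilities accrue per cycle occupancy at 1/12 year each.

The same core loop runs a single cohort (scalars) or a whole batch of
parameter draws (1-D arrays), which is what makes the probabilistic
sensitivity analysis cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .parameters import RunConfig, StrategyParams, UtilitySet

__all__ = [
    "State",
    "CohortTrace",
    "per_cycle_from_window",
    "discount_factor",
    "transition_matrix",
    "run_cohort",
    "run_cohort_batch",
    "simulate_individuals",
]


class State(IntEnum):
    WELL = 0
    READMIT_TUNNEL = 1
    REVISION_TUNNEL = 2
    POST_REVISION = 3
    DEATH = 4


N_STATES = len(State)


def per_cycle_from_window(p_window, n_cycles: int):
    """Constant per-cycle probability whose ``n_cycles``-fold compounding
    reproduces the window probability: ``1 - (1 - p)**(1/n)``."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    p = np.asarray(p_window, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("window probability must lie in [0, 1]")
    out = 1.0 - (1.0 - p) ** (1.0 / n_cycles)
    return float(out) if np.isscalar(p_window) else out


def discount_factor(cycle, annual_rate: float):
    """Present-value multiplier at ``cycle`` months: ``(1+r)**(-cycle/12)``."""
    return (1.0 + annual_rate) ** (-np.asarray(cycle, dtype=float) / 12.0)


def _revision_hazard(p_revision, cfg: RunConfig, cycle: int):
    """Monthly revision hazard active at transition out of ``cycle``."""
    mode = cfg.revision_spread_mode
    if mode == "horizon_constant_hazard":
        return per_cycle_from_window(p_revision, cfg.horizon_cycles)
    if mode == "annual":
        return per_cycle_from_window(p_revision, 12)
    # annual_window: annual probability active during the first W years
    if cycle < 12 * cfg.revision_window_years:
        return per_cycle_from_window(p_revision, 12)
    return np.zeros_like(np.asarray(p_revision, dtype=float)) if not np.isscalar(
        p_revision
    ) else 0.0


def _hazards(arm_p_readmit, arm_p_rev, cfg: RunConfig, lt: LifeTable, age: float, cycle: int):
    """(p_death, h_readmit, h_revision) for the transition out of ``cycle``."""
    pd_ = lt.monthly_death_prob(age)
    if cycle < cfg.periop_window_cycles:
        hr = per_cycle_from_window(arm_p_readmit, cfg.periop_window_cycles)
    else:
        hr = np.zeros_like(np.asarray(arm_p_readmit, dtype=float)) if not np.isscalar(
            arm_p_readmit
        ) else 0.0
    hv = _revision_hazard(arm_p_rev, cfg, cycle)
    return pd_, hr, hv


def transition_matrix(
    arm: StrategyParams,
    utilities: UtilitySet,
    cfg: RunConfig,
    lt: LifeTable,
    cycle: int,
) -> np.ndarray:
    """Row-stochastic matrix governing the transition out of ``cycle``.

    Mortality applies first; event risks scale the surviving fraction.  The
    joint readmission-and-revision mass is assigned to revision (the costlier
    path).  Tunnel survivors exit after one cycle: readmission back to WELL,
    acute revision on to POST_REVISION.
    """
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    age = cfg.effective_start_age(arm) + cycle / 12.0
    pd_, hr, hv = _hazards(
        arm.p_readmission_90d.base, arm.p_revision_total.base, cfg, lt, age, cycle
    )
    s = 1.0 - pd_
    M = np.zeros((N_STATES, N_STATES))
    M[State.WELL, State.DEATH] = pd_
    M[State.WELL, State.REVISION_TUNNEL] = s * hv
    M[State.WELL, State.READMIT_TUNNEL] = s * (1.0 - hv) * hr
    M[State.WELL, State.WELL] = s * (1.0 - hv) * (1.0 - hr)
    M[State.READMIT_TUNNEL, State.DEATH] = pd_
    M[State.READMIT_TUNNEL, State.WELL] = s
    M[State.REVISION_TUNNEL, State.DEATH] = pd_
    M[State.REVISION_TUNNEL, State.POST_REVISION] = s
    M[State.POST_REVISION, State.DEATH] = pd_
    M[State.POST_REVISION, State.POST_REVISION] = s
    M[State.DEATH, State.DEATH] = 1.0
    return M


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and discounted accruals for one cohort run."""

    occupancy: np.ndarray  # (T+1, 5) state probabilities
    cycle_costs: np.ndarray  # (T+1,) discounted USD accrued at each cycle
    cycle_qalys: np.ndarray  # (T+1,) discounted QALYs accrued at each cycle
    ages: np.ndarray  # (T+1,) exact age at each cycle
    label: str
    config: RunConfig
    #: running totals accumulated in cycle order (identical to the batch path)
    total_cost: float = 0.0
    total_qalys: float = 0.0

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        occ = self.occupancy
        return pd.DataFrame(
            {
                "cycle": np.arange(occ.shape[0]),
                "age": self.ages,
                "p_well": occ[:, State.WELL],
                "p_readmit": occ[:, State.READMIT_TUNNEL],
                "p_rev_tunnel": occ[:, State.REVISION_TUNNEL],
                "p_postrev": occ[:, State.POST_REVISION],
                "p_death": occ[:, State.DEATH],
                "cost_disc": self.cycle_costs,
                "qaly_disc": self.cycle_qalys,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _simulate(
    start_age: float,
    c_primary,
    c_readmission,
    c_revision,
    p_readmission,
    p_revision,
    u_well,
    u_post,
    u_acute,
    cfg: RunConfig,
    lt: LifeTable,
    keep_history: bool,
):
    """Core loop shared by the scalar and batch entry points.

    Parameters other than ``start_age`` may be scalars or same-length 1-D
    arrays (one element per Monte-Carlo draw).  Returns
    ``(total_cost, total_qaly, occ_hist, cost_hist, qaly_hist)``; the
    histories are None unless ``keep_history``.
    """
    T = cfg.horizon_cycles
    if T == 0:
        raise ValueError("horizon of 0 cycles")
    arrs = [np.asarray(a, dtype=float) for a in (
        c_primary, c_readmission, c_revision, p_readmission, p_revision,
        u_well, u_post, u_acute)]
    shape = np.broadcast_shapes(*(a.shape for a in arrs))
    c_primary, c_readmission, c_revision, p_readmission, p_revision, u_well, u_post, u_acute = (
        np.broadcast_to(a, shape) for a in arrs
    )
    occ = np.zeros(shape + (N_STATES,))
    occ[..., State.WELL] = 1.0
    cost = np.zeros(shape) + c_primary  # cycle-0 primary cost, undiscounted
    qaly = np.zeros(shape)
    if cfg.cycle0_utility:
        qaly += u_well / 12.0
    if keep_history:
        occ_hist = np.zeros((T + 1,) + shape + (N_STATES,))
        occ_hist[0] = occ
        cost_hist = np.zeros((T + 1,) + shape)
        cost_hist[0] = cost
        qaly_hist = np.zeros((T + 1,) + shape)
        qaly_hist[0] = qaly
    else:
        occ_hist = cost_hist = qaly_hist = None
    x = (1.0 + cfg.discount_rate_annual) ** (-1.0 / 12.0)
    df = 1.0
    for t in range(1, T + 1):
        cycle = t - 1  # transition out of `cycle`, landing at accounting step t
        age = start_age + cycle / 12.0
        pd_, hr, hv = _hazards(p_readmission, p_revision, cfg, lt, age, cycle)
        s = 1.0 - pd_
        w = occ[..., State.WELL]
        rt = occ[..., State.READMIT_TUNNEL]
        vt = occ[..., State.REVISION_TUNNEL]
        pr = occ[..., State.POST_REVISION]
        d = occ[..., State.DEATH]
        new = np.empty_like(occ)
        enter_rt = w * s * (1.0 - hv) * hr
        enter_vt = w * s * hv
        new[..., State.WELL] = w * s * (1.0 - hv) * (1.0 - hr) + rt * s
        new[..., State.READMIT_TUNNEL] = enter_rt
        new[..., State.REVISION_TUNNEL] = enter_vt
        new[..., State.POST_REVISION] = (vt + pr) * s
        new[..., State.DEATH] = d + (w + rt + vt + pr) * pd_
        df *= x
        c_t = (enter_rt * c_readmission + enter_vt * c_revision) * df
        if cfg.half_cycle_correction:
            acc = 0.5 * (occ + new)
        else:
            acc = new
        q_t = (
            acc[..., State.WELL] * u_well
            + (acc[..., State.READMIT_TUNNEL] + acc[..., State.REVISION_TUNNEL]) * u_acute
            + acc[..., State.POST_REVISION] * u_post
        ) / 12.0 * df
        cost += c_t
        qaly += q_t
        occ = new
        if keep_history:
            occ_hist[t] = occ
            cost_hist[t] = c_t
            qaly_hist[t] = q_t
    return cost, qaly, occ_hist, cost_hist, qaly_hist


def run_cohort(
    arm: StrategyParams, utilities: UtilitySet, cfg: RunConfig, lt: LifeTable
) -> CohortTrace:
    """Run one strategy arm's cohort at its base-case parameters."""
    start_age = cfg.effective_start_age(arm)
    cost, qaly, occ_hist, cost_hist, qaly_hist = _simulate(
        start_age,
        arm.c_primary.base,
        arm.c_readmission.base,
        arm.c_revision.base,
        arm.p_readmission_90d.base,
        arm.p_revision_total.base,
        utilities.u_well.base,
        utilities.u_post_revision.base,
        utilities.u_acute_event.base,
        cfg,
        lt,
        keep_history=True,
    )
    T = cfg.horizon_cycles
    ages = start_age + np.arange(T + 1) / 12.0
    return CohortTrace(
        occupancy=occ_hist,
        cycle_costs=cost_hist,
        cycle_qalys=qaly_hist,
        ages=ages,
        label=arm.label,
        config=cfg,
        total_cost=float(cost),
        total_qalys=float(qaly),
    )


def run_cohort_batch(
    arm: StrategyParams,
    cfg: RunConfig,
    lt: LifeTable,
    *,
    c_primary,
    c_readmission,
    c_revision,
    p_readmission,
    p_revision,
    u_well,
    u_post,
    u_acute,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized totals for a batch of parameter draws of one arm.

    Each keyword may be a scalar or a 1-D array of draws; arrays broadcast
    together.  Returns ``(total_costs, total_qalys)`` with the broadcast
    shape.  Identical accounting to :func:`run_cohort` (tested bit-for-bit).
    """
    start_age = cfg.effective_start_age(arm)
    cost, qaly, *_ = _simulate(
        start_age,
        c_primary,
        c_readmission,
        c_revision,
        p_readmission,
        p_revision,
        u_well,
        u_post,
        u_acute,
        cfg,
        lt,
        keep_history=False,
    )
    return cost, qaly


def simulate_individuals(
    arm: StrategyParams,
    utilities: UtilitySet,
    cfg: RunConfig,
    lt: LifeTable,
    n_walkers: int = 100_000,
    seed: int = 0,
) -> dict:
    """First-order individual-level simulation of the same transition matrices.

    A validation tool: walks ``n_walkers`` independent patients through the
    exact per-cycle matrices of :func:`transition_matrix` and returns the
    sample mean and Monte-Carlo standard error of discounted cost and QALY
    totals, for cross-checking the cohort expectation.
    """
    rng = np.random.default_rng(seed)
    T = cfg.horizon_cycles
    states = np.full(n_walkers, int(State.WELL))
    cost = np.full(n_walkers, arm.c_primary.base)
    qaly = np.zeros(n_walkers)
    u_by_state = np.array(
        [
            utilities.u_well.base,
            utilities.u_acute_event.base,
            utilities.u_acute_event.base,
            utilities.u_post_revision.base,
            0.0,
        ]
    )
    if cfg.cycle0_utility:
        qaly += utilities.u_well.base / 12.0
    x = (1.0 + cfg.discount_rate_annual) ** (-1.0 / 12.0)
    df = 1.0
    for t in range(1, T + 1):
        M = transition_matrix(arm, utilities, cfg, lt, t - 1)
        cum = np.cumsum(M, axis=1)
        r = rng.random(n_walkers)
        prev = states
        # vectorized categorical draw: row lookup then threshold search
        thresholds = cum[prev]  # (n, 5)
        states = (r[:, None] >= thresholds).sum(axis=1)
        df *= x
        entered_rt = (states == State.READMIT_TUNNEL) & (prev == State.WELL)
        entered_vt = (states == State.REVISION_TUNNEL) & (prev == State.WELL)
        cost += entered_rt * arm.c_readmission.base * df
        cost += entered_vt * arm.c_revision.base * df
        if cfg.half_cycle_correction:
            u_t = 0.5 * (u_by_state[prev] + u_by_state[states])
        else:
            u_t = u_by_state[states]
        qaly += u_t / 12.0 * df
    return {
        "mean_cost": float(cost.mean()),
        "se_cost": float(cost.std(ddof=1) / np.sqrt(n_walkers)),
        "mean_qalys": float(qaly.mean()),
        "se_qalys": float(qaly.std(ddof=1) / np.sqrt(n_walkers)),
        "n_walkers": n_walkers,
        "seed": seed,
    }
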