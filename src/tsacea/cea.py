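"""Incremental cost-effectiveness outcomes for a pair of cohort traces.

Convention: strategy A is the comparator of interest (outpatient) and B the
reference (inpatient); deltas are A minus B.  The incremental net monetary
benefit is ``INMB = wtp * dQALY - dCost`` (positive favors A).  The ICER is
reported as a ratio only when it is meaningful; when A is cheaper and more
effective it is "dominant", in the mirror case "dominated", and with zero
QALY difference "undefined".
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Union

from .life_tables import LifeTable
from .markov import CohortTrace, run_cohort
from .parameters import RunConfig, StrategyParams, UtilitySet

__all__ = ["CEResult", "compare", "compare_arms", "age_scenarios"]

Icer = Union[float, str]


@dataclass(frozen=True)
class CEResult:
    """Paired outcomes plus incremental cost-effectiveness summary."""

    label_A: str
    label_B: str
    cost_A: float
    cost_B: float
    qaly_A: float
    qaly_B: float
    delta_cost: float
    delta_qaly: float
    icer: Icer  # USD/QALY, or "dominant"/"dominated"/"undefined"
    inmb: float
    wtp: float
    verdict: str  # A_dominant | B_dominant | A_cost_effective | B_cost_effective | tie

    def to_dict(self) -> dict:
        return asdict(self)


def _icer(delta_cost: float, delta_qaly: float) -> Icer:
    if delta_cost < 0 and delta_qaly > 0:
        return "dominant"
    if delta_cost > 0 and delta_qaly < 0:
        return "dominated"
    if delta_qaly == 0:
        return "undefined"
    return delta_cost / delta_qaly


def compare(trace_A: CohortTrace, trace_B: CohortTrace, wtp: float) -> CEResult:
    """Incremental comparison of two cohort traces run under one configuration."""
    if trace_A.n_cycles != trace_B.n_cycles:
        raise ValueError(
            f"mismatched horizons: {trace_A.n_cycles} vs {trace_B.n_cycles} cycles"
        )
    dc = trace_A.total_cost - trace_B.total_cost
    dq = trace_A.total_qalys - trace_B.total_qalys
    inmb = wtp * dq - dc
    if dc < 0 and dq > 0:
        verdict = "A_dominant"
    elif dc > 0 and dq < 0:
        verdict = "B_dominant"
    elif inmb > 0:
        verdict = "A_cost_effective"
    elif inmb < 0:
        verdict = "B_cost_effective"
    else:
        verdict = "tie"
    return CEResult(
        label_A=trace_A.label,
        label_B=trace_B.label,
        cost_A=trace_A.total_cost,
        cost_B=trace_B.total_cost,
        qaly_A=trace_A.total_qalys,
        qaly_B=trace_B.total_qalys,
        delta_cost=dc,
        delta_qaly=dq,
        icer=_icer(dc, dq),
        inmb=inmb,
        wtp=wtp,
        verdict=verdict,
    )


def compare_arms(
    arms: tuple[StrategyParams, StrategyParams],
    utilities: UtilitySet,
    cfg: RunConfig,
    lt: LifeTable,
) -> CEResult:
    """Run both arms at base-case parameters and compare (A = first arm)."""
    trace_A = run_cohort(arms[0], utilities, cfg, lt)
    trace_B = run_cohort(arms[1], utilities, cfg, lt)
    return compare(trace_A, trace_B, cfg.wtp)


def age_scenarios(
    arms: tuple[StrategyParams, StrategyParams],
    utilities: UtilitySet,
    cfg: RunConfig,
    lt: LifeTable,
    offsets: list[float],
) -> list[tuple[float, CEResult]]:
    """Re-run the comparison with both arms' starting ages shifted together.

    The zero offset reproduces the base case exactly.
    """
    out = []
    for off in offsets:
        cfg_off = cfg.model_copy(update={"age_offset": cfg.age_offset + off})
        out.append((off, compare_arms(arms, utilities, cfg_off, lt)))
    return out
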