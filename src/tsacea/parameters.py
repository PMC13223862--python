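"""Model parameters: strategy inputs, health-state utilities, run configuration.

The model compares two surgical strategies (outpatient vs. inpatient total
shoulder arthroplasty) from a U.S. payer perspective.  Each strategy carries a
one-time primary procedure cost, a 90-day readmission probability, a revision
probability, and the costs of those downstream events; both strategies share a
set of health-state utilities.  Every uncertain quantity is stored as a
``Ranged`` triple ``(base, low, high)`` whose range feeds both the one-way
(tornado) and probabilistic sensitivity analyses.

Parameter files are YAML with top-level keys ``outpatient``, ``inpatient``,
``utilities`` and ``run``; the packaged file ``data/params_published.yaml`` holds
the published base-case inputs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Ranged",
    "StrategyParams",
    "UtilitySet",
    "RunConfig",
    "SensitivityParameter",
    "load_parameters",
    "save_parameters",
    "load_published_parameters",
    "parameter_inventory",
    "apply_override",
]


class Ranged(BaseModel):
    """A point estimate with its plausible (low, high) range.

    Ranges are interpreted as 95% intervals when calibrating sampling
    distributions for probabilistic sensitivity analysis.
    """

    model_config = ConfigDict(frozen=True)

    base: float
    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "Ranged":
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"range must satisfy low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        return self

    @classmethod
    def point(cls, value: float) -> "Ranged":
        """A degenerate (zero-width) range."""
        return cls(base=value, low=value, high=value)

    @property
    def width(self) -> float:
        return self.high - self.low

    def replace_base(self, value: float) -> "Ranged":
        """Copy with a new point estimate, widening the range if needed."""
        return Ranged(base=value, low=min(self.low, value), high=max(self.high, value))


def _check_probability(name: str, r: Ranged) -> None:
    if not (0.0 <= r.low and r.high <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1]; got range ({r.low}, {r.high})")


def _check_cost(name: str, r: Ranged) -> None:
    if r.low < 0.0:
        raise ValueError(f"{name} must be non-negative; got low={r.low}")


class StrategyParams(BaseModel):
    """One strategy arm: costs (2024 USD), event probabilities, starting age."""

    model_config = ConfigDict(frozen=True)

    label: str
    start_age: Ranged
    c_primary: Ranged
    c_readmission: Ranged
    c_revision: Ranged
    #: probability of readmission over the 90-day post-operative window
    p_readmission_90d: Ranged
    #: total revision probability over the model's revision-risk window
    p_revision_total: Ranged

    @model_validator(mode="after")
    def _invariants(self) -> "StrategyParams":
        for name in ("c_primary", "c_readmission", "c_revision"):
            _check_cost(name, getattr(self, name))
        for name in ("p_readmission_90d", "p_revision_total"):
            _check_probability(name, getattr(self, name))
        if self.start_age.base <= 0:
            raise ValueError("start_age must be positive")
        return self


class UtilitySet(BaseModel):
    """Health-state utilities shared by both arms (EQ-5D scale, 0=death, 1=full health).

    The temporary readmission and acute-revision tunnel states carry the same
    published utility and are modeled as one shared parameter ``u_acute_event``.
    Death is fixed at utility 0.
    """

    model_config = ConfigDict(frozen=True)

    u_well: Ranged
    u_post_revision: Ranged
    u_acute_event: Ranged
    u_death: float = 0.0

    @model_validator(mode="after")
    def _invariants(self) -> "UtilitySet":
        for name in ("u_well", "u_post_revision", "u_acute_event"):
            _check_probability(name, getattr(self, name))
        if self.u_death != 0.0:
            raise ValueError("u_death is fixed at 0")
        if not (
            self.u_acute_event.base <= self.u_post_revision.base <= self.u_well.base
        ):
            # base-case ordering is expected but not fatal (sensitivity draws
            # may cross); surface it loudly only when the base case violates it
            import warnings

            warnings.warn(
                "base-case utility ordering u_acute <= u_post_revision <= u_well "
                "is violated",
                stacklevel=2,
            )
        return self


RevisionSpreadMode = Literal["horizon_constant_hazard", "annual", "annual_window"]


class RunConfig(BaseModel):
    """Run configuration: horizon, discounting, thresholds, model conventions.

    Conventions the published analysis leaves unstated are exposed as toggles:

    ``revision_spread_mode``
        how the total revision probability is spread over time —
        ``horizon_constant_hazard`` (constant monthly hazard whose compounding
        over the full horizon reproduces the total), ``annual`` (the figure is
        an annual probability applied every year), or ``annual_window`` (an
        annual probability applied only during the first
        ``revision_window_years`` post-operative years).
    ``half_cycle_correction``
        average adjacent cycle occupancies when accruing utilities.
    ``cycle0_utility``
        accrue one month of well-state utility at cycle 0.
    ``common_cohort_age``
        run both arms at this shared starting age instead of each arm's own.
    """

    model_config = ConfigDict(frozen=True)

    horizon_years: int = 20
    cycle_length_months: int = 1
    discount_rate_annual: float = 0.03
    wtp: float = 100_000.0
    periop_window_cycles: int = 3
    revision_spread_mode: RevisionSpreadMode = "horizon_constant_hazard"
    revision_window_years: Optional[float] = None
    half_cycle_correction: bool = False
    cycle0_utility: bool = False
    common_cohort_age: Optional[float] = None
    age_offset: float = 0.0
    psa_iterations: int = 5000
    seed: int = 20240101

    @model_validator(mode="after")
    def _invariants(self) -> "RunConfig":
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if self.cycle_length_months != 1:
            raise ValueError("only monthly cycles are supported")
        if not (0.0 <= self.discount_rate_annual < 1.0):
            raise ValueError("discount_rate_annual must lie in [0, 1)")
        if self.wtp < 0:
            raise ValueError("wtp must be non-negative")
        if self.psa_iterations < 1:
            raise ValueError("psa_iterations must be >= 1")
        if self.periop_window_cycles < 1:
            raise ValueError("periop_window_cycles must be >= 1")
        if self.revision_spread_mode == "annual_window":
            if self.revision_window_years is None or self.revision_window_years <= 0:
                raise ValueError(
                    "revision_window_years must be positive when "
                    "revision_spread_mode='annual_window'"
                )
        return self

    @property
    def horizon_cycles(self) -> int:
        return self.horizon_years * 12

    def effective_start_age(self, arm: StrategyParams) -> float:
        age = (
            self.common_cohort_age
            if self.common_cohort_age is not None
            else arm.start_age.base
        )
        return age + self.age_offset


# ---------------------------------------------------------------------------
# file I/O


def _ranged_from_obj(name: str, obj) -> Ranged:
    if isinstance(obj, (int, float)):
        return Ranged.point(float(obj))
    if isinstance(obj, dict):
        missing = {"base", "low", "high"} - set(obj)
        if missing:
            raise KeyError(f"parameter '{name}' is missing field(s) {sorted(missing)}")
        return Ranged(**{k: float(obj[k]) for k in ("base", "low", "high")})
    raise TypeError(f"parameter '{name}' must be a number or a base/low/high mapping")


_ARM_FIELDS = (
    "start_age",
    "c_primary",
    "c_readmission",
    "c_revision",
    "p_readmission_90d",
    "p_revision_total",
)
_UTILITY_FIELDS = ("u_well", "u_post_revision", "u_acute_event")


def _arm_from_section(label: str, section: dict) -> StrategyParams:
    missing = set(_ARM_FIELDS) - set(section)
    if missing:
        raise KeyError(f"strategy '{label}' is missing field(s) {sorted(missing)}")
    fields = {f: _ranged_from_obj(f"{label}.{f}", section[f]) for f in _ARM_FIELDS}
    return StrategyParams(label=label, **fields)


def load_parameters(
    path: str | Path,
) -> tuple[tuple[StrategyParams, StrategyParams], UtilitySet, RunConfig]:
    """Read a YAML parameter file.

    Returns ``((outpatient, inpatient), utilities, run_config)`` with all
    invariants validated and RunConfig defaults applied for omitted keys.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path} does not contain a mapping")
    for key in ("outpatient", "inpatient", "utilities"):
        if key not in doc:
            raise KeyError(f"config is missing required section '{key}'")
    arms = tuple(
        _arm_from_section(label, doc[label]) for label in ("outpatient", "inpatient")
    )
    usec = doc["utilities"]
    missing = set(_UTILITY_FIELDS) - set(usec)
    if missing:
        raise KeyError(f"utilities section is missing field(s) {sorted(missing)}")
    utilities = UtilitySet(
        **{f: _ranged_from_obj(f"utilities.{f}", usec[f]) for f in _UTILITY_FIELDS}
    )
    cfg = RunConfig(**(doc.get("run") or {}))
    return arms, utilities, cfg


def _ranged_to_obj(r: Ranged) -> dict | float:
    if r.width == 0.0:
        return r.base
    return {"base": r.base, "low": r.low, "high": r.high}


def save_parameters(
    path: str | Path,
    arms: tuple[StrategyParams, StrategyParams],
    utilities: UtilitySet,
    cfg: RunConfig,
) -> None:
    """Write a parameter set back to YAML (round-trips with load_parameters)."""
    doc: dict = {}
    for arm in arms:
        doc[arm.label] = {f: _ranged_to_obj(getattr(arm, f)) for f in _ARM_FIELDS}
    doc["utilities"] = {
        f: _ranged_to_obj(getattr(utilities, f)) for f in _UTILITY_FIELDS
    }
    doc["run"] = {
        k: v for k, v in cfg.model_dump().items() if v != RunConfig.model_fields[k].default
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_published_parameters() -> tuple[
    tuple[StrategyParams, StrategyParams], UtilitySet, RunConfig
]:
    """Load the packaged published base-case parameter set."""
    res = importlib.resources.files("tsacea") / "data" / "params_published.yaml"
    with importlib.resources.as_file(res) as p:
        return load_parameters(p)


# ---------------------------------------------------------------------------
# sensitivity inventory


@dataclass(frozen=True)
class SensitivityParameter:
    """One tornado-eligible parameter: where it lives and its range.

    ``arm`` is ``"outpatient"``, ``"inpatient"`` or ``"both"`` (shared
    parameters — event costs and utilities — move in both arms at once).
    ``target`` is ``"strategy"`` or ``"utilities"``; ``field`` names the
    attribute on that object.
    """

    name: str
    arm: str
    target: str
    field: str
    base: float
    low: float
    high: float

    @property
    def width(self) -> float:
        return self.high - self.low


def parameter_inventory(
    arms: tuple[StrategyParams, StrategyParams], utilities: UtilitySet
) -> list[SensitivityParameter]:
    """Enumerate every cost, probability and utility for one-way sensitivity.

    Shared parameters (readmission cost, revision cost, all utilities — the
    published inputs list identical values for both arms) are emitted once and
    flagged ``arm="both"``; ages are handled by the explicit age-offset
    scenario analysis, not here.
    """
    out: list[SensitivityParameter] = []
    op, ip = arms
    for arm in (op, ip):
        for field, pretty in (
            ("c_primary", "primary cost"),
            ("p_readmission_90d", "readmission probability"),
            ("p_revision_total", "revision probability"),
        ):
            r = getattr(arm, field)
            out.append(
                SensitivityParameter(
                    name=f"{arm.label} {pretty}",
                    arm=arm.label,
                    target="strategy",
                    field=field,
                    base=r.base,
                    low=r.low,
                    high=r.high,
                )
            )
    for field, pretty in (
        ("c_readmission", "readmission cost"),
        ("c_revision", "revision surgery cost"),
    ):
        r = getattr(op, field)
        out.append(
            SensitivityParameter(
                name=pretty,
                arm="both",
                target="strategy",
                field=field,
                base=r.base,
                low=r.low,
                high=r.high,
            )
        )
    for field, pretty in (
        ("u_well", "utility: well"),
        ("u_post_revision", "utility: post-revision"),
        ("u_acute_event", "utility: acute event"),
    ):
        r = getattr(utilities, field)
        out.append(
            SensitivityParameter(
                name=pretty,
                arm="both",
                target="utilities",
                field=field,
                base=r.base,
                low=r.low,
                high=r.high,
            )
        )
    return out


def apply_override(
    arms: tuple[StrategyParams, StrategyParams],
    utilities: UtilitySet,
    param: SensitivityParameter,
    value: float,
) -> tuple[tuple[StrategyParams, StrategyParams], UtilitySet]:
    """Return copies of the inputs with one inventory parameter set to ``value``."""
    op, ip = arms
    if param.target == "utilities":
        new_r = getattr(utilities, param.field).replace_base(value)
        utilities = utilities.model_copy(update={param.field: new_r})
        return (op, ip), utilities
    new_arms = []
    for arm in (op, ip):
        if param.arm in (arm.label, "both"):
            new_r = getattr(arm, param.field).replace_base(value)
            arm = arm.model_copy(update={param.field: new_r})
        new_arms.append(arm)
    return (new_arms[0], new_arms[1]), utilities
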