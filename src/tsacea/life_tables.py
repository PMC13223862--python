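"""Age-indexed mortality for the absorbing death state.

A :class:`LifeTable` holds annual death probabilities ``qx`` (the probability
of dying between exact ages x and x+1) on a contiguous integer age grid.  The
engine converts them to monthly probabilities under a constant-hazard
assumption within each year of age, and treats every age at or beyond the
table's last row as certain death (the terminal row is forced to ``qx = 1`` at
load time so the closure is explicit).

The packaged file ``data/life_table_us2021_synthetic.csv`` is a SYNTHETIC
reconstruction of the 2021 U.S. all-population life table: log-linear
interpolation of qx between published 5-year anchor ages over ages 50-100.
To substitute the genuine table, export ``age,qx`` columns for the total
population from the published life table to CSV and pass its path anywhere a
life table is accepted.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "load_life_table", "us2021_synthetic"]


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities qx on a contiguous integer age grid."""

    ages: np.ndarray  # integer years, contiguous, strictly increasing
    qx: np.ndarray  # annual death probability per age row
    _monthly_cache: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.ndim != 1 or ages.size == 0 or ages.shape != qx.shape:
            raise ValueError("ages and qx must be matching non-empty 1-D arrays")
        diffs = np.diff(ages)
        if np.any(diffs <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(diffs != 1):
            missing = int(ages[np.argmax(diffs != 1)] + 1)
            raise ValueError(f"age column has a gap: missing age {missing}")
        if np.any((qx < 0) | (qx > 1)):
            bad = float(qx[(qx < 0) | (qx > 1)][0])
            raise ValueError(f"qx values must lie in [0, 1]; got {bad}")
        if qx[-1] != 1.0:
            raise ValueError(
                "terminal qx must be 1 (use load_life_table, which enforces it)"
            )
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        object.__setattr__(self, "_monthly_cache", 1.0 - (1.0 - qx) ** (1.0 / 12.0))

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        """Age at and beyond which death within the year is certain."""
        return int(self.ages[-1])

    def annual_qx(self, age: float) -> float:
        """Annual death probability for the year of age containing ``age``."""
        if age < self.min_age:
            raise ValueError(f"age {age} is below table coverage (min {self.min_age})")
        idx = int(np.floor(age)) - self.min_age
        if idx >= len(self.ages):
            return 1.0
        return float(self.qx[idx])

    def monthly_death_prob(self, age: float) -> float:
        """Per-cycle (monthly) death probability at exact ``age``.

        Constant hazard within the year of age: ``1 - (1 - qx)**(1/12)``;
        returns 1 for ages at or beyond ``max_age``.
        """
        if age < self.min_age:
            raise ValueError(f"age {age} is below table coverage (min {self.min_age})")
        idx = int(np.floor(age)) - self.min_age
        if idx >= len(self.ages):
            return 1.0
        return float(self._monthly_cache[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_life_table(path: str | Path) -> LifeTable:
    """Read an ``age,qx`` CSV, sort by age, and force the terminal row to qx=1."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"age", "qx"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path} must have columns 'age' and 'qx'")
    df = df.sort_values("age").reset_index(drop=True)
    ages = df["age"].to_numpy()
    if not np.allclose(ages, np.round(ages)):
        raise ValueError("ages must be integers")
    qx = df["qx"].to_numpy(dtype=float).copy()
    qx[-1] = 1.0  # terminal closure: death certain in the last tabulated year
    return LifeTable(ages=ages.astype(int), qx=qx)


def us2021_synthetic() -> LifeTable:
    """The packaged synthetic stand-in for the 2021 U.S. all-population table."""
    res = importlib.resources.files("tsacea") / "data" / "life_table_us2021_synthetic.csv"
    with importlib.resources.as_file(res) as p:
        return load_life_table(p)
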