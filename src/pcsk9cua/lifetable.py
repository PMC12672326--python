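"""Age-indexed background mortality.

A :class:`LifeTable` holds all-cause and cardiovascular (CV) mortality rates
per person-year in 1-year age bins. Non-CV mortality is the difference
``all_cause - cv`` and is treatment-invariant in the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LifeTable:
    """All-cause and CV mortality rates (per person-year) by integer age.

    Ages must be contiguous; CV rates may never exceed all-cause rates.
    Lookups floor fractional ages and clamp beyond the covered range, so the
    last row extends to arbitrarily old ages.
    """

    ages: np.ndarray
    all_cause_rate: np.ndarray
    cv_rate: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        ac = np.asarray(self.all_cause_rate, dtype=float)
        cv = np.asarray(self.cv_rate, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "all_cause_rate", ac)
        object.__setattr__(self, "cv_rate", cv)
        if not (len(ages) == len(ac) == len(cv)):
            raise ValueError("life table columns must have equal length")
        if len(ages) == 0:
            raise ValueError("life table is empty")
        if np.any(np.diff(ages) != 1):
            raise ValueError("life table ages must be contiguous 1-year bins")
        if np.any(ac < 0) or np.any(cv < 0):
            raise ValueError("life table rates must be non-negative")
        bad = np.nonzero(cv > ac)[0]
        if bad.size:
            raise ValueError(
                f"cv_rate exceeds all_cause_rate at age {ages[bad[0]]}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LifeTable):
            return NotImplemented
        return (np.array_equal(self.ages, other.ages)
                and np.array_equal(self.all_cause_rate, other.all_cause_rate)
                and np.array_equal(self.cv_rate, other.cv_rate))

    def _index(self, age: float) -> int:
        if age < self.ages[0]:
            raise ValueError(
                f"age {age} below life-table start {self.ages[0]}")
        return min(int(math.floor(age)) - int(self.ages[0]), len(self.ages) - 1)

    def all_cause(self, age: float) -> float:
        """All-cause mortality rate at (floored) ``age``."""
        return float(self.all_cause_rate[self._index(age)])

    def cv(self, age: float) -> float:
        """CV mortality rate at (floored) ``age``."""
        return float(self.cv_rate[self._index(age)])

    def covers(self, start_age: float, horizon: float) -> bool:
        """Whether the table's rows reach ``start_age + horizon`` without clamping."""
        return (self.ages[0] <= math.floor(start_age)
                and math.floor(start_age + horizon) <= self.ages[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages,
            "all_cause_rate": self.all_cause_rate,
            "cv_rate": self.cv_rate,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_life_table(path) -> LifeTable:
    """Load a life table from CSV with columns age, all_cause_rate, cv_rate."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"age", "all_cause_rate", "cv_rate"} - set(df.columns)
    if missing:
        raise ValueError(f"life-table CSV missing columns: {sorted(missing)}")
    return LifeTable(df["age"].to_numpy(), df["all_cause_rate"].to_numpy(),
                     df["cv_rate"].to_numpy())
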