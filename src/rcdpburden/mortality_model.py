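"""Discrete life-table survival model for the affected population.

The model is a sequence of annual mortality rates m_a (probability of
dying during the year of age a, conditional on reaching age a) with a
hard maximum lifespan: nobody survives past their (max_age + 1)-th
birthday, whatever the rates say.  The survival function is

    S(0) = 1,   S(a) = Π_{k<a} (1 − m_k)   for a ≤ max_age + 1,

with S(max_age + 1) forced to 0.

The packaged default encodes the published natural history of RCDP:
roughly 75% of patients reach their fifth birthday, mortality then
eases through late childhood, a uniform 8%/yr hazard applies from age
15, and the maximum lifespan is 34 completed years.  Ages 0–4 share a
constant rate r₀ solving (1 − r₀)⁵ = 0.75; ages 5–14 default to 2%/yr.
All three segments are overridable — the table is data, not code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_MAX_AGE = 34
DEFAULT_EARLY_SURVIVAL = 0.75   # cumulative survival to the fifth birthday
DEFAULT_EARLY_AGE = 5
DEFAULT_MID_RATE = 0.02         # ages early_age .. adult_start-1
DEFAULT_ADULT_RATE = 0.08       # from adult_start onward
DEFAULT_ADULT_START = 15


@dataclass(frozen=True)
class MortalityTable:
    """Age-indexed annual mortality rates with a maximum-lifespan cutoff."""

    rates: tuple[float, ...]
    max_age: int

    def __post_init__(self) -> None:
        if self.max_age < 0:
            raise ValueError(f"max_age must be >= 0, got {self.max_age}")
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))

    def survival_curve(self) -> np.ndarray:
        """S(a) for a = 0 .. max_age + 1 (the last entry is always 0)."""
        m = np.asarray(self.rates, dtype=float)
        s = np.empty(self.max_age + 2)
        s[0] = 1.0
        s[1:] = np.cumprod(1.0 - m)
        s[self.max_age + 1] = 0.0
        return s


def survival_to_age(table: MortalityTable, a: int) -> float:
    """Probability of surviving to the a-th birthday."""
    if a < 0:
        raise ValueError(f"age must be non-negative, got {a}")
    if a > table.max_age:
        return 0.0
    return float(table.survival_curve()[a])


def build_default_table(
    early_survival: float = DEFAULT_EARLY_SURVIVAL,
    early_age: int = DEFAULT_EARLY_AGE,
    mid_rate: float = DEFAULT_MID_RATE,
    adult_rate: float = DEFAULT_ADULT_RATE,
    adult_start: int = DEFAULT_ADULT_START,
    max_age: int = DEFAULT_MAX_AGE,
) -> MortalityTable:
    """Three-segment default table calibrated to early-childhood survival.

    The first segment (ages 0 .. early_age−1) uses the constant rate r₀
    with (1 − r₀)^early_age = early_survival, so S(early_age) hits the
    calibration target exactly.
    """
    if not (0.0 < early_survival <= 1.0):
        raise ValueError(f"early_survival must be in (0, 1], got {early_survival}")
    if not (0 < early_age <= adult_start <= max_age + 1):
        raise ValueError("segment boundaries must satisfy 0 < early_age <= adult_start <= max_age+1")
    r0 = 1.0 - early_survival ** (1.0 / early_age)
    rates = (
        [r0] * early_age
        + [mid_rate] * (adult_start - early_age)
        + [adult_rate] * (max_age + 1 - adult_start)
    )
    return MortalityTable(rates=tuple(rates), max_age=max_age)


def read_mortality_csv(path: str | Path) -> MortalityTable:
    """Read a table from CSV with columns ``age, annual_mortality_rate``.

    Ages must form the contiguous range 0..max_age.
    """
    df = pd.read_csv(path)
    required = {"age", "annual_mortality_rate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    df = df.sort_values("age")
    ages = df["age"].to_numpy(dtype=int)
    if not np.array_equal(ages, np.arange(len(ages))):
        raise ValueError(f"{path}: ages must form a contiguous range 0..max_age")
    table = MortalityTable(rates=tuple(df["annual_mortality_rate"]), max_age=len(ages) - 1)
    problems = validate_table(table)
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return table


def validate_table(table: MortalityTable) -> list[str]:
    """Structural diagnostics; an empty list means the table is valid."""
    diagnostics: list[str] = []
    if len(table.rates) != table.max_age + 1:
        diagnostics.append(
            f"rates length {len(table.rates)} != max_age + 1 = {table.max_age + 1}"
        )
    for a, m in enumerate(table.rates):
        if not (0.0 <= m <= 1.0):
            diagnostics.append(f"rate out of [0, 1] at age {a}: {m}")
    if not diagnostics:
        s = table.survival_curve()
        if np.any(np.diff(s) > 1e-15):
            diagnostics.append("survival function is not non-increasing")
    return diagnostics
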