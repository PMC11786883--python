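"""Period life tables from age-specific all-cause mortality rates.

Conventions (documented because "standard" life tables vary): single-year
ages, death probability ``q(x) = 1 - exp(-m(x))`` assuming a constant
hazard within the year, deaths spread evenly within the year
(``a(x) = 0.5``), and an open-ended closure interval at the top age where
person-years are ``l/m``.  The default top age is 105.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ScheduleValidationError

__all__ = [
    "MortalitySchedule",
    "LifeTableResult",
    "build_life_table",
    "life_expectancy_at",
    "read_mortality",
]

DEFAULT_A_MAX = 105


@dataclass
class MortalitySchedule:
    """All-cause mortality rates per person-year at single-year ages 0..A_max."""

    population_label: str
    sex: str
    ages: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.m = np.asarray(self.m, dtype=float)
        if self.ages.ndim != 1 or self.m.shape != self.ages.shape:
            raise ScheduleValidationError("ages and m must be 1-D arrays of equal length")
        if self.ages.size == 0 or self.ages[0] != 0 or np.any(np.diff(self.ages) != 1):
            raise ScheduleValidationError("ages must be contiguous single years from 0")
        if np.any(self.m < 0) or not np.all(np.isfinite(self.m)):
            bad = int(self.ages[np.flatnonzero((self.m < 0) | ~np.isfinite(self.m))[0]])
            raise ScheduleValidationError(f"invalid mortality rate at age {bad}")

    @property
    def a_max(self) -> int:
        return int(self.ages[-1])


@dataclass
class LifeTableResult:
    """Columns of a period life table (radix 1.0)."""

    ages: np.ndarray
    q: np.ndarray  # probability of dying within the year
    l: np.ndarray  # survivorship at exact age x
    L: np.ndarray  # person-years lived in [x, x+1); closure interval open-ended
    e: np.ndarray  # remaining life expectancy at exact age x


def _life_table_arrays(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core life-table recursion, vectorized over leading axes of ``m``.

    ``m`` has shape (..., A+1); the last age is the open-ended closure
    interval and must have a positive rate.
    """
    m = np.asarray(m, dtype=float)
    closure = m[..., -1]
    if np.any(closure <= 0):
        raise ScheduleValidationError(
            "closure-age mortality rate must be positive (open interval needs l/m)"
        )
    q = 1.0 - np.exp(-m)
    q[..., -1] = 1.0  # everyone dies in the open interval
    # survivorship: l(0)=1, l(x+1) = l(x) * exp(-m(x))
    surv = np.cumprod(np.exp(-m[..., :-1]), axis=-1)
    l = np.concatenate([np.ones(m.shape[:-1] + (1,)), surv], axis=-1)
    d = l * q
    L = l - 0.5 * d
    L[..., -1] = l[..., -1] / closure
    T = np.flip(np.cumsum(np.flip(L, axis=-1), axis=-1), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)
    return q, l, L, e


def build_life_table(schedule: MortalitySchedule) -> LifeTableResult:
    """Compute the period life table for one mortality schedule."""
    q, l, L, e = _life_table_arrays(schedule.m)
    return LifeTableResult(ages=schedule.ages.copy(), q=q, l=l, L=L, e=e)


def life_expectancy_at(result: LifeTableResult, age: int) -> float:
    """Remaining life expectancy e(x) at an exact age in the table."""
    if age < int(result.ages[0]) or age > int(result.ages[-1]):
        raise ValueError(
            f"age {age} outside table range {result.ages[0]}..{result.ages[-1]}"
        )
    return float(result.e[int(age) - int(result.ages[0])])


def read_mortality(
    path: str | Path,
    population: str | None = None,
    sex: str | None = None,
    min_a_max: int = 100,
) -> MortalitySchedule:
    """Read one mortality schedule from CSV.

    The file has columns ``population,sex,age_lo,age_hi,rate_per_person_year``;
    rows may be single years (``age_hi == age_lo``) or age bands, which are
    expanded to single years by holding the rate constant within the band.
    When the file holds several population/sex combinations the selectors
    are required.  Schedules must be contiguous from age 0 up to at least
    ``min_a_max``.
    """
    path = Path(path)
    with open(path) as fh:
        reader = csv.DictReader(fh)
        required = {"population", "sex", "age_lo", "age_hi", "rate_per_person_year"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise ScheduleValidationError(f"{path}: expected columns {sorted(required)}")
        rows = list(reader)
    combos = sorted({(r["population"], r["sex"]) for r in rows})
    selected = [
        c
        for c in combos
        if (population is None or c[0] == population) and (sex is None or c[1] == sex)
    ]
    if len(selected) != 1:
        raise ScheduleValidationError(
            f"{path}: selection (population={population!r}, sex={sex!r}) matches "
            f"{len(selected)} of the available combinations {combos}"
        )
    pop, sx = selected[0]
    rates: dict[int, float] = {}
    for lineno, row in enumerate(rows, start=2):
        if (row["population"], row["sex"]) != (pop, sx):
            continue
        try:
            lo, hi = int(row["age_lo"]), int(row["age_hi"])
            rate = float(row["rate_per_person_year"])
        except ValueError as exc:
            raise ScheduleValidationError(f"{path}, line {lineno}: {exc}") from exc
        if rate < 0:
            raise ScheduleValidationError(
                f"{path}, line {lineno}: negative rate at ages {lo}-{hi}"
            )
        if hi < lo:
            raise ScheduleValidationError(f"{path}, line {lineno}: age_hi < age_lo")
        for age in range(lo, hi + 1):
            if age in rates:
                raise ScheduleValidationError(
                    f"{path}, line {lineno}: duplicate coverage of age {age}"
                )
            rates[age] = rate
    ages = sorted(rates)
    if ages[0] != 0 or ages != list(range(ages[0], ages[-1] + 1)):
        missing = sorted(set(range(0, ages[-1] + 1)) - set(ages))
        raise ScheduleValidationError(
            f"{path}: schedule for {pop}/{sx} has gaps at ages {missing[:5]}"
        )
    if ages[-1] < min_a_max:
        raise ScheduleValidationError(
            f"{path}: schedule for {pop}/{sx} ends at age {ages[-1]} (< {min_a_max})"
        )
    return MortalitySchedule(
        population_label=pop,
        sex=sx,
        ages=np.array(ages),
        m=np.array([rates[a] for a in ages]),
    )


def write_mortality(schedule: MortalitySchedule, path: str | Path) -> None:
    """Write a schedule in the single-year CSV dialect ``read_mortality`` accepts."""
    lines = ["population,sex,age_lo,age_hi,rate_per_person_year"]
    for age, rate in zip(schedule.ages, schedule.m):
        lines.append(
            f"{schedule.population_label},{schedule.sex},{age},{age},{float(rate)!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
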