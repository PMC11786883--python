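"""Core projection: sustained diet change -> adjusted mortality -> LE gain.

A scenario changes the diet at one age and keeps it changed for life.  The
combined effect of all changed food groups is the product of per-group
hazard ratios from the dose-response curves, attenuated by a single
overlap factor ``overlap_w`` (the food-group effects are correlated, not
independent) and phased in linearly over ``lag_full_effect`` years (health
effects of a diet change take years to materialize).  Mortality at ages
past the change age is scaled accordingly, the life table is rebuilt, and
the gain is the difference of remaining life expectancies at the change
age.  The gain is decomposed by food group via one-at-a-time changes
rescaled to conserve the joint gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dose_response import DoseResponseCurve, hazard_ratio_of_change
from .foods import DietPattern, FoodGroup
from .life_table import (
    LifeTableResult,
    MortalitySchedule,
    _life_table_arrays,
    build_life_table,
    life_expectancy_at,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "ProjectionResult",
    "lag_fraction",
    "combined_log_hr",
    "adjusted_schedule",
    "project",
    "decompose",
    "aggregate_shares",
]


@dataclass
class ScenarioSpec:
    """One sustained diet-change scenario.

    ``diet_to`` may contain "unchanged" (None) intakes; they are resolved
    against ``diet_from`` when the scenario is evaluated.  ``groups_changed``
    defaults to every group whose resolved intakes differ.
    """

    diet_from: DietPattern
    diet_to: DietPattern
    change_age: int = 40
    lag_full_effect: float = 10.0
    initial_effect_fraction: float = 0.0
    overlap_w: float = 1.0
    groups_changed: frozenset[FoodGroup] | None = None

    def __post_init__(self) -> None:
        if self.change_age < 0:
            raise ValueError("change_age must be >= 0")
        if not 0.0 <= self.overlap_w <= 1.0:
            raise ValueError("overlap_w must lie in [0, 1]")
        if self.lag_full_effect < 0:
            raise ValueError("lag_full_effect must be >= 0")
        if not 0.0 <= self.initial_effect_fraction <= 1.0:
            raise ValueError("initial_effect_fraction must lie in [0, 1]")

    def resolved_diet_to(self) -> DietPattern:
        return self.diet_to.resolved_against(self.diet_from)

    def changed_groups(self) -> list[FoodGroup]:
        """Groups whose intake actually changes in this scenario."""
        diet_to = self.resolved_diet_to()
        groups = [
            g
            for g in FoodGroup
            if self.diet_from.intakes[g] != diet_to.intakes[g]
        ]
        if self.groups_changed is not None:
            groups = [g for g in groups if g in self.groups_changed]
        return groups


@dataclass
class ProjectionResult:
    """Projected life expectancies and their food-group decomposition."""

    le_baseline: float
    le_new: float
    gain: float
    ui: tuple[float, float] | None = None
    decomposition: dict[FoodGroup, tuple[float, tuple[float, float] | None]] = field(
        default_factory=dict
    )
    shares: dict[FoodGroup, float] = field(default_factory=dict)


def lag_fraction(t: float, spec: ScenarioSpec):
    """Fraction of the full mortality effect realized ``t`` years after the change.

    Linear ramp from ``initial_effect_fraction`` at t=0 to 1 at
    ``lag_full_effect`` years; identically 1 for a zero lag.  Accepts arrays.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if spec.lag_full_effect == 0:
        out = np.ones_like(t)
    else:
        ramp = np.minimum(t / spec.lag_full_effect, 1.0)
        out = spec.initial_effect_fraction + (1.0 - spec.initial_effect_fraction) * ramp
    return float(out) if out.ndim == 0 else out


def combined_log_hr(
    diet_from: DietPattern,
    diet_to: DietPattern,
    curves: Mapping[FoodGroup, DoseResponseCurve],
    overlap_w: float = 1.0,
    groups: list[FoodGroup] | None = None,
) -> float:
    """Overlap-attenuated sum of per-group log hazard ratios for the change.

    Groups without a curve (or outside ``groups``) contribute nothing; the
    uncategorized-energy remainder carries no central effect by design.
    """
    diet_to = diet_to.resolved_against(diet_from)
    total = 0.0
    for group in groups if groups is not None else list(FoodGroup):
        curve = curves.get(group)
        if curve is None:
            continue
        total += np.log(
            hazard_ratio_of_change(
                curve, diet_from.intakes[group], diet_to.intakes[group]
            )
        )
    return float(overlap_w * total)


def _effect_log_hr_by_age(
    schedule: MortalitySchedule, spec: ScenarioSpec, log_hr: float
) -> np.ndarray:
    """Per-age log hazard adjustment: zero before the change age, lag-ramped after."""
    adjust = np.zeros_like(schedule.m)
    idx = schedule.ages >= spec.change_age
    t = schedule.ages[idx] - spec.change_age
    adjust[idx] = lag_fraction(t, spec) * log_hr
    return adjust


def adjusted_schedule(
    schedule: MortalitySchedule,
    spec: ScenarioSpec,
    curves: Mapping[FoodGroup, DoseResponseCurve],
    log_hr: float | None = None,
) -> MortalitySchedule:
    """Mortality schedule after the diet change.

    ``m'(x) = m(x) * exp(f(x - change_age) * log_hr)`` for ages at or past
    the change age, unchanged before it.  ``log_hr`` defaults to the
    scenario's combined log hazard ratio.
    """
    if spec.change_age > schedule.a_max:
        raise ValueError("change_age lies outside the mortality schedule")
    if log_hr is None:
        log_hr = combined_log_hr(
            spec.diet_from, spec.diet_to, curves, spec.overlap_w, spec.changed_groups()
        )
    m_new = schedule.m * np.exp(_effect_log_hr_by_age(schedule, spec, log_hr))
    return MortalitySchedule(
        population_label=schedule.population_label,
        sex=schedule.sex,
        ages=schedule.ages.copy(),
        m=m_new,
    )


def _gain_for_log_hr(
    schedule: MortalitySchedule, spec: ScenarioSpec, log_hr
) -> np.ndarray | float:
    """LE gain at the change age for one or many combined log-HRs (vectorized)."""
    log_hr = np.asarray(log_hr, dtype=float)
    adjust = _effect_log_hr_by_age(schedule, spec, 1.0)  # unit profile
    m_new = schedule.m * np.exp(log_hr[..., None] * adjust)
    _, _, _, e_new = _life_table_arrays(m_new)
    _, _, _, e_base = _life_table_arrays(schedule.m)
    idx = spec.change_age - int(schedule.ages[0])
    out = e_new[..., idx] - e_base[idx]
    return float(out) if out.ndim == 0 else out


def project(
    schedule: MortalitySchedule,
    spec: ScenarioSpec,
    curves: Mapping[FoodGroup, DoseResponseCurve],
    with_decomposition: bool = True,
) -> ProjectionResult:
    """Central (point-curve) projection of the scenario.

    Uncertainty intervals are filled by :func:`nutrispan.uncertainty.run_mc`.
    """
    baseline = build_life_table(schedule)
    new = build_life_table(adjusted_schedule(schedule, spec, curves))
    le_baseline = life_expectancy_at(baseline, spec.change_age)
    le_new = life_expectancy_at(new, spec.change_age)
    result = ProjectionResult(
        le_baseline=le_baseline, le_new=le_new, gain=le_new - le_baseline
    )
    if with_decomposition:
        contributions, shares = decompose(schedule, spec, curves)
        result.decomposition = {g: (v, None) for g, v in contributions.items()}
        result.shares = shares
    return result


def decompose(
    schedule: MortalitySchedule,
    spec: ScenarioSpec,
    curves: Mapping[FoodGroup, DoseResponseCurve],
) -> tuple[dict[FoodGroup, float], dict[FoodGroup, float]]:
    """Food-group decomposition of the joint LE gain.

    Each group's raw contribution is the gain from changing that group
    alone (all others held at the baseline diet) under the same lag and
    overlap settings; signed contributions are then rescaled by a common
    factor so they sum exactly to the joint gain, and shares are the
    percentages of the absolute rescaled contributions (summing to 100).
    """
    diet_to = spec.resolved_diet_to()
    groups = spec.changed_groups()
    joint_log_hr = combined_log_hr(
        spec.diet_from, spec.diet_to, curves, spec.overlap_w, groups
    )
    joint_gain = _gain_for_log_hr(schedule, spec, joint_log_hr)
    raw: dict[FoodGroup, float] = {}
    for group in groups:
        curve = curves.get(group)
        if curve is None:
            raw[group] = 0.0
            continue
        solo = spec.overlap_w * np.log(
            hazard_ratio_of_change(
                curve, spec.diet_from.intakes[group], diet_to.intakes[group]
            )
        )
        raw[group] = _gain_for_log_hr(schedule, spec, solo)
    total_raw = sum(raw.values())
    if total_raw == 0.0:
        if joint_gain == 0.0:
            contributions = {g: 0.0 for g in raw}
        else:
            logger.warning(
                "one-at-a-time contributions cancel exactly; returning unscaled values"
            )
            contributions = raw
    else:
        scale = joint_gain / total_raw
        contributions = {g: v * scale for g, v in raw.items()}
    total_abs = sum(abs(v) for v in contributions.values())
    if total_abs == 0.0:
        if contributions:
            logger.warning("total gain is zero; food-group shares are undefined")
        shares: dict[FoodGroup, float] = {}
    else:
        shares = {g: 100.0 * abs(v) / total_abs for g, v in contributions.items()}
    return contributions, shares


def aggregate_shares(results: list[ProjectionResult]) -> dict[FoodGroup, float]:
    """Average food-group shares over several projections, renormalized to 100%."""
    if not results:
        raise ValueError("need at least one projection result")
    groups = sorted({g for r in results for g in r.shares}, key=lambda g: g.value)
    if not groups:
        return {}
    mean = {
        g: float(np.mean([r.shares.get(g, 0.0) for r in results])) for g in groups
    }
    total = sum(mean.values())
    if total == 0.0:
        return {g: 0.0 for g in groups}
    return {g: 100.0 * v / total for g, v in mean.items()}
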