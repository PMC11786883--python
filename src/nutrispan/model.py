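"""Model-object facade over the projection pipeline.

`DietShiftModel` bundles the three inputs of a projection — a mortality
schedule, a dose-response curve set and a diet-change scenario — the way a
statsmodels model bundles data and design; ``fit()`` runs the point
projection plus Monte-Carlo uncertainty propagation and returns a
`DietShiftResults` with the estimates, intervals, decomposition and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .dose_response import DoseResponseCurve
from .foods import FoodGroup, get_diet, load_diet_fixtures
from .life_table import MortalitySchedule
from .projection import ProjectionResult, ScenarioSpec
from .uncertainty import MCSettings, run_mc

__all__ = ["DietShiftModel", "DietShiftResults"]


class DietShiftModel:
    """Projection of the life-expectancy effect of one sustained diet change."""

    def __init__(
        self,
        schedule: MortalitySchedule,
        curves: Mapping[FoodGroup, DoseResponseCurve],
        scenario: ScenarioSpec,
    ) -> None:
        self.schedule = schedule
        self.curves = dict(curves)
        self.scenario = scenario

    @classmethod
    def from_fixtures(
        cls,
        schedule: MortalitySchedule,
        curves: Mapping[FoodGroup, DoseResponseCurve],
        population: str,
        sex: str,
        target: str = "feasible",
        **scenario_kwargs,
    ) -> "DietShiftModel":
        """Build a scenario from the packaged diets: one country/sex to a
        recommendation target (``"feasible"`` or ``"full"``)."""
        diets = load_diet_fixtures()
        diet_from = get_diet(diets, population, sex)
        diet_to = get_diet(diets, f"NNR_{target}", "both")
        return cls(
            schedule,
            curves,
            ScenarioSpec(diet_from=diet_from, diet_to=diet_to, **scenario_kwargs),
        )

    def fit(self, mc: MCSettings | None = None) -> "DietShiftResults":
        """Run the projection; with ``mc`` settings, fill uncertainty intervals."""
        if mc is None:
            mc = MCSettings()
        result = run_mc(self.schedule, self.scenario, self.curves, mc)
        return DietShiftResults(model=self, mc=mc, result=result)


@dataclass
class DietShiftResults:
    """Results of a fitted diet-shift projection."""

    model: DietShiftModel
    mc: MCSettings
    result: ProjectionResult = field(repr=False)

    @property
    def le_baseline(self) -> float:
        return self.result.le_baseline

    @property
    def le_new(self) -> float:
        return self.result.le_new

    @property
    def gain(self) -> float:
        return self.result.gain

    @property
    def ui(self) -> tuple[float, float] | None:
        return self.result.ui

    def decomposition_frame(self) -> pd.DataFrame:
        """Per-food-group contributions (years), intervals and shares (%)."""
        rows = []
        for group, (years, ui) in self.result.decomposition.items():
            rows.append(
                {
                    "food_group": group.value,
                    "contribution_years": years,
                    "ui_low": ui[0] if ui else float("nan"),
                    "ui_high": ui[1] if ui else float("nan"),
                    "share_percent": self.result.shares.get(group, float("nan")),
                }
            )
        frame = pd.DataFrame(
            rows,
            columns=[
                "food_group",
                "contribution_years",
                "ui_low",
                "ui_high",
                "share_percent",
            ],
        )
        return frame.sort_values(
            "contribution_years", ascending=False, ignore_index=True
        )

    def summary(self) -> str:
        """Human-readable summary table of the projection."""
        spec = self.model.scenario
        lines = [
            "Diet-shift life expectancy projection",
            "=" * 53,
            f"Population:        {self.model.schedule.population_label} "
            f"({self.model.schedule.sex})",
            f"Diet change:       {spec.diet_from.population_label} -> "
            f"{spec.diet_to.population_label} at age {spec.change_age}",
            f"Lag to full effect: {spec.lag_full_effect:g} y  "
            f"(initial fraction {spec.initial_effect_fraction:g})",
            f"Overlap weight:    {spec.overlap_w:g}",
            f"MC draws:          {self.mc.n_draws} (seed {self.mc.seed}, "
            f"{self.mc.interval:g}% interval)",
            "-" * 53,
            f"LE at age {spec.change_age} (baseline diet): {self.le_baseline:8.2f} y",
            f"LE at age {spec.change_age} (new diet):      {self.le_new:8.2f} y",
        ]
        if self.ui is not None:
            lines.append(
                f"LE gain:           {self.gain:6.2f} y  "
                f"(UI: {self.ui[0]:.2f}, {self.ui[1]:.2f})"
            )
        else:
            lines.append(f"LE gain:           {self.gain:6.2f} y")
        frame = self.decomposition_frame()
        if not frame.empty:
            lines += ["-" * 53, "Food-group decomposition (years of the gain):"]
            for _, row in frame.iterrows():
                ui_txt = (
                    f"  (UI: {row.ui_low:.2f}, {row.ui_high:.2f})"
                    if row.ui_low == row.ui_low
                    else ""
                )
                lines.append(
                    f"  {row.food_group:<15s} {row.contribution_years:7.2f} y  "
                    f"{row.share_percent:5.1f}%{ui_txt}"
                )
        lines.append("=" * 53)
        return "\n".join(lines)

    def plot_decomposition(self, ax=None):
        """Horizontal bar chart of per-group contributions (requires matplotlib)."""
        import matplotlib.pyplot as plt

        frame = self.decomposition_frame()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * max(len(frame), 4) + 1))
        ax.barh(frame["food_group"], frame["contribution_years"], color="#41709c")
        if frame["ui_low"].notna().any():
            err = [
                frame["contribution_years"] - frame["ui_low"],
                frame["ui_high"] - frame["contribution_years"],
            ]
            ax.errorbar(
                frame["contribution_years"],
                frame["food_group"],
                xerr=err,
                fmt="none",
                ecolor="0.3",
                capsize=2,
            )
        ax.axvline(0.0, color="0.6", lw=0.8)
        ax.set_xlabel("life expectancy contribution (years)")
        ax.invert_yaxis()
        return ax
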