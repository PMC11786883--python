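"""Diet patterns, food groups, unit conversions and energy accounting.

The model works with 14 food groups, each recorded as an average intake in
grams per day on a fresh/prepared-weight convention: whole grains are fresh
weight (dry grain converted at ingest), legumes are prepared weight, and
cheese is expressed as milk equivalents.  A :class:`DietPattern` holds one
population's intakes plus an estimated daily energy requirement; whatever
share of that requirement is not covered by the 14 groups is the
"uncategorized" fraction, which carries no central mortality effect but
widens uncertainty intervals downstream.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ConfigError, FixtureError

logger = logging.getLogger(__name__)

__all__ = [
    "FoodGroup",
    "UnitConversion",
    "DietPattern",
    "convert_units",
    "energy_account",
    "estimate_energy_requirement",
    "load_config",
    "load_diet_fixtures",
    "read_diets",
    "write_diets",
]


class FoodGroup(str, Enum):
    """The 14 food groups the projection model distinguishes."""

    WHOLE_GRAINS = "whole_grains"
    VEGETABLES = "vegetables"
    FRUITS = "fruits"
    NUTS = "nuts"
    LEGUMES = "legumes"
    FISH = "fish"
    EGGS = "eggs"
    MILK_DAIRY = "milk_dairy"
    REFINED_GRAINS = "refined_grains"
    RED_MEAT = "red_meat"
    PROCESSED_MEAT = "processed_meat"
    WHITE_MEAT = "white_meat"
    SSB = "ssb"
    ADDED_SUGARS = "added_sugars"

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]


_DISPLAY_NAMES = {
    FoodGroup.WHOLE_GRAINS: "Whole grain products",
    FoodGroup.VEGETABLES: "Vegetables including potatoes",
    FoodGroup.FRUITS: "Fruits",
    FoodGroup.NUTS: "Nuts",
    FoodGroup.LEGUMES: "Legumes",
    FoodGroup.FISH: "Fish",
    FoodGroup.EGGS: "Eggs",
    FoodGroup.MILK_DAIRY: "Milk and dairy",
    FoodGroup.REFINED_GRAINS: "Refined grains",
    FoodGroup.RED_MEAT: "Red meat",
    FoodGroup.PROCESSED_MEAT: "Processed meat",
    FoodGroup.WHITE_MEAT: "White meat",
    FoodGroup.SSB: "Sugar-sweetened beverages",
    FoodGroup.ADDED_SUGARS: "Added sugars",
}

VALID_SEXES = ("female", "male", "both")


@dataclass(frozen=True)
class UnitConversion:
    """Dry/cheese-to-canonical weight ratios applied at data ingest.

    Canonical intake units are fresh weight for whole grains, prepared
    weight for legumes and milk equivalents for cheese; all ratios must
    exceed 1 (the canonical form is always the heavier, hydrated one).
    """

    whole_grain_dry_to_fresh: float = 3.33
    legume_dry_to_prepared: float = 2.5
    cheese_to_milk: float = 7.5

    def __post_init__(self) -> None:
        for name in (
            "whole_grain_dry_to_fresh",
            "legume_dry_to_prepared",
            "cheese_to_milk",
        ):
            if not getattr(self, name) > 1:
                raise ValueError(f"conversion ratio {name} must be > 1")


@dataclass
class DietPattern:
    """Average daily intakes of the 14 food groups for one population.

    Parameters
    ----------
    population_label
        Country name or a recommendation label such as ``"NNR_feasible"``.
    sex
        ``"female"``, ``"male"`` or ``"both"`` (recommendation targets).
    intakes
        g/day per food group, fresh/prepared-weight convention.  A value of
        ``None`` marks a group whose target intake is "unchanged", i.e. to
        be inherited from the baseline diet when a scenario is built.
    total_energy
        Estimated daily energy requirement in kJ/day, if known.
    uncategorized_fraction
        Share (0..1) of the energy requirement not covered by the 14
        groups; may be supplied from data or derived via
        :func:`energy_account`.
    """

    population_label: str
    sex: str
    intakes: dict[FoodGroup, float | None]
    total_energy: float | None = None
    uncategorized_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        missing = set(FoodGroup) - set(self.intakes)
        if missing:
            raise ValueError(
                f"diet {self.population_label!r} is missing food groups: "
                f"{sorted(g.value for g in missing)}"
            )
        for group, grams in self.intakes.items():
            if grams is not None and grams < 0:
                raise ValueError(
                    f"negative intake {grams} g/d for {group.value} in "
                    f"{self.population_label!r}"
                )
        if self.uncategorized_fraction is not None and not (
            0.0 <= self.uncategorized_fraction <= 1.0
        ):
            raise ValueError("uncategorized_fraction must lie in [0, 1]")

    def resolved_against(self, baseline: "DietPattern") -> "DietPattern":
        """Fill ``None`` ("unchanged") intakes from a baseline diet."""
        filled = {
            g: (baseline.intakes[g] if v is None else v)
            for g, v in self.intakes.items()
        }
        return replace(self, intakes=filled)

    @property
    def has_unresolved(self) -> bool:
        return any(v is None for v in self.intakes.values())


def convert_units(
    raw_intake: float, conversion: UnitConversion, group: FoodGroup
) -> float:
    """Convert a raw intake to the canonical fresh/prepared convention.

    Whole grains are assumed reported in dry weight, legumes in dry weight
    and milk/dairy in cheese weight; every other group passes through
    unchanged.  Apply at ingest only — packaged fixtures are already
    canonical.
    """
    if raw_intake < 0:
        raise ValueError(f"negative intake {raw_intake} g/d")
    if group is FoodGroup.WHOLE_GRAINS:
        return raw_intake * conversion.whole_grain_dry_to_fresh
    if group is FoodGroup.LEGUMES:
        return raw_intake * conversion.legume_dry_to_prepared
    if group is FoodGroup.MILK_DAIRY:
        return raw_intake * conversion.cheese_to_milk
    return raw_intake


def energy_account(
    diet: DietPattern,
    densities: Mapping[FoodGroup, float],
    requirement: float,
) -> tuple[float, float]:
    """Split an energy requirement into categorized and uncategorized parts.

    Returns ``(categorized_kj, uncategorized_fraction)`` where categorized
    energy is the sum of intake times energy density over the 14 groups and
    the uncategorized fraction is the non-negative remainder of the
    requirement.  If the categorized energy exceeds the requirement the
    fraction is clamped at zero with a logged warning.
    """
    if requirement <= 0:
        raise ValueError("energy requirement must be positive")
    categorized = 0.0
    for group, grams in diet.intakes.items():
        if grams is None:
            continue
        density = densities.get(group, 0.0)
        if density < 0:
            raise ValueError(f"negative energy density for {group.value}")
        categorized += grams * density
    fraction = 1.0 - categorized / requirement
    if fraction < 0:
        logger.warning(
            "categorized energy %.0f kJ exceeds requirement %.0f kJ for %s; "
            "uncategorized fraction clamped to 0",
            categorized,
            requirement,
            diet.population_label,
        )
        fraction = 0.0
    return categorized, fraction


def estimate_energy_requirement(
    sex: str,
    age: float,
    anthropometry: Mapping[str, float] | None = None,
    config: Mapping[str, object] | None = None,
) -> float:
    """Estimate a daily energy requirement (kJ/day) from a configured equation.

    The equation is a linear energy-expenditure projection whose
    coefficients come from the ``energy_requirement`` block of the package
    config; the shipped defaults are documented approximations, and studies
    with access to a published expenditure equation should supply their own
    coefficients.
    """
    if age < 18:
        raise ValueError("energy requirement equation is defined for adults (age >= 18)")
    if sex not in ("female", "male"):
        raise ValueError("sex must be 'female' or 'male'")
    if config is None:
        config = load_config()
    try:
        eq = config["energy_requirement"]
    except (KeyError, TypeError) as exc:
        raise ConfigError("config lacks an 'energy_requirement' block") from exc
    required = (
        "intercept_kj",
        "sex_offset_male_kj",
        "age_coef_kj_per_year",
        "weight_coef_kj_per_kg",
        "height_coef_kj_per_cm",
    )
    for key in required:
        if key not in eq:
            raise ConfigError(f"energy_requirement config is missing {key!r}")
    anthro = dict(eq.get("default_anthropometry", {}))
    if anthropometry:
        anthro.update(anthropometry)
    weight = float(anthro.get("weight_kg", 70.0))
    height = float(anthro.get("height_cm", 170.0))
    kj = (
        float(eq["intercept_kj"])
        + (float(eq["sex_offset_male_kj"]) if sex == "male" else 0.0)
        + float(eq["age_coef_kj_per_year"]) * age
        + float(eq["weight_coef_kj_per_kg"]) * weight
        + float(eq["height_coef_kj_per_cm"]) * height
    )
    return kj


# ---------------------------------------------------------------------------
# configuration and fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("nutrispan").joinpath("data", name)))


def load_config(path: str | Path | None = None) -> dict:
    """Load the package configuration (energy densities, conversions, equation).

    Without a path the versioned config shipped with the package is used.
    """
    p = Path(path) if path is not None else _data_path("config.yaml")
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    with open(p) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config file {p} is not a mapping")
    return cfg


def energy_densities(config: Mapping[str, object] | None = None) -> dict[FoodGroup, float]:
    """Energy density (kJ/g) per food group from config."""
    if config is None:
        config = load_config()
    try:
        table = config["energy_density_kj_per_g"]
    except (KeyError, TypeError) as exc:
        raise ConfigError("config lacks 'energy_density_kj_per_g'") from exc
    out: dict[FoodGroup, float] = {}
    for group in FoodGroup:
        if group.value not in table:
            raise ConfigError(f"energy density missing for {group.value}")
        density = float(table[group.value])
        if density < 0:
            raise ConfigError(f"negative energy density for {group.value}")
        out[group] = density
    return out


_META_ROWS = ("energy_kj_per_day", "uncategorized_percent")
_FIXTURE_COLUMNS = ["population", "sex", "food_group", "intake_g_per_day", "provenance"]


def _rows_checksum(rows: Iterable[str]) -> str:
    digest = hashlib.sha256()
    for line in rows:
        digest.update(line.rstrip("\n").encode())
        digest.update(b"\n")
    return digest.hexdigest()


def read_diets(
    path: str | Path, verify_checksum: bool = False
) -> dict[tuple[str, str], DietPattern]:
    """Read diet patterns from a tidy CSV.

    Columns are ``population,sex,food_group,intake_g_per_day,provenance``;
    besides the 14 food-group ids, ``food_group`` may be
    ``energy_kj_per_day`` or ``uncategorized_percent`` carrying the energy
    metadata for the pattern.  An empty intake with provenance
    ``unchanged`` marks a target to be inherited from the baseline diet.
    A leading ``# sha256: <hex>`` comment, when present and
    ``verify_checksum`` is set, is validated against the remaining lines.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    expected_sum = None
    if lines and lines[0].startswith("# sha256:"):
        expected_sum = lines[0].split(":", 1)[1].strip()
        lines = lines[1:]
    if verify_checksum:
        if expected_sum is None:
            raise FixtureError(f"{path}: checksum header missing")
        actual = _rows_checksum(lines)
        if actual != expected_sum:
            raise FixtureError(
                f"{path}: checksum mismatch (expected {expected_sum}, got {actual})"
            )
    reader = csv.DictReader(lines)
    if reader.fieldnames is None or [c for c in _FIXTURE_COLUMNS[:4] if c not in reader.fieldnames]:
        raise FixtureError(f"{path}: expected columns {_FIXTURE_COLUMNS[:4]}")
    raw: dict[tuple[str, str], dict] = {}
    for lineno, row in enumerate(reader, start=2):
        pop = row["population"]
        sex = row["sex"]
        key = (pop, sex)
        entry = raw.setdefault(key, {"intakes": {}, "energy": None, "uncat": None})
        fg = row["food_group"]
        cell = (row["intake_g_per_day"] or "").strip()
        provenance = (row.get("provenance") or "").strip()
        try:
            if fg == "energy_kj_per_day":
                entry["energy"] = float(cell)
            elif fg == "uncategorized_percent":
                entry["uncat"] = float(cell) / 100.0
            else:
                group = FoodGroup(fg)
                if cell == "" and provenance == "unchanged":
                    entry["intakes"][group] = None
                else:
                    entry["intakes"][group] = float(cell)
        except ValueError as exc:
            raise FixtureError(
                f"{path}, line {lineno}: bad row for population={pop!r} "
                f"food_group={fg!r}: {exc}"
            ) from exc
    patterns: dict[tuple[str, str], DietPattern] = {}
    for (pop, sex), entry in raw.items():
        try:
            patterns[(pop, sex)] = DietPattern(
                population_label=pop,
                sex=sex,
                intakes=entry["intakes"],
                total_energy=entry["energy"],
                uncategorized_fraction=entry["uncat"],
            )
        except ValueError as exc:
            raise FixtureError(f"{path}: invalid diet for {pop!r}/{sex}: {exc}") from exc
    return patterns


def write_diets(
    patterns: Iterable[DietPattern], path: str | Path, checksum: bool = True
) -> None:
    """Write diet patterns in the tidy fixture CSV dialect (round-trip safe)."""
    lines = [",".join(_FIXTURE_COLUMNS)]
    for diet in patterns:
        for group in FoodGroup:
            grams = diet.intakes[group]
            cell = "" if grams is None else repr(float(grams))
            prov = "unchanged" if grams is None else "reported"
            lines.append(
                f"{diet.population_label},{diet.sex},{group.value},{cell},{prov}"
            )
        if diet.total_energy is not None:
            lines.append(
                f"{diet.population_label},{diet.sex},energy_kj_per_day,"
                f"{diet.total_energy!r},reported"
            )
        if diet.uncategorized_fraction is not None:
            lines.append(
                f"{diet.population_label},{diet.sex},uncategorized_percent,"
                f"{diet.uncategorized_fraction * 100.0!r},reported"
            )
    body = "\n".join(lines) + "\n"
    header = f"# sha256: {_rows_checksum(lines)}\n" if checksum else ""
    Path(path).write_text(header + body)


def load_diet_fixtures(verify_checksum: bool = True) -> dict[tuple[str, str], DietPattern]:
    """Load the packaged current diets (8 countries x 2 sexes) and the two
    recommendation targets (``NNR_feasible``, ``NNR_full``, sex ``both``).

    Intakes are transcribed averages in g/day on the canonical
    fresh/prepared-weight convention; rows with provenance ``ambiguous``
    were hard to transcribe unambiguously from the source table and should
    be treated with extra caution.  Recommendation rows for refined grains
    and white meat are ``unchanged`` (inherited from the baseline diet in
    a scenario).
    """
    patterns = read_diets(_data_path("diets.csv"), verify_checksum=verify_checksum)
    n_expected = 18
    if len(patterns) != n_expected:
        raise FixtureError(
            f"expected {n_expected} diet patterns in the fixture set, got {len(patterns)}"
        )
    return patterns


def get_diet(
    patterns: Mapping[tuple[str, str], DietPattern],
    population: str,
    sex: str | None = None,
) -> DietPattern:
    """Select one pattern by population (and sex, unless unambiguous)."""
    matches = [p for (pop, s), p in patterns.items() if pop == population and (sex is None or s == sex)]
    if not matches:
        raise KeyError(f"no diet pattern for {population!r} (sex={sex!r})")
    if len(matches) > 1:
        raise KeyError(f"ambiguous selection for {population!r}; specify sex")
    return matches[0]
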