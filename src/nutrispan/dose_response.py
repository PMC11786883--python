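"""Dose-response relative-risk curves for all-cause mortality.

Each curve gives the relative risk of death as a function of average daily
intake of one food group, normalized to 1 at a reference intake, with
pointwise 95% confidence bounds from the underlying meta-analysis.
Interpolation is piecewise-linear on the log-RR scale (risks multiply);
intakes beyond the evidence grid are clamped to the terminal grid values
rather than extrapolated.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import CurveValidationError
from .foods import FoodGroup

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseCurve",
    "CurveDraw",
    "relative_risk",
    "hazard_ratio_of_change",
    "sample_curve",
    "read_curves",
    "write_curves",
]

EVIDENCE_GRADES = ("very_low", "low", "moderate", "high")
_Z95 = 1.96  # CI bounds assumed to be point +/- 1.96 SD on the log scale


@dataclass
class DoseResponseCurve:
    """Gridded relative risk of all-cause mortality vs intake for one group."""

    group: FoodGroup
    grid: np.ndarray        # intakes, g/day, strictly increasing
    rr: np.ndarray          # point estimates, > 0
    rr_lo: np.ndarray       # lower 95% bound
    rr_hi: np.ndarray       # upper 95% bound
    reference_intake: float  # g/day where RR = 1
    evidence_grade: str = "moderate"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.rr_lo = np.asarray(self.rr_lo, dtype=float)
        self.rr_hi = np.asarray(self.rr_hi, dtype=float)
        name = self.group.value
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise CurveValidationError(f"{name}: grid needs at least 2 points")
        if np.any(np.diff(self.grid) <= 0):
            raise CurveValidationError(f"{name}: grid must be strictly increasing")
        for arr, label in ((self.rr, "rr"), (self.rr_lo, "rr_lo"), (self.rr_hi, "rr_hi")):
            if arr.shape != self.grid.shape:
                raise CurveValidationError(f"{name}: {label} shape mismatch")
            if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
                row = int(np.flatnonzero((arr <= 0) | ~np.isfinite(arr))[0])
                raise CurveValidationError(
                    f"{name}: non-positive or non-finite {label} at grid row {row}"
                )
        bad = np.flatnonzero((self.rr_lo > self.rr) | (self.rr > self.rr_hi))
        if bad.size:
            raise CurveValidationError(
                f"{name}: CI inversion at grid row {int(bad[0])} "
                f"(intake {self.grid[int(bad[0])]} g/d)"
            )
        if self.evidence_grade not in EVIDENCE_GRADES:
            raise CurveValidationError(
                f"{name}: evidence grade {self.evidence_grade!r} not in {EVIDENCE_GRADES}"
            )
        if abs(relative_risk(self, self.reference_intake) - 1.0) > 1e-6:
            raise CurveValidationError(
                f"{name}: RR at reference intake {self.reference_intake} g/d "
                f"is not 1 within 1e-6"
            )

    @property
    def log_sd(self) -> np.ndarray:
        """Pointwise SD of log RR implied by the 95% CI."""
        return (np.log(self.rr_hi) - np.log(self.rr_lo)) / (2.0 * _Z95)


@dataclass
class CurveDraw:
    """One Monte-Carlo realization of a curve's gridded RR values."""

    group: FoodGroup
    rr_sampled: np.ndarray

    def __post_init__(self) -> None:
        self.rr_sampled = np.asarray(self.rr_sampled, dtype=float)
        if np.any(self.rr_sampled <= 0):
            raise CurveValidationError(f"{self.group.value}: sampled RR must be positive")


def _log_interp(curve: DoseResponseCurve, intake, values: np.ndarray):
    """Interpolate ``values`` (a log-scale grid quantity) at clamped intakes."""
    return np.interp(intake, curve.grid, values)


def relative_risk(curve: DoseResponseCurve, intake) -> float | np.ndarray:
    """RR at an intake, log-linear between grid points, clamped beyond them."""
    if np.any(np.asarray(intake) < 0):
        raise ValueError("intake must be non-negative")
    out = np.exp(_log_interp(curve, intake, np.log(curve.rr)))
    return float(out) if np.isscalar(intake) or np.ndim(intake) == 0 else out


def hazard_ratio_of_change(
    curve: DoseResponseCurve, intake_from: float, intake_to: float
) -> float:
    """Mortality hazard ratio of moving from one sustained intake to another."""
    return float(
        np.exp(
            _log_interp(curve, intake_to, np.log(curve.rr))
            - _log_interp(curve, intake_from, np.log(curve.rr))
        )
    )


def sample_curve(curve: DoseResponseCurve, rng: np.random.Generator) -> CurveDraw:
    """Draw one curve realization from its CI.

    A single standard-normal z is drawn per curve and applied to every grid
    point on the log-RR scale with the pointwise CI-implied SD, so draws
    within one curve are perfectly correlated (the meta-analytic point
    estimates at adjacent doses come from the same studies); degenerate CIs
    give back the point curve.
    """
    z = rng.standard_normal()
    rr_sampled = np.exp(np.log(curve.rr) + z * curve.log_sd)
    return CurveDraw(group=curve.group, rr_sampled=rr_sampled)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_CURVE_COLUMNS = [
    "food_group",
    "intake_g_per_day",
    "rr",
    "rr_lo",
    "rr_hi",
    "reference",
    "evidence_grade",
]


def _build_curve(name: str, block: list[dict]) -> DoseResponseCurve:
    try:
        group = FoodGroup(name)
    except ValueError as exc:
        raise CurveValidationError(f"unknown food group {name!r}") from exc
    block = sorted(block, key=lambda r: float(r["intake_g_per_day"]))
    refs = {float(r["reference"]) for r in block}
    grades = {str(r.get("evidence_grade", "moderate")) for r in block}
    if len(refs) != 1:
        raise CurveValidationError(f"{name}: inconsistent reference intake across rows")
    if len(grades) != 1:
        raise CurveValidationError(f"{name}: inconsistent evidence grade across rows")
    return DoseResponseCurve(
        group=group,
        grid=np.array([float(r["intake_g_per_day"]) for r in block]),
        rr=np.array([float(r["rr"]) for r in block]),
        rr_lo=np.array([float(r["rr_lo"]) for r in block]),
        rr_hi=np.array([float(r["rr_hi"]) for r in block]),
        reference_intake=refs.pop(),
        evidence_grade=grades.pop(),
    )


def read_curves(path: str | Path) -> dict[FoodGroup, DoseResponseCurve]:
    """Read dose-response curves from CSV (or a JSON list of row objects).

    Missing food groups are permitted — they contribute no effect to a
    projection — and are logged.  Structural violations (non-monotone grid,
    CI inversion, RR <= 0) are rejected naming the group and row.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise CurveValidationError(f"{path}: JSON curve file must be a list of rows")
    else:
        with open(path) as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or set(_CURVE_COLUMNS[:6]) - set(reader.fieldnames):
                raise CurveValidationError(f"{path}: expected columns {_CURVE_COLUMNS}")
            rows = list(reader)
    blocks: dict[str, list[dict]] = {}
    for row in rows:
        blocks.setdefault(str(row["food_group"]), []).append(row)
    curves = {}
    for name, block in blocks.items():
        curve = _build_curve(name, block)
        curves[curve.group] = curve
    absent = sorted(g.value for g in set(FoodGroup) - set(curves))
    if absent:
        logger.warning(
            "curve file %s lacks groups %s; they will carry no effect", path, absent
        )
    return curves


def write_curves(
    curves: Mapping[FoodGroup, DoseResponseCurve], path: str | Path
) -> None:
    """Write curves in the CSV dialect ``read_curves`` accepts (round-trip safe)."""
    lines = [",".join(_CURVE_COLUMNS)]
    for group in FoodGroup:
        if group not in curves:
            continue
        c = curves[group]
        for x, r, lo, hi in zip(c.grid, c.rr, c.rr_lo, c.rr_hi):
            lines.append(
                f"{group.value},{float(x)!r},{float(r)!r},{float(lo)!r},"
                f"{float(hi)!r},{float(c.reference_intake)!r},{c.evidence_grade}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
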