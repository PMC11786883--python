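import numpy as np
import pytest

from nutrispan import (
    DietPattern,
    DoseResponseCurve,
    FoodGroup,
    MortalitySchedule,
)


def constant_schedule(m: float, a_max: int = 105, label: str = "const") -> MortalitySchedule:
    ages = np.arange(a_max + 1)
    return MortalitySchedule(label, "female", ages, np.full(a_max + 1, m))


def flat_diet(label: str, **intakes_by_name) -> DietPattern:
    intakes = {g: float(intakes_by_name.get(g.value, 0.0)) for g in FoodGroup}
    return DietPattern(population_label=label, sex="female", intakes=intakes)


def log_linear_curve(
    group: FoodGroup = FoodGroup.WHOLE_GRAINS,
    upper: float = 100.0,
    rr_at_upper: float = 0.8,
    rel_ci: float = 0.0,
    n_grid: int = 5,
) -> DoseResponseCurve:
    """Toy curve: log RR linear from 1 at intake 0 to rr_at_upper at upper."""
    grid = np.linspace(0.0, upper, n_grid)
    log_rr = np.log(rr_at_upper) * grid / upper
    half = 1.96 * rel_ci * np.abs(log_rr)
    return DoseResponseCurve(
        group=group,
        grid=grid,
        rr=np.exp(log_rr),
        rr_lo=np.exp(log_rr - half),
        rr_hi=np.exp(log_rr + half),
        reference_intake=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def const_schedule():
    return constant_schedule(0.02)
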