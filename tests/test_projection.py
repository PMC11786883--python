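import numpy as np
import pytest

from nutrispan import (
    DietPattern,
    FoodGroup,
    ScenarioSpec,
    adjusted_schedule,
    aggregate_shares,
    build_life_table,
    combined_log_hr,
    decompose,
    illustrative_curves,
    lag_fraction,
    make_mortality,
    GompertzMakehamParams,
    project,
)
from nutrispan.projection import ProjectionResult

from conftest import constant_schedule, flat_diet, log_linear_curve


def _simple_scenario(x_from=0.0, x_to=100.0, **kwargs):
    spec = ScenarioSpec(
        diet_from=flat_diet("from", whole_grains=x_from),
        diet_to=flat_diet("to", whole_grains=x_to),
        **kwargs,
    )
    curve = log_linear_curve(upper=100.0, rr_at_upper=0.8)
    return spec, {FoodGroup.WHOLE_GRAINS: curve}


class TestLagFraction:
    def test_linear_ramp(self):
        spec, _ = _simple_scenario(lag_full_effect=10.0)
        assert lag_fraction(0.0, spec) == 0.0
        assert lag_fraction(5.0, spec) == pytest.approx(0.5)
        assert lag_fraction(10.0, spec) == 1.0
        assert lag_fraction(50.0, spec) == 1.0

    def test_zero_lag_is_immediate(self):
        spec, _ = _simple_scenario(lag_full_effect=0.0)
        assert lag_fraction(0.0, spec) == 1.0

    def test_initial_fraction_sets_the_onset(self):
        spec, _ = _simple_scenario(lag_full_effect=10.0, initial_effect_fraction=0.4)
        assert lag_fraction(0.0, spec) == pytest.approx(0.4)
        assert lag_fraction(5.0, spec) == pytest.approx(0.7)

    def test_negative_time_rejected(self):
        spec, _ = _simple_scenario()
        with pytest.raises(ValueError):
            lag_fraction(-1.0, spec)


class TestCombinedLogHr:
    def test_no_change_gives_zero(self):
        spec, curves = _simple_scenario(x_from=50.0, x_to=50.0)
        assert combined_log_hr(spec.diet_from, spec.diet_to, curves) == 0.0

    def test_two_group_product(self):
        """HRs 0.9 and 0.8 combine multiplicatively to ln(0.72)."""
        diet_from = flat_diet("from")
        diet_to = flat_diet("to", whole_grains=100.0, nuts=100.0)
        curves = {
            FoodGroup.WHOLE_GRAINS: log_linear_curve(FoodGroup.WHOLE_GRAINS, 100.0, 0.9),
            FoodGroup.NUTS: log_linear_curve(FoodGroup.NUTS, 100.0, 0.8),
        }
        value = combined_log_hr(diet_from, diet_to, curves, overlap_w=1.0)
        assert value == pytest.approx(np.log(0.72), abs=1e-12)

    def test_full_overlap_attenuation_kills_the_effect(self):
        spec, curves = _simple_scenario()
        assert combined_log_hr(spec.diet_from, spec.diet_to, curves, overlap_w=0.0) == 0.0

    def test_groups_without_curves_contribute_nothing(self):
        diet_from = flat_diet("from")
        diet_to = flat_diet("to", fish=50.0, whole_grains=100.0)
        curves = {FoodGroup.WHOLE_GRAINS: log_linear_curve(upper=100.0, rr_at_upper=0.8)}
        assert combined_log_hr(diet_from, diet_to, curves) == pytest.approx(np.log(0.8))


class TestAdjustedSchedule:
    def test_null_effect_leaves_schedule_unchanged(self, const_schedule):
        spec, curves = _simple_scenario(x_from=50.0, x_to=50.0)
        out = adjusted_schedule(const_schedule, spec, curves)
        np.testing.assert_array_equal(out.m, const_schedule.m)

    def test_immediate_effect_scales_all_later_ages(self, const_schedule):
        spec, curves = _simple_scenario(change_age=40, lag_full_effect=0.0)
        out = adjusted_schedule(const_schedule, spec, curves)
        np.testing.assert_allclose(out.m[40:], const_schedule.m[40:] * 0.8)
        np.testing.assert_array_equal(out.m[:40], const_schedule.m[:40])

    def test_ramp_applies_on_the_log_scale(self, const_schedule):
        """Five years into a ten-year lag, half the log effect applies."""
        spec = ScenarioSpec(
            diet_from=flat_diet("from"),
            diet_to=flat_diet("to", whole_grains=100.0),
            change_age=40,
            lag_full_effect=10.0,
        )
        curve = log_linear_curve(upper=100.0, rr_at_upper=0.5)
        out = adjusted_schedule(const_schedule, spec, {FoodGroup.WHOLE_GRAINS: curve})
        assert out.m[45] / const_schedule.m[45] == pytest.approx(
            0.7071067811865476, abs=1e-12
        )


class TestProject:
    def test_no_change_gives_exactly_zero_gain(self, const_schedule):
        spec, curves = _simple_scenario(x_from=30.0, x_to=30.0)
        res = project(const_schedule, spec, curves)
        assert res.gain == 0.0

    def test_constant_hazard_closed_form(self):
        """Immediate HR 0.8 at constant hazard 0.02: gain ~ 1/(m h) - 1/m = 12.5 y."""
        spec, curves = _simple_scenario(change_age=0, lag_full_effect=0.0)
        res = project(constant_schedule(0.02), spec, curves)
        expected = 1.0 / (0.02 * 0.8) - 1.0 / 0.02
        assert res.gain == pytest.approx(expected, rel=0.01)

    def test_gain_is_difference_of_expectancies(self, const_schedule):
        spec, curves = _simple_scenario(change_age=40)
        res = project(const_schedule, spec, curves)
        assert res.gain == pytest.approx(res.le_new - res.le_baseline, abs=1e-9)

    def test_stronger_effect_never_gives_smaller_gain(self, const_schedule):
        gains = []
        for rr in (0.95, 0.85, 0.7, 0.55):
            spec = ScenarioSpec(
                diet_from=flat_diet("f"), diet_to=flat_diet("t", whole_grains=100.0)
            )
            curves = {FoodGroup.WHOLE_GRAINS: log_linear_curve(upper=100.0, rr_at_upper=rr)}
            gains.append(project(const_schedule, spec, curves).gain)
        assert all(b >= a for a, b in zip(gains, gains[1:]))

    def test_longer_lag_never_increases_gain(self, const_schedule):
        gains = []
        for lag in (0.0, 5.0, 15.0, 30.0):
            spec, curves = _simple_scenario(change_age=40, lag_full_effect=lag)
            gains.append(project(const_schedule, spec, curves).gain)
        assert all(a >= b - 1e-12 for a, b in zip(gains, gains[1:]))

    def test_later_change_never_increases_gain(self):
        sched = make_mortality(GompertzMakehamParams())
        gains = []
        for age in (40, 60, 80):
            spec, curves = _simple_scenario(change_age=age)
            gains.append(project(sched, spec, curves).gain)
        assert gains[0] >= gains[1] >= gains[2]


class TestDecompose:
    def test_single_changed_group_carries_all_of_the_share(self, const_schedule):
        spec, curves = _simple_scenario()
        _, shares = decompose(const_schedule, spec, curves)
        assert shares == {FoodGroup.WHOLE_GRAINS: pytest.approx(100.0)}

    def test_symmetric_changes_split_evenly(self, const_schedule):
        diet_from = flat_diet("from")
        diet_to = flat_diet("to", whole_grains=100.0, nuts=100.0)
        curves = {
            FoodGroup.WHOLE_GRAINS: log_linear_curve(FoodGroup.WHOLE_GRAINS, 100.0, 0.9),
            FoodGroup.NUTS: log_linear_curve(FoodGroup.NUTS, 100.0, 0.9),
        }
        spec = ScenarioSpec(diet_from=diet_from, diet_to=diet_to)
        contrib, shares = decompose(const_schedule, spec, curves)
        assert shares[FoodGroup.WHOLE_GRAINS] == pytest.approx(50.0)
        assert contrib[FoodGroup.WHOLE_GRAINS] == pytest.approx(contrib[FoodGroup.NUTS])

    def test_matches_one_at_a_time_oracle_with_rescaling(self, const_schedule):
        """Three-group toy scenario vs a brute-force solo-change oracle."""
        diet_from = flat_diet("from", red_meat=80.0)
        diet_to = flat_diet("to", whole_grains=60.0, nuts=90.0, red_meat=20.0)
        curves = {
            FoodGroup.WHOLE_GRAINS: log_linear_curve(FoodGroup.WHOLE_GRAINS, 100.0, 0.85),
            FoodGroup.NUTS: log_linear_curve(FoodGroup.NUTS, 100.0, 0.9),
            FoodGroup.RED_MEAT: log_linear_curve(FoodGroup.RED_MEAT, 100.0, 1.2),
        }
        spec = ScenarioSpec(
            diet_from=diet_from, diet_to=diet_to, change_age=40, overlap_w=0.9
        )
        contrib, shares = decompose(const_schedule, spec, curves)
        joint = project(const_schedule, spec, curves, with_decomposition=False).gain
        raw = {}
        for g in (FoodGroup.WHOLE_GRAINS, FoodGroup.NUTS, FoodGroup.RED_MEAT):
            solo_intakes = dict(diet_from.intakes)
            solo_intakes[g] = diet_to.intakes[g]
            solo_to = DietPattern("solo", "female", solo_intakes)
            solo_spec = ScenarioSpec(
                diet_from=diet_from, diet_to=solo_to, change_age=40, overlap_w=0.9
            )
            raw[g] = project(const_schedule, solo_spec, curves, with_decomposition=False).gain
        scale = joint / sum(raw.values())
        for g, value in raw.items():
            assert contrib[g] == pytest.approx(value * scale, abs=1e-9)
        assert sum(contrib.values()) == pytest.approx(joint, abs=1e-9)
        assert sum(shares.values()) == pytest.approx(100.0, abs=1e-6)

    def test_additivity_limit_makes_rescaling_the_identity(self, const_schedule):
        """With full overlap weight and no lag the solo log-HRs sum exactly."""
        diet_from = flat_diet("from")
        diet_to = flat_diet("to", whole_grains=50.0, nuts=70.0)
        curves = {
            FoodGroup.WHOLE_GRAINS: log_linear_curve(FoodGroup.WHOLE_GRAINS, 100.0, 0.8),
            FoodGroup.NUTS: log_linear_curve(FoodGroup.NUTS, 100.0, 0.9),
        }
        spec = ScenarioSpec(
            diet_from=diet_from, diet_to=diet_to, overlap_w=1.0, lag_full_effect=0.0
        )
        solo = sum(
            np.log(0.8) * 0.5 if g is FoodGroup.WHOLE_GRAINS else np.log(0.9) * 0.7
            for g in (FoodGroup.WHOLE_GRAINS, FoodGroup.NUTS)
        )
        assert combined_log_hr(diet_from, diet_to, curves) == pytest.approx(solo, abs=1e-12)

    def test_zero_gain_yields_empty_shares_with_warning(self, const_schedule, caplog):
        import logging

        spec, curves = _simple_scenario(x_from=20.0, x_to=20.0)
        with caplog.at_level(logging.WARNING):
            contrib, shares = decompose(const_schedule, spec, curves)
        assert shares == {}
        assert contrib == {}


class TestAggregateShares:
    def _result(self, shares):
        return ProjectionResult(le_baseline=0, le_new=0, gain=0, shares=shares)

    def test_single_result_returns_its_own_shares(self):
        r = self._result({FoodGroup.NUTS: 60.0, FoodGroup.FISH: 40.0})
        assert aggregate_shares([r]) == {FoodGroup.NUTS: 60.0, FoodGroup.FISH: 40.0}

    def test_mean_of_two_disjoint_results(self):
        a = self._result({FoodGroup.NUTS: 100.0, FoodGroup.FISH: 0.0})
        b = self._result({FoodGroup.NUTS: 0.0, FoodGroup.FISH: 100.0})
        out = aggregate_shares([a, b])
        assert out[FoodGroup.NUTS] == pytest.approx(50.0)
        assert out[FoodGroup.FISH] == pytest.approx(50.0)

    def test_output_sums_to_one_hundred(self, rng):
        results = []
        for _ in range(5):
            vals = rng.uniform(0, 1, size=3)
            vals = 100 * vals / vals.sum()
            results.append(
                self._result(
                    dict(zip((FoodGroup.NUTS, FoodGroup.FISH, FoodGroup.SSB), vals))
                )
            )
        assert sum(aggregate_shares(results).values()) == pytest.approx(100.0, abs=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_shares([])
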