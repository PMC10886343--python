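import numpy as np
import pytest

from extractopt.desirability import (
    DesirabilityGoal,
    desirability_value,
    goals_from_observed,
    optimize_desirability,
    overall_desirability,
)
from extractopt.design import DATESEED_FACTORS
from extractopt.rsm import QuadraticSurface


@pytest.fixture
def max_goal():
    return DesirabilityGoal("y", "maximize", low=10.0, high=20.0)


class TestRamp:
    def test_anchors_and_midpoint(self, max_goal):
        assert desirability_value(20.0, max_goal) == 1.0
        assert desirability_value(10.0, max_goal) == 0.0
        assert desirability_value(15.0, max_goal) == pytest.approx(0.5)

    def test_clamped_outside_range(self, max_goal):
        assert desirability_value(25.0, max_goal) == 1.0
        assert desirability_value(5.0, max_goal) == 0.0

    def test_shape_exponent_bends_ramp(self):
        goal = DesirabilityGoal("y", "maximize", 0.0, 1.0, shape=2.0)
        assert desirability_value(0.5, goal) == pytest.approx(0.25)

    def test_minimize_and_target_kinds(self):
        mini = DesirabilityGoal("y", "minimize", 0.0, 10.0)
        assert desirability_value(0.0, mini) == 1.0
        assert desirability_value(10.0, mini) == 0.0
        tgt = DesirabilityGoal("y", "target", 0.0, 10.0, target=4.0)
        assert desirability_value(4.0, tgt) == 1.0
        assert desirability_value(2.0, tgt) == pytest.approx(0.5)
        assert desirability_value(7.0, tgt) == pytest.approx(0.5)


class TestOverall:
    def test_unit_desirabilities(self):
        assert overall_desirability([1.0, 1.0]) == 1.0

    def test_weighted_geometric_mean(self):
        assert overall_desirability([0.9, 0.4]) == pytest.approx(0.6)

    def test_zero_annihilates(self):
        assert overall_desirability([0.0, 0.99, 1.0]) == 0.0

    def test_weights_shift_the_mean(self):
        d = overall_desirability([0.25, 1.0], weights=[1.0, 3.0])
        assert d == pytest.approx(0.25**0.25)


class TestOptimize:
    def test_reproduces_published_optimum(self, dateseed, tpc_model, tfc_model):
        design, responses = dateseed
        result = optimize_desirability(
            {"TPC": tpc_model, "TFC": tfc_model},
            goals_from_observed(responses),
            design.factors,
        )
        # reported optimum: 61.43 % EtOH, 29.60 min, 50.24 C
        assert result.actual[0] == pytest.approx(61.43, abs=0.5)
        assert result.actual[1] == pytest.approx(29.60, abs=0.5)
        assert result.actual[2] == pytest.approx(50.24, abs=0.5)
        assert 0 <= result.overall <= 1
        assert result.overall >= result.grid_best  # refinement never degrades
        # D = weighted geometric mean of the component desirabilities
        d = list(result.desirabilities.values())
        assert result.overall == pytest.approx(
            overall_desirability(d), abs=1e-12
        )

    def test_single_unsaturated_goal_finds_polynomial_argmax(self, tpc_model):
        # ramp anchored far above the surface maximum stays unsaturated,
        # so the desirability argmax is the polynomial's own argmax
        goal = DesirabilityGoal("TPC", "maximize", low=0.0, high=200.0)
        result = optimize_desirability(
            {"TPC": tpc_model}, [goal], DATESEED_FACTORS, grid_step=0.05
        )
        assert np.allclose(result.coded, tpc_model.stationary_point(), atol=1e-4)

    def test_concave_toy_model_optimum_at_center(self):
        model = QuadraticSurface.from_coefficients(
            [1.0, 0, 0, 0, -1.0, 0, 0, 0, 0, 0]
        )
        goal = DesirabilityGoal("y", "maximize", low=-3.0, high=1.0)
        result = optimize_desirability({"y": model}, [goal], DATESEED_FACTORS,
                                       grid_step=0.05)
        assert result.coded[0] == pytest.approx(0.0, abs=1e-6)

    def test_raising_upper_anchor_never_raises_optimal_d(self, dateseed, tpc_model):
        _, responses = dateseed
        y = responses["TPC"]
        base = DesirabilityGoal("TPC", "maximize", float(y.min()), float(y.max()))
        d_values = []
        for bump in (0.0, 2.0, 8.0):
            goal = DesirabilityGoal("TPC", "maximize", base.low, base.high + bump)
            result = optimize_desirability(
                {"TPC": tpc_model}, [goal], DATESEED_FACTORS, grid_step=0.05
            )
            d_values.append(result.overall)
        assert d_values == sorted(d_values, reverse=True)

    def test_degenerate_surface_warns_and_returns_grid_point(self):
        model = QuadraticSurface.from_coefficients([0.0] * 10)
        goal = DesirabilityGoal("y", "maximize", low=5.0, high=6.0)
        with pytest.warns(UserWarning):
            result = optimize_desirability({"y": model}, [goal],
                                           DATESEED_FACTORS, grid_step=0.25)
        assert result.overall == 0.0

    def test_missing_goal_rejected(self, tpc_model):
        with pytest.raises(ValueError):
            optimize_desirability({"TPC": tpc_model}, [], DATESEED_FACTORS)
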