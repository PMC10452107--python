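"""Tests for dose-response metrics, combination surfaces and Loewe synergy."""

import math

import numpy as np
import pytest

from rafresist.errors import InvalidParameterError
from rafresist.inhibitor_pharmacology import preset_pair
from rafresist.pathway_network import (
    SimulationCondition,
    build_model,
    generate_network,
)
from rafresist.response_analysis import (
    CombinationGrid,
    DoseResponseCurve,
    additive_reference_grid,
    combination_grid,
    dose_response,
    log_dose_grid,
    loewe_isobole,
    paradoxical_range,
)


def synthetic_curve(doses, values):
    doses = np.asarray(doses, dtype=float)
    return DoseResponseCurve(
        inhibitor="synthetic", doses=doses, pperk=np.asarray(values, dtype=float),
        condition=SimulationCondition(),
        converged=np.ones(len(doses), dtype=bool),
    )


class TestParadoxicalRange:
    def test_triangle_curve_crossing_by_log_interpolation(self):
        # basal 1, peak 2 at dose 10, down to 0.5 at dose 100
        curve = synthetic_curve([0, 1, 10, 100], [1.0, 1.2, 2.0, 0.5])
        pr = paradoxical_range(curve)
        assert not pr.no_paradox
        assert pr.peak_dose == 10.0
        assert pr.peak_fold == pytest.approx(2.0)
        # log-linear interpolation between (10, 2.0) and (100, 0.5) at level 1
        t = (1.0 - 2.0) / (0.5 - 2.0)
        expected = 10.0 ** (1.0 + t * 1.0)
        assert pr.crossing_dose == pytest.approx(expected, rel=1e-12)
        assert not pr.crossing_censored

    def test_strictly_decreasing_curve_is_no_paradox(self):
        curve = synthetic_curve([0, 1, 10, 100], [1.0, 0.9, 0.5, 0.1])
        pr = paradoxical_range(curve)
        assert pr.no_paradox
        assert pr.peak_fold == pytest.approx(1.0)
        assert pr.crossing_dose == 1.0  # first grid dose below basal

    def test_curve_never_returning_below_basal_is_right_censored(self):
        curve = synthetic_curve([0, 1, 10, 100], [1.0, 1.5, 2.0, 1.2])
        pr = paradoxical_range(curve)
        assert pr.crossing_censored
        assert pr.crossing_dose == 100.0

    def test_scale_invariance_of_fold_metrics(self):
        doses = [0, 1, 10, 100, 1000]
        values = np.array([1.0, 1.6, 2.0, 0.8, 0.2])
        pr1 = paradoxical_range(synthetic_curve(doses, values))
        pr2 = paradoxical_range(synthetic_curve(doses, 37.5 * values))
        assert pr1.peak_fold == pytest.approx(pr2.peak_fold)
        assert pr1.peak_dose == pr2.peak_dose
        assert pr1.crossing_dose == pytest.approx(pr2.crossing_dose)

    def test_grid_validation(self):
        with pytest.raises(InvalidParameterError):
            synthetic_curve([1, 10], [1.0, 0.5])  # missing zero dose
        with pytest.raises(InvalidParameterError):
            synthetic_curve([0, 10, 10], [1.0, 0.5, 0.4])  # not increasing


class TestLoeweOnSyntheticSurface:
    def test_additive_surface_gives_ci_of_one(self):
        doses = log_dose_grid(0.1, 1000.0, 4)
        grid = additive_reference_grid(doses, doses, e0=100.0, ic50=10.0,
                                       potency_ratio=2.0)
        for level in (60.0, 40.0, 20.0):
            assessment = loewe_isobole(grid, level)
            cis = [c for c in assessment.ci if c is not None]
            assert len(cis) >= 4
            assert np.allclose(cis, 1.0, atol=0.02), cis
            assert assessment.classification == "additivity"

    def test_single_agent_axis_point_has_ci_exactly_one(self):
        doses = log_dose_grid(0.1, 1000.0, 4)
        grid = additive_reference_grid(doses, doses)
        assessment = loewe_isobole(grid, 50.0)
        d1, d2 = assessment.isobole[0]
        assert d2 == 0.0
        assert assessment.ci[0] == pytest.approx(1.0, abs=1e-9)

    def test_isobole_endpoints_on_axes_at_single_agent_doses(self):
        doses = log_dose_grid(0.1, 1000.0, 4)
        grid = additive_reference_grid(doses, doses, ic50=10.0, potency_ratio=2.0)
        assessment = loewe_isobole(grid, 50.0)
        # Hill with ic50=10: D1 = 10; drug 2 is half as potent: D2 = 20
        # (interpolation on the log-dose grid is accurate to well under 1%)
        assert assessment.d1_single == pytest.approx(10.0, rel=5e-3)
        assert assessment.d2_single == pytest.approx(20.0, rel=5e-3)
        assert assessment.isobole[0][0] == pytest.approx(assessment.d1_single,
                                                         rel=1e-9)
        assert assessment.isobole[0][1] == 0.0

    def test_effect_outside_surface_range_rejected(self):
        doses = log_dose_grid(0.1, 1000.0, 3)
        grid = additive_reference_grid(doses, doses)
        with pytest.raises(InvalidParameterError):
            loewe_isobole(grid, 1e4)

    def test_synergy_classification_on_warped_surface(self):
        # compress the additive surface's interior: every interior point needs
        # less drug for the same effect -> CI < 1 -> synergy
        doses = log_dose_grid(0.1, 1000.0, 4)
        grid = additive_reference_grid(doses, doses)
        warped = grid.pperk.copy()
        interior = np.ix_(range(1, len(grid.doses1)), range(1, len(grid.doses2)))
        warped[interior] = warped[interior] * 0.25
        synergic = CombinationGrid(
            inhibitor1="a", inhibitor2="b", doses1=grid.doses1,
            doses2=grid.doses2, pperk=warped, condition=grid.condition,
        )
        assessment = loewe_isobole(synergic, 40.0)
        assert assessment.median_ci < 0.9
        assert assessment.classification == "synergy"


@pytest.fixture(scope="module")
def small_pathway():
    """Small two-inhibitor pathway network (single RAF isoform) for sweeps."""
    cond = SimulationCondition(araf=0.0, braf=100.0, craf=0.0,
                               ras_status="mutant")
    s1, s2, factors = preset_pair("I", "II")
    net = generate_network(build_model(cond, [s1, s2], factors))
    return cond, s1, s2, factors, net


class TestPathwaySweeps:
    def test_non_binding_inhibitor_gives_flat_curve(self):
        # an inhibitor with an effectively infinite Kd leaves ppERK at basal
        from rafresist.inhibitor_pharmacology import InhibitorSpec, closed_factors

        cond = SimulationCondition(araf=0.0, braf=100.0, craf=0.0,
                                   ras_status="mutant")
        inert = InhibitorSpec("inert", "II", Kd_ref=1e12)
        curve = dose_response(cond, inert, closed_factors(),
                              [0.0, 10.0, 1000.0])
        assert np.allclose(curve.pperk, curve.basal, rtol=1e-5)

    def test_combination_margins_reproduce_single_drug_curves(self, small_pathway):
        cond, s1, s2, factors, net = small_pathway
        grid = np.array([0.0, 10.0, 100.0])
        surface = combination_grid(cond, s1, s2, factors, grid, grid, net=net)
        curve1 = dose_response(cond, [s1, s2], factors, grid, slot=1, net=net)
        np.testing.assert_array_equal(surface.margin1(), curve1.pperk)

    def test_identical_drugs_give_symmetric_surface(self):
        cond = SimulationCondition(araf=0.0, braf=80.0, craf=0.0,
                                   ras_status="mutant")
        from rafresist.inhibitor_pharmacology import (
            InhibitorSpec, closed_factors,
        )
        spec = InhibitorSpec("same", "II", Kd_ref=10.0)
        factors = closed_factors(fa=0.1, fb=0.1, g1a=30.0, g1b=30.0,
                                 h_cross=30.0)
        net = generate_network(build_model(cond, [spec, spec], factors))
        grid = np.array([0.0, 3.0, 30.0])
        surface = combination_grid(cond, spec, spec, factors, grid, grid,
                                   net=net)
        np.testing.assert_allclose(surface.pperk, surface.pperk.T, rtol=1e-5)

    def test_log_dose_grid_properties(self):
        grid = log_dose_grid(0.1, 1000.0, 5)
        assert grid[0] == 0.0
        assert np.all(np.diff(grid) > 0)
        assert grid[1] == pytest.approx(0.1)
        assert grid[-1] == pytest.approx(1000.0)
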