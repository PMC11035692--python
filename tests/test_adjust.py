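import numpy as np
import pytest

from cropfuse import (scale_crop, enforce_upper_bound, enforce_lower_bound,
                      adjust_country, adjust_all, consistency_check)
from cropfuse.adjust import factor_table
from cropfuse.grid import CropAreaGrid


def grid_of(ha, ca=None, crop="c"):
    ha = np.asarray(ha, dtype=float)
    ca = ha.copy() if ca is None else np.asarray(ca, dtype=float)
    return CropAreaGrid(crop, ha.copy(), ca.copy())


ALL = np.ones((2, 3), dtype=bool)


class TestScaleCrop:
    def test_matching_target_is_identity(self):
        g = grid_of(np.full((2, 3), 10.0))
        assert scale_crop(g, 60.0, ALL) == pytest.approx(1.0)
        assert np.all(g.HA == 10.0)

    def test_factor_applied_uniformly(self):
        g = grid_of(np.full((2, 3), 10.0), np.full((2, 3), 5.0))
        f = scale_crop(g, 90.0, ALL)
        assert f == pytest.approx(1.5)
        assert np.all(g.HA == 15.0) and np.all(g.CA == 7.5)

    def test_intensity_preserved(self, rng):
        ca = rng.random((2, 3)) + 0.5
        ha = ca * rng.uniform(1, 3, size=(2, 3))
        ci_before = ha / ca
        g = grid_of(ha, ca)
        scale_crop(g, 2.5 * ha.sum(), ALL)
        np.testing.assert_allclose(g.HA / g.CA, ci_before, rtol=1e-9)

    def test_zero_target_empties_cells(self):
        g = grid_of(np.full((2, 3), 10.0))
        assert scale_crop(g, 0.0, ALL) == 0.0
        assert np.all(g.HA == 0.0)

    def test_no_support_reported_unadjustable(self):
        g = grid_of(np.zeros((2, 3)))
        assert scale_crop(g, 100.0, ALL) is None


class TestUpperBound:
    def test_no_violation_is_identity(self):
        g = grid_of(np.full((2, 3), 5.0))
        before = g.CA.copy()
        res = enforce_upper_bound({"c": g}, np.full((2, 3), 100.0), ALL)
        assert res == {}
        np.testing.assert_array_equal(g.CA, before)

    def test_single_crop_uniform_redistribution(self):
        # one cell 20 ha over LA, four other occupied cells with headroom
        la = np.full((1, 5), 50.0)
        ca = np.array([[70.0, 10.0, 10.0, 10.0, 10.0]])
        g = grid_of(ca, ca)
        mask = np.ones((1, 5), dtype=bool)
        enforce_upper_bound({"c": g}, la, mask)
        assert g.CA[0, 0] == pytest.approx(50.0)
        np.testing.assert_allclose(g.CA[0, 1:], 15.0)
        assert g.CA.sum() == pytest.approx(ca.sum(), rel=1e-9)

    def test_multi_crop_proportional_attribution(self):
        # crops 3:1 in the violating cell, 20 ha excess
        la = np.array([[40.0, 100.0, 100.0]])
        a = grid_of(np.array([[45.0, 10.0, 10.0]]), crop="a")
        b = grid_of(np.array([[15.0, 10.0, 10.0]]), crop="b")
        mask = np.ones((1, 3), dtype=bool)
        enforce_upper_bound({"a": a, "b": b}, la, mask)
        assert a.CA[0, 0] == pytest.approx(45.0 - 15.0)
        assert b.CA[0, 0] == pytest.approx(15.0 - 5.0)
        assert a.CA.sum() == pytest.approx(65.0, rel=1e-9)
        assert b.CA.sum() == pytest.approx(35.0, rel=1e-9)

    def test_receiving_cells_keep_their_intensity(self):
        la = np.array([[40.0, 100.0, 100.0]])
        ca = np.array([[50.0, 10.0, 10.0]])
        ha = ca * np.array([[1.0, 2.0, 1.5]])
        g = grid_of(ha, ca)
        mask = np.ones((1, 3), dtype=bool)
        enforce_upper_bound({"c": g}, la, mask)
        np.testing.assert_allclose(g.HA[0, 1:] / g.CA[0, 1:], [2.0, 1.5],
                                   rtol=1e-9)

    def test_infeasible_headroom_reported(self):
        la = np.array([[40.0, 10.0]])
        ca = np.array([[50.0, 10.0]])
        g = grid_of(ca, ca)
        res = enforce_upper_bound({"c": g}, la, np.ones((1, 2), dtype=bool))
        assert res["c"] == pytest.approx(10.0)


class TestLowerBound:
    def test_no_cell_below_bound_is_identity(self):
        g = grid_of(np.full((1, 4), 1.0))
        before = g.HA.copy()
        assert enforce_lower_bound(g, np.ones((1, 4), dtype=bool)) == 0.0
        np.testing.assert_array_equal(g.HA, before)

    def test_uniform_removal_from_donors(self):
        ha = np.array([[0.004, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]])
        g = grid_of(ha)
        enforce_lower_bound(g, np.ones_like(ha, dtype=bool))
        assert g.HA[0, 0] == pytest.approx(0.01)
        np.testing.assert_allclose(g.HA[0, 1:], 1.0 - 0.006 / 6, rtol=1e-9)
        assert g.HA.sum() == pytest.approx(ha.sum(), rel=1e-9)

    def test_all_cells_below_bound_reports_residual(self):
        ha = np.full((1, 3), 0.005)
        g = grid_of(ha)
        residual = enforce_lower_bound(g, np.ones_like(ha, dtype=bool))
        assert residual > 0
        assert np.all(g.HA == 0.01)


class TestAdjustCountry:
    def test_unconstrained_country_converges_in_one_iteration(self, rng):
        shape = (4, 6)
        la = np.full(shape, 1000.0)
        mask = np.ones(shape, dtype=bool)
        crops = {f"c{i}": grid_of(rng.random(shape) * 10 + 1)
                 for i in range(3)}
        targets = {c: 1.3 * g.HA.sum() for c, g in crops.items()}
        rep = adjust_country(crops, la, mask, targets)
        assert rep.converged and rep.iterations == 1
        for c, g in crops.items():
            assert g.HA.sum() == pytest.approx(targets[c], rel=5e-3)

    def test_saturated_cell_forces_redistribution_but_converges(self, rng):
        shape = (3, 5)
        mask = np.ones(shape, dtype=bool)
        ca = rng.random(shape) * 10 + 5
        la = ca * 1.05           # very tight capacity
        la[0, 0] = ca[0, 0] * 0.5  # one saturated cell
        crops = {"c": grid_of(ca)}
        targets = {"c": ca.sum()}
        rep = adjust_country(crops, la, mask, targets)
        assert rep.iterations <= 60
        assert np.all(crops["c"].CA <= la + 1e-6)

    def test_iteration_cap_respected_on_tight_world(self, rng):
        shape = (2, 4)
        mask = np.ones(shape, dtype=bool)
        ca = np.full(shape, 10.0)
        la = np.full(shape, 10.5)    # total capacity 84 < target 160
        crops = {"c": grid_of(ca)}
        rep = adjust_country(crops, la, mask, {"c": 160.0})
        assert rep.iterations <= 60
        assert np.all(crops["c"].CA <= la + 1e-6)

    def test_absent_crops_untouched(self, rng):
        shape = (2, 4)
        mask = np.ones(shape, dtype=bool)
        tracked = grid_of(rng.random(shape))
        untouched = grid_of(rng.random(shape))
        before = untouched.HA.copy()
        crops = {"a": tracked, "b": untouched}
        adjust_country(crops, np.full(shape, 100.0), mask,
                       {"a": 2 * tracked.HA.sum()})
        np.testing.assert_array_equal(untouched.HA, before)


class TestAdjustAll:
    def test_pipeline_world_reaches_targets(self, world, pipeline_result):
        for rep in pipeline_result.adjust_reports:
            for crop, total in rep.final_totals.items():
                target = rep.targets[crop]
                if target > 0:
                    assert abs(total - target) / target < 0.005

    def test_post_state_consistent(self, world, pipeline_result):
        la = world.geometry.LA
        ga = world.geometry.GA
        total_ca = np.zeros(world.spec.shape)
        for crop, g in pipeline_result.mosaic.crops.items():
            rep = consistency_check(g, la, ga)
            assert not rep.violations.get("CA<=HA")
            assert not rep.violations.get("CI<=3")
            total_ca += g.CA
        assert np.all(total_ca <= la + 1e-6)

    def test_factor_table_shape(self, pipeline_result):
        df = factor_table(pipeline_result.adjust_reports)
        assert {"country", "crop", "factor", "iterations"} <= set(df.columns)
        assert (df["factor"] > 0).all()
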