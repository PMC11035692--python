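import numpy as np
import pytest

from cropfuse import (disaggregate_unit, finalize_gapfill, fallback_legacy,
                      gapfill_quality)
from cropfuse.gapfill import gapfill_pair
from cropfuse.grid import CamStack, CropAreaGrid, CAM_LEVELS
from cropfuse.quality import EndogenousScores


def uniform_cam(shape, value=10.0):
    return CamStack({lev: np.full(shape, value) for lev in CAM_LEVELS})


def cam_from(weights):
    """Same weight map at every percentile level."""
    w = np.asarray(weights, dtype=float)
    return CamStack({lev: w.copy() for lev in CAM_LEVELS})


class TestDisaggregateUnit:
    def test_uniform_weights_split_equally(self):
        unit = np.ones((2, 2), dtype=bool)
        res = disaggregate_unit(100.0, unit, uniform_cam((2, 2)))
        np.testing.assert_allclose(res.HA, 25.0)
        # identical maps at every level: the reported percentile is the
        # median since no cell ever falls below the bound
        assert res.n_clamped == 0
        assert res.residual_ha == 0.0

    def test_proportional_to_weights(self):
        unit = np.ones((1, 3), dtype=bool)
        res = disaggregate_unit(100.0, unit, cam_from([[1.0, 1.0, 2.0]]))
        np.testing.assert_allclose(res.HA, [[25.0, 25.0, 50.0]])

    def test_zero_value_spreads_zero(self):
        unit = np.ones((2, 2), dtype=bool)
        res = disaggregate_unit(0.0, unit, uniform_cam((2, 2)))
        assert np.all(res.HA == 0.0) and res.n_clamped == 0

    def test_stopping_rule_clamps_small_cells(self):
        unit = np.ones((1, 3), dtype=bool)
        cam = cam_from([[1.0, 1.0, 2.0]])
        # 0.05 ha: smallest share 0.0125 >= 0.01, no trigger -> median map
        res = disaggregate_unit(0.05, unit, cam)
        assert res.percentile == 50.0 and res.n_clamped == 0
        # 0.03 ha: smallest share 0.0075 < 0.01 -> stop at 2.5 and clamp
        res = disaggregate_unit(0.03, unit, cam)
        assert res.percentile == 2.5 and res.n_clamped == 2
        assert res.HA[0, 0] == 0.01
        assert res.residual_ha > 0

    def test_percentile_iteration_advances_with_support(self):
        # lower percentiles concentrate on one strong cell; the 25th adds a
        # weak cell whose share falls below the bound and triggers the stop
        maps = {2.5: [[1.0, 0.0]], 5.0: [[1.0, 0.0]], 10.0: [[1.0, 0.0]],
                25.0: [[1.0, 0.004]], 50.0: [[1.0, 0.004]],
                95.0: [[1.0, 0.004]]}
        cam = CamStack({lev: np.array(v) for lev, v in maps.items()})
        res = disaggregate_unit(1.0, np.ones((1, 2), dtype=bool), cam)
        assert res.percentile == 25.0 and res.n_clamped == 1

    def test_all_zero_weights_skips_unit(self):
        unit = np.ones((2, 2), dtype=bool)
        with pytest.warns(UserWarning, match="skipped"):
            assert disaggregate_unit(10.0, unit,
                                     uniform_cam((2, 2), 0.0)) is None

    def test_unclamped_conservation(self, rng):
        for _ in range(20):
            unit = rng.random((4, 4)) < 0.7
            unit[0, 0] = True
            cam = cam_from(rng.random((4, 4)) + 0.5)
            value = rng.uniform(10, 1000)
            res = disaggregate_unit(value, unit, cam)
            if res.n_clamped == 0:
                assert res.HA.sum() == pytest.approx(value, rel=1e-9)


class TestFinalizeGapfill:
    @pytest.mark.parametrize("ha,la,cam95,expected", [
        (20.0, 30.0, 40.0, 20.0),
        (50.0, 30.0, 40.0, 30.0),
        (50.0, 60.0, 20.0, 20.0)])
    def test_min_of_three_and_unit_intensity(self, ha, la, cam95, expected):
        g = finalize_gapfill(np.array([[ha]]), np.array([[la]]),
                             np.array([[cam95]]))
        assert g.CA[0, 0] == expected
        assert g.HA[0, 0] == expected  # CI = 1 assumed


class TestFallbackLegacy:
    def test_layers_copied_unchanged_in_region(self):
        legacy = CropAreaGrid("x", np.arange(4.0).reshape(2, 2),
                              np.arange(4.0).reshape(2, 2) / 2)
        region = np.array([[True, False], [True, False]])
        out = fallback_legacy(legacy, region)
        np.testing.assert_array_equal(out.HA[:, 0], legacy.HA[:, 0])
        assert np.all(out.HA[:, 1] == 0.0)

    def test_national_total_preserved(self, world, pipeline_result):
        legacy = pipeline_result.harmonized["LEGACY"]["wheat"]
        region = world.masks.country == 3
        out = fallback_legacy(legacy, region)
        assert out.HA.sum() == pytest.approx(legacy.HA[region].sum(),
                                             rel=1e-12)


class TestGapfillQuality:
    def test_perfect_scores_reach_two_thirds(self):
        endo = EndogenousScores(1, 1, 1, 1, 1, 1, 1)
        assert gapfill_quality(endo, 1.0) == pytest.approx(2 / 3)

    def test_all_zero(self):
        endo = EndogenousScores(0, 0, 0, 0, 0, 0, 0)
        assert gapfill_quality(endo, 0.0) == 0.0

    def test_arithmetic(self):
        endo = EndogenousScores(0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
        assert gapfill_quality(endo, 0.6) == pytest.approx(3.5 / 21 + 0.2)


class TestGapfillPair:
    def test_units_without_statistics_fall_back_to_legacy(self, world,
                                                          pipeline_result):
        nso = world.nso_tables[3]
        units = world.masks.units_of(3)
        partial = nso[nso["unit"] == units[0]]
        legacy = pipeline_result.harmonized["LEGACY"]["wheat"]
        filled, rep = gapfill_pair("wheat", 3, partial, world.masks,
                                   world.cam, world.geometry.LA, legacy)
        assert rep["units_nso"] == [units[0]]
        assert units[1] in rep["units_legacy"]
        other = world.masks.subnational == units[1]
        np.testing.assert_array_equal(filled.HA[other], legacy.HA[other])

    def test_filled_cells_have_unit_intensity(self, world, pipeline_result):
        nso = world.nso_tables[3]
        filled, rep = gapfill_pair("wheat", 3, nso, world.masks, world.cam,
                                   world.geometry.LA, None)
        nso_cells = np.isin(world.masks.subnational, rep["units_nso"])
        np.testing.assert_allclose(filled.HA[nso_cells],
                                   filled.CA[nso_cells], rtol=1e-12)
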