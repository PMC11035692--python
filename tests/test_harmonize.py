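import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cropfuse import (GridSpec, CropAreaGrid, binary_to_fraction, cell_area,
                      fraction_to_areas, impute_CA_from_HA, combine_seasons,
                      apply_intensity, resample_conservative,
                      apply_lower_bound, consistency_check, harmonize_layer)
from cropfuse.harmonize import CropClassRegistry, RawLayer


def small_spec(res=1.0):
    return GridSpec(resolution=res, lon_min=0, lon_max=4, lat_min=0,
                    lat_max=2)


class TestBinaryToFraction:
    def test_full_blocks_give_one(self):
        common = small_spec(1.0)
        fine = common.refine(4)
        f = binary_to_fraction(np.ones(fine.shape, dtype=np.int8), fine,
                               common)
        assert np.all(f == 1.0)

    def test_partial_block_counted(self):
        common = small_spec(1.0)
        fine = common.refine(4)
        w = np.zeros(fine.shape, dtype=np.int8)
        w[0, 0] = w[1, 1] = w[2, 2] = 1  # 3 of 16 pixels of cell (0, 0)
        f = binary_to_fraction(w, fine, common)
        assert f[0, 0] == pytest.approx(0.1875)
        assert f[0, 1] == 0.0

    def test_empty_layer_gives_zero(self):
        common = small_spec(1.0)
        fine = common.refine(2)
        f = binary_to_fraction(np.zeros(fine.shape, dtype=np.int8), fine,
                               common)
        assert np.all(f == 0.0)

    def test_coarser_than_common_rejected(self):
        common = small_spec(1.0)
        with pytest.raises(ValueError):
            binary_to_fraction(np.zeros(small_spec(2.0).shape), small_spec(2.0),
                               common)


class TestAreaConversions:
    def test_fraction_to_areas(self):
        ga = np.full((2, 2), 3000.0)
        ca, ha = fraction_to_areas(np.full((2, 2), 0.5), ga)
        assert np.all(ca == 1500.0) and np.all(ha == 1500.0)

    @pytest.mark.parametrize("cls,ha,la,cam,expected", [
        ("permanent", 120.0, 100.0, 80.0, 120.0),
        ("temporary", 120.0, 100.0, 80.0, 80.0),
        ("temporary", 50.0, 100.0, 80.0, 50.0),
    ])
    def test_ca_imputation_branches(self, cls, ha, la, cam, expected):
        out = impute_CA_from_HA(np.array([[ha]]), cls, np.array([[la]]),
                                np.array([[cam]]))
        assert out[0, 0] == expected

    def test_unknown_crop_class_rejected(self):
        with pytest.raises(ValueError):
            impute_CA_from_HA(np.ones((1, 1)), "biennial", np.ones((1, 1)),
                              np.ones((1, 1)))

    def test_combine_seasons_max_and_sum(self):
        seasons = [np.array([[10.0]]), np.array([[20.0]]), np.array([[5.0]])]
        ca, ha = combine_seasons(seasons)
        assert ca[0, 0] == 20.0 and ha[0, 0] == 35.0

    def test_three_equal_seasons_hit_ci_boundary(self):
        a = np.array([[7.0]])
        ca, ha = combine_seasons([a, a, a])
        assert ha[0, 0] / ca[0, 0] == pytest.approx(3.0)

    def test_apply_intensity(self):
        ha = apply_intensity(np.array([[40.0]]), np.array([[2.5]]))
        assert ha[0, 0] == 100.0
        with pytest.raises(ValueError):
            apply_intensity(np.ones((1, 1)), np.array([[3.5]]))


class TestResampleConservative:
    def test_identity_when_grids_equal(self, rng):
        spec = small_spec(1.0)
        layer = rng.random(spec.shape)
        np.testing.assert_array_equal(
            resample_conservative(layer, spec, spec), layer)

    def test_one_coarse_cell_split_conserves(self):
        src = small_spec(2.0)
        dst = small_spec(1.0)
        layer = np.zeros(src.shape)
        layer[0, 0] = 400.0
        out = resample_conservative(layer, src, dst)
        assert out.sum() == pytest.approx(400.0, rel=1e-12)
        assert out[:2, :2].sum() == pytest.approx(400.0, rel=1e-12)

    def test_random_layer_total_conserved(self, rng):
        src = GridSpec(resolution=0.1, lon_min=0, lon_max=4, lat_min=40,
                       lat_max=42)
        dst = GridSpec(resolution=0.05, lon_min=0, lon_max=4, lat_min=40,
                       lat_max=42)
        layer = rng.random(src.shape) * 1000
        out = resample_conservative(layer, src, dst)
        assert out.sum() == pytest.approx(layer.sum(), rel=1e-9)
        assert np.all(out >= 0)

    def test_non_nesting_ratio_conserves(self, rng):
        src = GridSpec(resolution=0.25, lon_min=0, lon_max=1, lat_min=0,
                       lat_max=0.5)
        dst = GridSpec(resolution=0.1, lon_min=0, lon_max=1, lat_min=0,
                       lat_max=0.5)
        layer = rng.random(src.shape) * 50
        out = resample_conservative(layer, src, dst)
        assert out.sum() == pytest.approx(layer.sum(), rel=1e-9)

    def test_mismatched_bounds_rejected(self):
        with pytest.raises(ValueError):
            resample_conservative(np.ones(small_spec(1.0).shape),
                                  small_spec(1.0),
                                  GridSpec(resolution=1.0, lon_min=0,
                                           lon_max=4, lat_min=10, lat_max=12))


class TestLowerBound:
    def test_sub_bound_cells_zeroed(self):
        ca = np.array([[0.009, 0.01, 0.0]])
        ha = np.array([[0.02, 0.02, 0.0]])
        ca2, ha2 = apply_lower_bound(ca, ha)
        assert ca2[0, 0] == 0.0 and ha2[0, 0] == 0.0
        assert ca2[0, 1] == 0.01 and ha2[0, 1] == 0.02

    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=50)
    def test_idempotent(self, vals):
        ca = np.array(vals).reshape(2, 2)
        ha = ca * 1.5
        once = apply_lower_bound(ca, ha)
        twice = apply_lower_bound(once[0], once[1])
        np.testing.assert_array_equal(once[0], twice[0])
        np.testing.assert_array_equal(once[1], twice[1])


class TestConsistencyCheck:
    def _clean(self):
        la = np.full((2, 2), 100.0)
        ga = np.full((2, 2), 120.0)
        grid = CropAreaGrid("x", np.full((2, 2), 50.0),
                            np.full((2, 2), 40.0))
        return grid, la, ga

    def test_clean_layers_pass(self):
        grid, la, ga = self._clean()
        assert consistency_check(grid, la, ga).ok

    def test_injected_ca_above_ha_flagged(self):
        grid, la, ga = self._clean()
        grid.CA[1, 1] = 60.0
        rep = consistency_check(grid, la, ga)
        assert rep.violations["CA<=HA"] == [(1, 1)]

    def test_injected_excess_intensity_flagged(self):
        grid, la, ga = self._clean()
        grid.HA[0, 0] = grid.CA[0, 0] * 3.5
        rep = consistency_check(grid, la, ga)
        assert (0, 0) in rep.violations["CI<=3"]


class TestHarmonizeLayer:
    def test_every_synthetic_dataset_passes_diagnostics(self, world):
        from cropfuse.pipeline import harmonize_all
        harmonized = harmonize_all(world)  # raises if any check fails
        assert set(harmonized) == {d.acronym for d in world.datasets}

    def test_zero_noise_native_resolution_is_identity(self, world):
        gold = next(d for d in world.datasets if d.acronym == "GOLD")
        raw = gold.layers["wheat"]
        g = harmonize_layer(raw, world.spec, world.geometry, world.cam,
                            world.crop_registry)
        covered = np.isin(world.masks.country, gold.countries)
        np.testing.assert_allclose(g.HA[covered],
                                   world.truth["wheat"].HA[covered],
                                   rtol=1e-9)

    def test_national_totals_survive_coarsening_roundtrip(self, world):
        from cropfuse.synthetic import degrade_to_dataset
        from cropfuse.quality import DatasetMeta
        rec = degrade_to_dataset(
            world, "ha_ca", resolution_factor=2,
            meta=DatasetMeta("COARSE", overrides={n: 0.5 for n in
                                                  ("Qy", "Qa", "Qs", "Qv",
                                                   "Qr", "Qm", "Qd")}))
        raw = rec.layers["maize"]
        g = harmonize_layer(raw, world.spec, world.geometry, world.cam,
                            world.crop_registry)
        # conservation holds where the lower-bound truncation does not fire
        assert g.HA.sum() == pytest.approx(world.truth["maize"].HA.sum(),
                                           rel=1e-3)

    def test_crop_name_aggregation(self, world):
        registry = CropClassRegistry({"wheat": "temporary"},
                                     {"winter_wheat": "wheat"})
        raw = RawLayer("winter_wheat", "f", world.spec,
                       values=np.zeros(world.spec.shape))
        g = harmonize_layer(raw, world.spec, world.geometry, world.cam,
                            registry)
        assert g.crop == "wheat"
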