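import numpy as np
import pytest

from snagmap.evaluation import CountComparison
from snagmap.geodata_io import GridLayer, GridSpec
from snagmap.grid_metrics import (BiasModel, brown_pct_grid, canopy_metrics,
                                  cluster_size_profile, count_grid,
                                  estimate_bias, percent_mortality,
                                  three_prong_map)

from conftest import CRS, make_crown


def _spec(cell=100.0, n=10, top=1000.0):
    return GridSpec((0.0, top), cell, (n, n))


class TestCountGrid:
    def test_three_centroids_one_cell(self):
        crowns = [make_crown(10, 990, crown_id=i) for i in range(1, 4)]
        layer = count_grid(crowns, _spec(), CRS)
        assert layer.values[0, 0] == 3
        assert layer.values.sum() == 3
        assert not layer.bias_corrected

    def test_bias_correction_adds_me_per_cell(self):
        crowns = [make_crown(10, 990, crown_id=i) for i in range(1, 4)]
        layer = count_grid(crowns, _spec(), CRS,
                           bias=BiasModel(me_per_ha=0.56, F=10.0))
        # 100 m cell = 1 ha, so the cell gains exactly the ME
        assert layer.values[0, 0] == pytest.approx(3.56)
        assert layer.bias_corrected

    def test_bias_changes_total_by_cells_times_me(self):
        crowns = [make_crown(10, 990), make_crown(550, 440, crown_id=2)]
        raw = count_grid(crowns, _spec(), CRS)
        corr = count_grid(crowns, _spec(), CRS, bias=BiasModel(0.2, 10.0))
        n_cells = raw.values.size
        assert corr.values.sum() - raw.values.sum() == pytest.approx(n_cells * 0.2)

    def test_cell_edge_centroid_assigned_once(self):
        crowns = [make_crown(100.0, 990.0)]  # exactly on the shared edge
        layer = count_grid(crowns, _spec(), CRS)
        assert layer.values.sum() == 1
        assert layer.values[0, 1] == 1  # half-open: edge belongs to the right cell

    def test_thirty_metre_grid_refuses_bias(self):
        with pytest.raises(ValueError):
            count_grid([], _spec(cell=30.0), CRS, bias=BiasModel(0.5, 10.0))

    def test_conservation_raw_counts_equal_crown_count(self, default_scene):
        from snagmap.energy_encoding import instances_to_energy
        from snagmap.instance_extraction import extract_crowns, watershed_instances

        e = instances_to_energy(default_scene.truth_instances, 5,
                                default_scene.image.transform,
                                default_scene.image.crs)
        crowns = extract_crowns(watershed_instances(e, 4), default_scene.image)
        spec = GridSpec.from_raster(default_scene.image, 30.0)
        layer = count_grid(crowns, spec, CRS)
        assert layer.values.sum() == len(crowns)

    def test_nested_240m_counts_are_block_sums_of_30m(self):
        rng = np.random.default_rng(8)
        crowns = [make_crown(float(x), float(y), crown_id=i + 1)
                  for i, (x, y) in enumerate(zip(rng.uniform(0, 480, 200),
                                                 rng.uniform(0, 480, 200)))]
        top = 480.0
        fine = count_grid(crowns, GridSpec((0.0, top), 30.0, (16, 16)), CRS)
        coarse = count_grid(crowns, GridSpec((0.0, top), 240.0, (2, 2)), CRS)
        block = fine.values.reshape(2, 8, 2, 8).sum(axis=(1, 3))
        np.testing.assert_array_equal(block, coarse.values)


class TestEstimateBias:
    def test_hand_example(self):
        c = CountComparison([5, 3, 4], [4, 3, 3])
        model = estimate_bias(c, patch_area_ha=0.1)
        assert model.F == 10.0
        assert model.me_per_ha == pytest.approx(10 * (2 / 3))

    def test_perfect_predictions_zero_me(self):
        model = estimate_bias(CountComparison([4, 2], [4, 2]), 0.5)
        assert model.me_per_ha == 0.0

    def test_invalid_area_rejected(self):
        with pytest.raises(ValueError):
            estimate_bias(CountComparison([1], [1]), 0.0)


class TestPercentMortality:
    def _layers(self, dead, base):
        spec = _spec(cell=240.0, n=1)
        return (GridLayer(np.array([[float(dead)]]), spec, CRS),
                GridLayer(np.array([[float(base)]]), spec, CRS))

    def test_simple_percentage(self):
        dead, base = self._layers(5, 100)
        assert percent_mortality(dead, base).values[0, 0] == pytest.approx(5.0)

    def test_zero_baseline_is_nodata(self):
        dead, base = self._layers(5, 0)
        assert np.isnan(percent_mortality(dead, base).values[0, 0])

    def test_overshoot_clamped_with_warning(self, caplog):
        dead, base = self._layers(120, 100)
        with caplog.at_level("WARNING", logger="snagmap"):
            out = percent_mortality(dead, base)
        assert out.values[0, 0] == 100.0
        assert any("clamped" in r.message for r in caplog.records)

    def test_misaligned_grids_rejected(self):
        dead, _ = self._layers(5, 100)
        other = GridLayer(np.zeros((1, 1)), GridSpec((5.0, 1000.0), 240.0, (1, 1)), CRS)
        with pytest.raises(ValueError):
            percent_mortality(dead, other)


class TestCanopyMetrics:
    def test_hand_example(self):
        crowns = [make_crown(50, 950, radius_m=np.sqrt(50 / np.pi), crown_id=1),
                  make_crown(60, 960, radius_m=np.sqrt(150 / np.pi), crown_id=2)]
        for c, a in zip(crowns, (50.0, 150.0)):
            c.area_m2 = a
        pct, med = canopy_metrics(crowns, _spec(), CRS)
        assert pct.values[0, 0] == pytest.approx(2.0)
        assert med.values[0, 0] == pytest.approx(100.0)

    def test_empty_cells_nodata(self):
        pct, med = canopy_metrics([], _spec(), CRS)
        assert np.isnan(pct.values).all() and np.isnan(med.values).all()

    def test_full_cell_crown_caps_at_hundred(self):
        crown = make_crown(50, 950)
        crown.area_m2 = 10_000.0
        pct, _ = canopy_metrics([crown], _spec(), CRS)
        assert pct.values[0, 0] == 100.0


class TestBrownPct:
    def _crowns(self, n_brown, n_grey):
        crowns = []
        for i in range(n_brown + n_grey):
            stage = "brown" if i < n_brown else "grey"
            crowns.append(make_crown(10 + i, 990, crown_id=i + 1, stage=stage))
        return crowns

    def test_two_of_four_is_fifty_percent(self):
        layer = brown_pct_grid(self._crowns(2, 2), _spec(), CRS)
        assert layer.values[0, 0] == pytest.approx(50.0)

    def test_single_brown_noise_rule_zeroes_cell(self):
        layer = brown_pct_grid(self._crowns(1, 3), _spec(), CRS)
        assert layer.values[0, 0] == 0.0

    def test_drop_single_brown_option(self):
        layer = brown_pct_grid(self._crowns(1, 3), _spec(), CRS,
                               drop_single_brown=True)
        assert np.isnan(layer.values[0, 0])

    def test_no_dead_trees_nodata(self):
        layer = brown_pct_grid([], _spec(), CRS)
        assert np.isnan(layer.values).all()


class TestThreeProng:
    def _layer(self, values):
        spec = GridSpec((0.0, float(len(values)) * 100.0), 100.0,
                        (len(values[0]), len(values)))
        return GridLayer(np.array(values, dtype=float), spec, CRS)

    def test_percentile_endpoints(self):
        vals = np.linspace(0, 100, 100).reshape(10, 10)
        count = self._layer(vals)
        brown = self._layer(vals)
        size = self._layer(vals)
        rgb = three_prong_map(count, brown, size)
        lo = np.nanmin(rgb)
        hi = np.nanmax(rgb)
        assert lo == 0.0 and hi == 1.0
        # a cell at the 98th percentile of all three is white (1,1,1)
        idx = np.unravel_index(np.nanargmax(count.values), count.values.shape)
        np.testing.assert_allclose(rgb[:, idx[0], idx[1]], 1.0)

    def test_constant_band_becomes_half(self, caplog):
        vals = np.linspace(0, 9, 9).reshape(3, 3)
        const = self._layer(np.full((3, 3), 7.0))
        var = self._layer(vals)
        with caplog.at_level("WARNING", logger="snagmap"):
            rgb = three_prong_map(const, var, var)
        assert np.allclose(rgb[0][~np.isnan(rgb[0])], 0.5)

    def test_nodata_propagates_to_all_bands(self):
        a = np.ones((3, 3))
        a[1, 1] = np.nan
        rgb = three_prong_map(self._layer(a), self._layer(np.ones((3, 3))),
                              self._layer(np.ones((3, 3))))
        assert np.isnan(rgb[:, 1, 1]).all()

    def test_high_count_low_brown_high_size_is_magenta(self):
        rng = np.random.default_rng(0)
        count = self._layer(rng.uniform(0, 10, (10, 10)))
        brown = self._layer(rng.uniform(0, 100, (10, 10)))
        size = self._layer(rng.uniform(0, 300, (10, 10)))
        count.values[0, 0] = 50.0   # far above the 98th percentile
        brown.values[0, 0] = 0.0
        size.values[0, 0] = 500.0
        rgb = three_prong_map(count, brown, size)
        r, g, b = rgb[:, 0, 0]
        assert r == 1.0 and b == 1.0 and g <= 0.05


class TestClusterProfile:
    def test_hand_example(self):
        spec = GridSpec((0.0, 90.0), 30.0, (3, 1))
        layer = GridLayer(np.array([[1.0, 1.0, 3.0]]), spec, CRS)
        prof = cluster_size_profile(layer)
        row1 = prof[prof.k == 1].iloc[0]
        assert row1.n_cells == 2 and row1.n_trees == 2
        assert row1.cum_pct_trees == pytest.approx(40.0)
        row3 = prof[prof.k == 3].iloc[0]
        assert row3.n_cells == 1 and row3.cum_pct_trees == pytest.approx(100.0)

    def test_empty_grid_empty_table(self):
        layer = GridLayer(np.zeros((2, 2)), GridSpec((0, 60.0), 30.0, (2, 2)), CRS)
        assert cluster_size_profile(layer).empty

    def test_bias_corrected_counts_rejected(self):
        layer = GridLayer(np.ones((2, 2)), GridSpec((0, 60.0), 30.0, (2, 2)), CRS,
                          bias_corrected=True)
        with pytest.raises(ValueError):
            cluster_size_profile(layer)
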