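import numpy as np
import pandas as pd
import pytest

from islandcarbon.raster import RasterGrid
from islandcarbon.validation import (extract_map_acd, forest_mask,
                                     jitter_sensitivity, partition_report,
                                     protection_summary, rasterize_polygons,
                                     validate_map, zonal_summary)


def grid(vals, cell=30.0):
    vals = np.asarray(vals, dtype=float)
    return RasterGrid(vals, origin=(0.0, vals.shape[0] * cell), cell_size=cell)


def plot_frame(acd_map, values):
    """Plots at the first len(values) cell centers with given plot ACD."""
    rows = []
    for i, v in enumerate(values):
        r, c = divmod(i, acd_map.shape[1])
        x, y = acd_map.cell_center(r, c)
        rows.append((f"p{i}", float(x), float(y), float(v)))
    return pd.DataFrame(rows, columns=["plot_id", "x", "y", "plot_acd"])


class TestExtraction:
    def test_constant_map_returns_constant_for_any_window(self):
        g = grid(np.full((9, 9), 50.0))
        locs = [("a", 135.0, 135.0)]
        for w in (1, 3, 5):
            out = extract_map_acd(g, locs, window=w)
            assert out.map_acd.iloc[0] == pytest.approx(50.0)

    def test_window_mean_skips_nodata_cells(self):
        vals = np.full((3, 3), 10.0)
        vals[0, :2] = np.nan
        vals[1, :2] = np.nan
        g = grid(vals)
        out = extract_map_acd(g, [("a", 45.0, 45.0)], window=3)
        assert out.map_acd.iloc[0] == pytest.approx(10.0)
        assert out.n_cells.iloc[0] == 5

    def test_corner_plot_window_truncates(self):
        g = grid(np.arange(16.0).reshape(4, 4))
        out = extract_map_acd(g, [("c", 15.0, 105.0)], window=3)  # cell (0, 0)
        assert out.n_cells.iloc[0] == 4
        assert out.map_acd.iloc[0] == pytest.approx(np.mean([0, 1, 4, 5]))

    def test_plot_outside_map_dropped_with_warning(self):
        g = grid(np.ones((3, 3)))
        with pytest.warns(UserWarning, match="outside"):
            out = extract_map_acd(g, [("gone", 1e4, 1e4), ("ok", 45.0, 45.0)])
        assert list(out.plot_id) == ["ok"]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            extract_map_acd(grid(np.ones((3, 3))), [], window=2)


class TestValidate:
    def test_identical_map_and_plots(self):
        g = grid(np.arange(1.0, 17.0).reshape(4, 4))
        plots = plot_frame(g, g.values.ravel()[:6])
        res = validate_map(g, plots, window=1)
        assert res.r2 == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-12)
        assert res.bias == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_gives_bias_equal_rmse(self):
        g = grid(np.arange(1.0, 17.0).reshape(4, 4))
        plots = plot_frame(g, g.values.ravel()[:6] - 10.0)
        res = validate_map(g, plots, window=1)
        assert res.bias == pytest.approx(10.0)
        assert res.rmse == pytest.approx(10.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.r2_sse < 1.0  # the variance-explained variant penalizes offset

    def test_fewer_than_three_pairs_is_an_error(self):
        g = grid(np.ones((3, 3)))
        with pytest.raises(ValueError, match="3"):
            validate_map(g, plot_frame(g, [1.0, 2.0]), window=1)


class TestForestMask:
    def test_class_list_rule(self):
        veg = grid(np.array([[1.0, 5.0], [3.0, 6.0]]))
        mask = forest_mask(veg, rule="veg_classes", classes=[1, 2, 3, 4])
        assert mask.values.tolist() == [[1.0, 0.0], [1.0, 0.0]]

    def test_tch_threshold_rule_and_bare_scene(self):
        tch = grid(np.array([[5.0, 1.0], [2.0, 0.0]]))
        mask = forest_mask(tch, rule="tch", tch_threshold=2.0)
        assert mask.values.sum() == 2.0
        bare = forest_mask(grid(np.zeros((4, 4))), rule="tch")
        assert bare.values.sum() == 0.0

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            forest_mask(grid(np.ones((2, 2))), rule="nope")

    def test_toy_grid_area_matches_hand_count(self):
        veg = grid(np.where(np.arange(100).reshape(10, 10) < 37, 1.0, 9.0))
        mask = forest_mask(veg, rule="veg_classes", classes=[1])
        acd = grid(np.full((10, 10), 10.0))
        zones = grid(np.ones((10, 10)))
        report = zonal_summary(acd, zones, mask)
        assert report.loc[0, "area_ha"] == pytest.approx(37 * 0.09)


class TestZonal:
    def test_stock_equals_area_times_density(self):
        acd = grid(np.full((10, 10), 64.0))
        zones = grid(np.ones((10, 10)))
        rep = zonal_summary(acd, zones)
        assert rep.loc[0, "stock_tg"] == pytest.approx(
            rep.loc[0, "area_ha"] * 64.0 / 1e6)

    def test_splitting_a_zone_conserves_stock_exactly(self):
        rng = np.random.default_rng(0)
        acd = grid(rng.uniform(0, 200, (20, 20)))
        one = grid(np.ones((20, 20)))
        two = grid(np.where(np.arange(400).reshape(20, 20) < 173, 1.0, 2.0))
        total_one = zonal_summary(acd, one).iloc[-1]
        split = zonal_summary(acd, two)
        assert split.loc[:1, "stock_tg"].sum() == pytest.approx(
            total_one["stock_tg"], rel=1e-12)
        assert split.iloc[-1]["area_ha"] == pytest.approx(total_one["area_ha"])

    def test_empty_zone_reported_as_zero_row_with_warning(self):
        acd = grid(np.ones((4, 4)))
        zones = grid(np.ones((4, 4)))
        zones.values[0, 0] = 2.0
        mask = grid(np.ones((4, 4)))
        mask.values[0, 0] = 0.0
        with pytest.warns(UserWarning, match="zone 2"):
            rep = zonal_summary(acd, zones, mask)
        row = rep[rep.zone == "2"].iloc[0]
        assert row.area_ha == 0.0 and row.stock_tg == 0.0


class TestPartition:
    def setup_layers(self):
        rng = np.random.default_rng(1)
        cls = grid(np.where(rng.random((12, 12)) < 0.5, 1.0, 2.0))
        acd_vals = np.where(cls.values == 1, 40.0, 80.0)
        acd = grid(acd_vals + rng.normal(0, 2, (12, 12)))
        elev = grid(rng.uniform(0, 2000, (12, 12)))
        return acd, cls, elev

    def test_single_class_single_bin_matches_zonal_totals(self):
        acd, cls, elev = self.setup_layers()
        ones = grid(np.ones((12, 12)))
        rep = partition_report(acd, None, ones, {1: "all"}, {"elev": elev},
                               {"elev": [0.0, 2000.0]})
        zs = zonal_summary(acd, ones)
        assert rep.area_ha.sum() == pytest.approx(zs.iloc[-1]["area_ha"])
        assert rep.mean_acd.iloc[0] == pytest.approx(zs.iloc[-1]["mean_acd"])

    def test_constructed_two_class_acd_ratio_recovered(self):
        acd, cls, elev = self.setup_layers()
        rep = partition_report(acd, None, cls, {1: "low", 2: "high"},
                               {"elev": elev}, {"elev": [0.0, 1000.0, 2000.0]})
        means = rep.groupby("class").apply(
            lambda d: np.average(d.mean_acd, weights=np.maximum(d.area_ha, 1e-12)),
            include_groups=False)
        assert means["high"] / means["low"] == pytest.approx(2.0, rel=0.1)

    def test_partition_areas_sum_to_masked_area(self):
        acd, cls, elev = self.setup_layers()
        mask = grid((np.arange(144).reshape(12, 12) % 3 == 0).astype(float))
        rep = partition_report(acd, mask, cls, {1: "a", 2: "b"}, {"elev": elev},
                               {"elev": [0.0, 700.0, 1400.0, 2000.0]})
        assert rep.area_ha.sum() == pytest.approx(mask.values.sum() * 0.09)

    def test_nonincreasing_bin_edges_rejected(self):
        acd, cls, elev = self.setup_layers()
        with pytest.raises(ValueError, match="increasing"):
            partition_report(acd, None, cls, {1: "a"}, {"elev": elev},
                             {"elev": [0.0, 500.0, 500.0]})


class TestProtection:
    def test_everything_protected_gives_full_share(self):
        acd = grid(np.full((5, 5), 60.0))
        tenure = grid(np.ones((5, 5)))
        rep = protection_summary(acd, None, tenure).set_index("tenure")
        assert rep.loc["protected", "protected_share_pct"] == pytest.approx(100.0)

    def test_share_matches_stock_ratio(self):
        # 185 protected and 175 unprotected cells of equal density: 51.4 %
        codes = np.zeros(360)
        codes[:185] = 1.0
        tenure = grid(codes.reshape(18, 20))
        acd = grid(np.full((18, 20), 100.0))
        rep = protection_summary(acd, None, tenure).set_index("tenure")
        assert rep.loc["protected", "protected_share_pct"] == pytest.approx(
            100 * 185 / 360, rel=1e-9)

    def test_unlabeled_cells_fall_to_unprotected(self):
        tenure = grid(np.array([[1.0, 7.0], [np.nan, 0.0]]))
        acd = grid(np.full((2, 2), 10.0))
        rep = protection_summary(acd, None, tenure).set_index("tenure")
        assert rep.loc["unprotected", "area_ha"] == pytest.approx(3 * 0.09)


class TestJitterSensitivity:
    def test_constant_map_is_insensitive_to_location_error(self):
        g = grid(np.full((8, 8), 75.0))
        plots = plot_frame(g, [75.0] * 4)
        rep = jitter_sensitivity(g, plots, max_offset=30.0, n_draws=20, seed=0)
        assert np.allclose(rep.jitter_sd, 0.0)
        assert np.allclose(rep.map_acd, 75.0)

    def test_heterogeneous_map_shows_spread_and_is_seeded(self):
        rng = np.random.default_rng(2)
        g = grid(rng.uniform(0, 200, (10, 10)))
        plots = plot_frame(g, [50.0] * 5)
        a = jitter_sensitivity(g, plots, n_draws=15, seed=3)
        b = jitter_sensitivity(g, plots, n_draws=15, seed=3)
        assert a.equals(b)
        assert (a.jitter_sd > 0).any()


def test_polygon_rasterization_by_cell_center():
    from shapely.geometry import box

    template = grid(np.zeros((4, 4)))
    # covers cell centers with x < 60, y > 60: the top-left 2 x 2 block
    out = rasterize_polygons([box(0, 60, 60, 120)], template, [7.0])
    assert np.nansum(out.values) == pytest.approx(28.0)
    assert np.isnan(out.values[3, 3])
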