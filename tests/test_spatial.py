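import math

import numpy as np
import pytest

from paraniche import SynthConfig, aggregate_dataset, generate_dataset
from paraniche.data import Dataset, LayerObservation
from paraniche.spatial import (bray_curtis, build_hex_grid, conflicting_pairs,
                               grid_summarise, plot_distance, quantile_classes,
                               thin_plots)

from conftest import make_plot, make_trait


class TestPlotDistance:
    def test_identical_coordinates(self):
        a = make_plot("a", 5.0, 5.0)
        assert plot_distance(a, a) == 0.0

    def test_planar_3_4_5(self):
        assert plot_distance(make_plot("a", 0, 0), make_plot("b", 3, 4)) == 5.0

    def test_haversine_one_degree_on_equator(self):
        d = plot_distance(make_plot("a", 0.0, 0.0), make_plot("b", 1.0, 0.0),
                          crs_mode="degrees")
        assert d == pytest.approx(111.19, abs=0.1)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            plot_distance(make_plot("a"), make_plot("b"), crs_mode="webmercator")


class TestBrayCurtis:
    def test_identical_is_zero(self):
        assert bray_curtis({"a": 2.0, "b": 1.0}, {"a": 2.0, "b": 1.0}) == 0.0

    def test_disjoint_is_one(self):
        assert bray_curtis({"a": 2.0}, {"b": 5.0}) == 1.0

    def test_worked_example(self):
        assert bray_curtis((2, 0, 1), (1, 1, 0)) == pytest.approx(0.6)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis({}, {})


def _tiny_dataset(positions, covers):
    """Plots at given planar positions with given species->cover maps."""
    headers = [make_plot(f"p{i}", x, y) for i, (x, y) in enumerate(positions)]
    taxa = sorted({t for c in covers for t in c})
    traits = [make_trait(t) for t in taxa]
    obs = [LayerObservation(f"p{i}", t, 1, c)
           for i, cover in enumerate(covers) for t, c in cover.items()]
    return Dataset(headers=headers, observations=obs, traits=traits)


class TestThinning:
    def test_colocated_identical_pair_keeps_one(self):
        ds = _tiny_dataset([(0, 0), (0.1, 0)], [{"a": 50.0}, {"a": 50.0}])
        agg = aggregate_dataset(ds)
        result = thin_plots(ds, agg, seed=0)
        assert len(result.retained) == 1
        assert len(result.dropped) == 1

    def test_distant_plots_all_retained(self):
        ds = _tiny_dataset([(0, 0), (5, 0), (10, 0)], [{"a": 50.0}] * 3)
        agg = aggregate_dataset(ds)
        result = thin_plots(ds, agg, seed=0)
        assert len(result.retained) == 3

    def test_chain_conflicts_resolved(self):
        # A~B and B~C conflict, A and C are 1.2 km apart (no conflict)
        ds = _tiny_dataset([(0, 0), (0.6, 0), (1.2, 0)], [{"a": 50.0}] * 3)
        agg = aggregate_dataset(ds)
        for seed in range(10):
            result = thin_plots(ds, agg, seed=seed)
            remaining = [p for p in conflicting_pairs(ds, agg)
                         if p[0] in result.retained and p[1] in result.retained]
            assert remaining == []

    def test_dissimilarity_mode_flag(self):
        # nearly disjoint compositions: BC ~ 1, so similarity rule keeps both
        ds = _tiny_dataset([(0, 0), (0.1, 0)], [{"a": 50.0}, {"b": 50.0}])
        agg = aggregate_dataset(ds)
        assert len(thin_plots(ds, agg, seed=0, mode="similarity").retained) == 2
        assert len(thin_plots(ds, agg, seed=0, mode="dissimilarity").retained) == 1

    def test_idempotent_and_oracle_clean_on_synthetic(self):
        dataset, _ = generate_dataset(SynthConfig(n_plots=600, dup_pair_fraction=0.1,
                                                  seed=21))
        agg = aggregate_dataset(dataset)
        result = thin_plots(dataset, agg, seed=3)
        # O(n^2) oracle: no retained pair violates the rule
        violating = [p for p in conflicting_pairs(dataset, agg)
                     if p[0] in result.retained and p[1] in result.retained]
        assert violating == []
        # idempotence: thinning the thinned dataset removes nothing
        keep = result.retained
        sub = Dataset(
            headers=[h for h in dataset.headers if h.plot_id in keep],
            observations=[o for o in dataset.observations if o.plot_id in keep],
            traits=dataset.traits)
        sub_agg = {k: v for k, v in agg.items() if k in keep}
        again = thin_plots(sub, sub_agg, seed=99)
        assert again.dropped == []

    def test_seed_reproducible(self):
        dataset, _ = generate_dataset(SynthConfig(n_plots=400, dup_pair_fraction=0.1,
                                                  seed=22))
        agg = aggregate_dataset(dataset)
        a = thin_plots(dataset, agg, seed=7)
        b = thin_plots(dataset, agg, seed=7)
        assert a.retained == b.retained and a.dropped == b.dropped


class TestHexGrid:
    @pytest.mark.parametrize("width,area", [(50.0, 2165.0635), (10.0, 86.6025)])
    def test_cell_area(self, width, area):
        grid = build_hex_grid((0, 0, 200, 200), width)
        assert grid.cell_area_km2 == pytest.approx(area, abs=1e-3)
        for poly in grid.polygons[:5]:
            assert poly.area == pytest.approx(grid.cell_area_km2, rel=1e-6)

    def test_flat_to_flat_width(self):
        grid = build_hex_grid((0, 0, 100, 100), 50.0)
        ymin, ymax = grid.polygons[0].bounds[1], grid.polygons[0].bounds[3]
        assert ymax - ymin == pytest.approx(50.0)

    def test_degenerate_bbox_single_cell(self):
        from shapely.geometry import Point
        grid = build_hex_grid((10.0, 10.0, 10.0, 10.0), 50.0)
        idx = grid.assign(np.array([[10.0, 10.0]]))
        assert grid.polygons[idx[0]].covers(Point(10.0, 10.0))

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            build_hex_grid((0, 0, 1, 1), 0.0)

    def test_every_point_in_its_assigned_cell(self):
        grid = build_hex_grid((0, 0, 300, 300), 50.0)
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 300, size=(200, 2))
        idx = grid.assign(xy)
        from shapely.geometry import Point
        for (x, y), i in zip(xy, idx):
            assert grid.polygons[i].distance(Point(x, y)) < 1e-9


class TestGridSummarise:
    def test_min_plot_rule_and_mean(self):
        grid = build_hex_grid((0, 0, 200, 200), 50.0)
        # 4 plots in one location, 5 in another far away
        xy = np.array([[10.0, 10.0]] * 4 + [[160.0, 160.0]] * 5)
        values = np.array([0.3] * 4 + [0.0, 0.0, 0.0, 0.0, 0.5])
        grid_summarise(grid, xy, {"euphytoid": values}, min_plots=5)
        sparse_cell = grid.assign(np.array([[10.0, 10.0]]))[0]
        dense_cell = grid.assign(np.array([[160.0, 160.0]]))[0]
        assert math.isnan(grid.mean_cover["euphytoid"][sparse_cell])
        assert grid.mean_cover["euphytoid"][dense_cell] == pytest.approx(0.1)

    def test_means_match_bruteforce(self):
        rng = np.random.default_rng(5)
        grid = build_hex_grid((0, 0, 300, 300), 50.0)
        xy = rng.uniform(0, 300, size=(400, 2))
        values = rng.uniform(0, 1, 400)
        grid_summarise(grid, xy, {"t": values}, min_plots=1)
        idx = grid.assign(xy)
        for cell in np.unique(idx):
            expect = values[idx == cell].mean()
            assert grid.mean_cover["t"][cell] == pytest.approx(expect)


class TestQuantileClasses:
    def test_all_zero(self):
        breaks, classes = quantile_classes(np.zeros(10), 5)
        assert len(breaks) == 0 and (classes == 0).all()

    def test_linear_interpolation_breaks(self):
        breaks, classes = quantile_classes(np.arange(1.0, 101.0), 4)
        assert breaks == pytest.approx([25.75, 50.5, 75.25])
        counts = np.bincount(classes)[1:]
        assert counts.tolist() == [25, 25, 25, 25]

    def test_single_nonzero_value(self):
        with pytest.warns(UserWarning):
            _, classes = quantile_classes(np.array([0.0, 0.0, 0.7]), 5)
        assert classes.tolist() == [0, 0, 1]

    def test_zeros_excluded_from_breaks(self):
        values = np.array([0.0] * 50 + list(np.arange(1.0, 11.0)))
        breaks, classes = quantile_classes(values, 2)
        assert breaks == pytest.approx([5.5])
        assert (classes[:50] == 0).all()
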