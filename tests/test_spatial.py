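"""NND, Delaunay, Voronoi, border exclusion, and regularity index."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conemosaic import (
    ConeField,
    DegenerateFieldError,
    SomaSizes,
    Window,
    delaunay_neighbours,
    exclude_border_cells,
    gen_honeycomb,
    gen_mixed_triple_field,
    mosaic_summary,
    nearest_neighbour_distances,
    regularity_index,
    voronoi_domains,
)
from conftest import uniform_field
from oracles import brute_nnd


def field_from(points, window=Window(100, 100), label="single"):
    pts = np.asarray(points, dtype=float)
    return ConeField(pts, np.asarray([label] * len(pts), dtype=object), window)


class TestNND:
    def test_three_four_five_triangle(self):
        f = field_from([(0, 0), (3, 4), (6, 8)])
        np.testing.assert_allclose(
            nearest_neighbour_distances(f, "single"), [5.0, 5.0, 5.0])

    def test_fewer_than_two_points_raises(self):
        with pytest.raises(DegenerateFieldError):
            nearest_neighbour_distances(field_from([(1, 1)]), "single")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n=st.integers(4, 60), seed=st.integers(0, 10_000))
    def test_matches_brute_force(self, n, seed):
        f = uniform_field(n, Window(52, 52), seed)
        np.testing.assert_allclose(
            nearest_neighbour_distances(f, "single"), brute_nnd(f.points),
            rtol=1e-12)


class TestDelaunay:
    def test_square_plus_centre(self):
        f = field_from([(0, 0), (1, 0), (0, 1), (1, 1), (0.5, 0.5)])
        adj = delaunay_neighbours(f, "single")
        assert set(adj[4].tolist()) == {0, 1, 2, 3}

    def test_collinear_points_raise(self):
        with pytest.raises(DegenerateFieldError):
            delaunay_neighbours(field_from([(0, 0), (1, 1), (2, 2)]), "single")

    def test_too_few_points_raise(self):
        with pytest.raises(DegenerateFieldError):
            delaunay_neighbours(field_from([(0, 0), (1, 0)]), "single")

    def test_honeycomb_modal_degree_six(self):
        f = gen_honeycomb(5.0, Window(52, 52), jitter_sd=0.05, seed=1)
        adj = delaunay_neighbours(f, "all")
        interior = exclude_border_cells(f, "single")
        degrees = [len(adj[i]) for i in interior]
        values, counts = np.unique(degrees, return_counts=True)
        assert values[np.argmax(counts)] == 6


class TestVoronoi:
    def test_square_grid_interior_unit_areas(self):
        w = Window(10, 10)
        pts = [(i + 0.5, j + 0.5) for i in range(10) for j in range(10)]
        f = field_from(pts, w)
        areas = voronoi_domains(f, "single")
        interior = exclude_border_cells(f, "single")
        assert interior.size == 64
        np.testing.assert_allclose(areas[interior], 1.0, atol=1e-9)

    def test_honeycomb_interior_hexagon_area(self):
        s = 5.0
        f = gen_honeycomb(s, Window(52, 52), jitter_sd=0.0, seed=0)
        areas = voronoi_domains(f, "single")
        interior = exclude_border_cells(f, "single")
        np.testing.assert_allclose(
            areas[interior], np.sqrt(3) / 2 * s**2, rtol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(4, 50), seed=st.integers(0, 10_000))
    def test_clipped_areas_sum_to_window_area(self, n, seed):
        f = uniform_field(n, Window(52, 52), seed)
        areas = voronoi_domains(f, "single")
        assert np.sum(areas) == pytest.approx(f.window.area_um2, rel=1e-6)

    def test_too_few_points_raise(self):
        with pytest.raises(DegenerateFieldError):
            voronoi_domains(field_from([(0, 0), (5, 5), (9, 2)]), "single")


class TestBorderExclusion:
    def test_two_by_two_grid_has_no_interior(self):
        f = field_from([(2.5, 2.5), (7.5, 2.5), (2.5, 7.5), (7.5, 7.5)],
                       Window(10, 10))
        assert exclude_border_cells(f, "single").size == 0

    def test_ten_by_ten_grid_interior_is_inner_eight_square(self):
        w = Window(10, 10)
        pts = [(i + 0.5, j + 0.5) for i in range(10) for j in range(10)]
        f = field_from(pts, w)
        interior = set(exclude_border_cells(f, "single").tolist())
        expected = {
            idx for idx, (x, y) in enumerate(pts)
            if 1 < x < 9 and 1 < y < 9
        }
        assert interior == expected

    def test_single_point_has_no_interior(self):
        f = field_from([(5, 5)], Window(10, 10))
        assert exclude_border_cells(f, "single").size == 0

    def test_shrinking_window_never_adds_interior_cells(self):
        big = Window(52, 52)
        small = Window(40, 40)
        f_big = uniform_field(60, big, seed=9)
        keep = f_big.window.contains(f_big.points) & small.contains(f_big.points)
        pts_small = f_big.points[keep]
        f_small = ConeField(pts_small,
                            np.asarray(["single"] * len(pts_small), dtype=object),
                            small)
        interior_small = {tuple(p) for p in
                          pts_small[exclude_border_cells(f_small, "single")]}
        interior_big = {tuple(p) for p in
                        f_big.points[exclude_border_cells(f_big, "single")]}
        assert interior_small <= interior_big


class TestRegularityIndex:
    def test_hand_arithmetic(self):
        assert regularity_index([8, 10, 12]) == pytest.approx(5.0)

    def test_zero_sd_gives_infinity(self):
        assert regularity_index([10, 10, 10, 10]) == np.inf

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            regularity_index([10])

    def test_order_lattice_above_hardcore_above_poisson(self):
        """Mosaic order ranks: jittered lattice > soma-constrained random >
        unconstrained random, by median NND regularity index."""
        ri = {"lattice": [], "hardcore": [], "poisson": []}
        for seed in range(20):
            lat = gen_honeycomb(5.0, Window(52, 52), jitter_sd=0.25, seed=seed)
            n = lat.class_counts()["single"]
            hc = gen_mixed_triple_field({"single": n}, SomaSizes(),
                                        Window(52, 52), seed=seed)
            po = uniform_field(n, Window(52, 52), seed=seed)
            for name, f in [("lattice", lat), ("hardcore", hc), ("poisson", po)]:
                ri[name].append(mosaic_summary(f, "single").nnd.regularity_index)
        med = {k: np.median(v) for k, v in ri.items()}
        assert med["lattice"] > med["hardcore"] > med["poisson"]


class TestMosaicSummary:
    def test_perfect_square_grid_statistics(self):
        w = Window(20, 20)
        pts = [(1 + 2 * i, 1 + 2 * j) for i in range(10) for j in range(10)]
        stats = mosaic_summary(field_from(pts, w), "single")
        assert stats.nnd.mean == pytest.approx(2.0)
        assert stats.nnd.sd == pytest.approx(0.0, abs=1e-12)
        assert stats.nnd.regularity_index == np.inf

    def test_summary_consistent_with_per_cell_values(self):
        f = uniform_field(50, Window(52, 52), seed=4)
        stats = mosaic_summary(f, "single")
        assert stats.nnd.mean == pytest.approx(np.mean(stats.nnd_values))
        assert stats.voronoi.sd == pytest.approx(np.std(stats.vd_values, ddof=1))
        assert stats.n_interior == stats.nnd_values.size <= stats.n_total

    def test_hardcore_nnd_minimum_respects_constraint(self):
        for seed in range(20):
            f = gen_mixed_triple_field({"single": 60}, SomaSizes(),
                                       Window(52, 52), seed=seed)
            stats = mosaic_summary(f, "single")
            assert stats.nnd.min >= 2.2

    def test_border_cells_would_change_statistics(self):
        """Guard against silently including border cells: on a honeycomb
        clipped by the window, border Voronoi polygons are truncated, so
        the all-cell mean area differs from the interior mean."""
        f = gen_honeycomb(5.0, Window(52, 52), jitter_sd=0.0, seed=0)
        areas = voronoi_domains(f, "single")
        stats = mosaic_summary(f, "single")
        assert stats.voronoi.mean != pytest.approx(np.mean(areas), rel=1e-3)
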