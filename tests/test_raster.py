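import math

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import box

from burdenmap.raster import (
    Grid,
    GridTransform,
    align_stack,
    classify_urbanicity,
    cost_distance,
    great_circle_km,
    read_ascii_grid,
    read_zones,
    resample_bilinear,
    write_ascii_grid,
    write_zones,
    zone_id_grid,
)


def km_grid(values, cell=1.0):
    values = np.asarray(values, dtype=float)
    t = GridTransform(west=0.0, north=values.shape[0] * cell, dx=cell, dy=cell)
    return Grid(values, t, crs="km")


class TestBilinear:
    def test_identity_on_own_geometry(self):
        rng = np.random.default_rng(0)
        src = km_grid(rng.normal(size=(7, 9)))
        out = resample_bilinear(src, src)
        np.testing.assert_array_equal(out.values, src.values)

    def test_constant_preserved(self):
        src = km_grid(np.full((6, 6), 3.5), cell=1.0)
        template = km_grid(np.zeros((11, 11)), cell=0.5)
        out = resample_bilinear(src, template)
        assert np.allclose(out.values[out.mask], 3.5)

    def test_center_of_2x2(self):
        src = km_grid([[0.0, 1.0], [0.0, 1.0]])
        # template cell centered exactly between the four source centers
        t = GridTransform(west=0.5, north=1.5, dx=1.0, dy=1.0)
        out = resample_bilinear(src, Grid(np.zeros((1, 1)), t, crs="km"))
        assert out.values[0, 0] == pytest.approx(0.5)

    def test_disjoint_extents_rejected(self):
        src = km_grid(np.ones((4, 4)))
        far = Grid(np.zeros((4, 4)), GridTransform(100.0, 104.0, 1.0, 1.0), crs="km")
        with pytest.raises(ValueError):
            resample_bilinear(src, far)

    def test_nodata_propagates_to_touching_cells(self):
        vals = np.ones((4, 4))
        vals[1, 1] = np.nan
        src = km_grid(vals)
        template = km_grid(np.zeros((7, 7)), cell=0.5)
        out = resample_bilinear(src, template)
        assert np.isnan(out.values).any()
        assert np.allclose(out.values[out.mask], 1.0)

    def test_bounded_by_local_corners(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            src = km_grid(rng.normal(size=(6, 8)))
            t = GridTransform(west=rng.uniform(0, 2), north=rng.uniform(4, 6),
                              dx=0.37, dy=0.53)
            out = resample_bilinear(src, Grid(np.zeros((5, 5)), t, crs="km"))
            ok = out.mask
            assert np.all(out.values[ok] >= src.values.min() - 1e-12)
            assert np.all(out.values[ok] <= src.values.max() + 1e-12)


class TestUrbanicity:
    def lonlat_grid(self, values, cell=0.05):
        values = np.asarray(values, dtype=float)
        t = GridTransform(west=38.0, north=9.0 + values.shape[0] * cell,
                          dx=cell, dy=cell)
        return Grid(values, t, crs="EPSG:4326")

    def test_density_thresholds(self):
        # 0.05 deg ~ 5.5 km: the 300 cell next to the 1500 cell is peri-urban
        pop = self.lonlat_grid([[1500.0, 300.0, 100.0]])
        out = classify_urbanicity(pop)
        assert out.values[0, 0] == 2.0
        assert out.values[0, 1] == 1.0
        assert out.values[0, 2] == 0.0

    def test_dense_cell_far_from_urban_is_rural(self):
        vals = np.full((1, 12), 100.0)
        vals[0, 0] = 1500.0
        vals[0, 11] = 300.0  # ~60 km away from the urban cell
        out = classify_urbanicity(self.lonlat_grid(vals))
        assert out.values[0, 11] == 0.0

    def test_monotone_in_density(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1200, size=(6, 6))
        base = classify_urbanicity(self.lonlat_grid(vals))
        bumped_vals = vals.copy()
        bumped_vals[3, 3] += 500
        bumped = classify_urbanicity(self.lonlat_grid(bumped_vals))
        assert np.all(bumped.values >= base.values)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            classify_urbanicity(self.lonlat_grid([[-1.0]]))


class TestCostDistance:
    def test_single_edge_at_unit_spacing(self):
        friction = km_grid(np.ones((1, 2)))
        out = cost_distance(friction, [(0.5, 0.5)])
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] == pytest.approx(1.0)

    def test_diagonal_path_across_uniform_grid(self):
        friction = km_grid(np.ones((5, 5)))
        out = cost_distance(friction, [(0.5, 4.5)])   # top-left corner cell
        assert out.values[4, 4] == pytest.approx(4 * math.sqrt(2))

    def test_all_sources_outside_rejected(self):
        with pytest.raises(ValueError):
            cost_distance(km_grid(np.ones((3, 3))), [(99.0, 99.0)])

    def test_nonpositive_friction_rejected(self):
        with pytest.raises(ValueError):
            cost_distance(km_grid(np.zeros((2, 2))), [(0.5, 0.5)])

    @staticmethod
    def oracle(friction: Grid, source_rc):
        """Independent shortest-path oracle on the 8-connected cell graph."""
        from burdenmap.raster import _edge_lengths_km

        vals = friction.values
        h, w = vals.shape
        ew, ns, diag = _edge_lengths_km(friction)
        G = nx.Graph()
        for r in range(h):
            for c in range(w):
                if not np.isfinite(vals[r, c]):
                    continue
                for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and np.isfinite(vals[r2, c2]):
                        length = ew[r] if (dr, dc) == (0, 1) else (
                            ns if (dr, dc) == (1, 0) else diag[r])
                        G.add_edge((r, c), (r2, c2),
                                   weight=(vals[r, c] + vals[r2, c2]) / 2 * length)
        G.add_node(source_rc)
        return nx.single_source_dijkstra_path_length(G, source_rc)

    @pytest.mark.parametrize("size", range(2, 9))
    @pytest.mark.parametrize("crs", ["km", "EPSG:4326"])
    def test_matches_independent_dijkstra(self, size, crs):
        rng = np.random.default_rng(size)
        for rep in range(3):
            vals = rng.uniform(0.5, 4.0, size=(size, size))
            if rep == 2 and size > 2:  # add a nodata hole
                vals[rng.integers(size), rng.integers(size)] = np.nan
            if crs == "km":
                grid = km_grid(vals)
            else:
                t = GridTransform(west=38.0, north=9.0 + size * 0.05, dx=0.05, dy=0.05)
                grid = Grid(vals, t, crs="EPSG:4326")
            r0, c0 = 0, 0
            if not np.isfinite(vals[r0, c0]):
                continue
            x, y = grid.transform.xy(c0, r0)
            got = cost_distance(grid, [(float(x), float(y))])
            want = self.oracle(grid, (r0, c0))
            for r in range(size):
                for c in range(size):
                    if not np.isfinite(vals[r, c]):
                        assert np.isnan(got.values[r, c])
                    elif (r, c) in want:
                        assert got.values[r, c] == pytest.approx(want[(r, c)], rel=1e-9)
                    else:
                        assert np.isnan(got.values[r, c])


class TestAlignStack:
    def test_identity_template_unchanged(self):
        g = km_grid(np.arange(12, dtype=float).reshape(3, 4))
        stack = align_stack({"a": g}, g)
        np.testing.assert_array_equal(stack["a"].values, g.values)

    def test_nodata_hole_propagates_to_all(self):
        a = km_grid(np.ones((4, 4)))
        b_vals = np.ones((4, 4))
        b_vals[2, 2] = np.nan
        b = km_grid(b_vals)
        stack = align_stack({"a": a, "b": b}, a)
        assert np.isnan(stack["a"].values[2, 2])

    def test_aligned_members_share_transform(self):
        template = km_grid(np.zeros((6, 6)), cell=0.5)
        grids = {f"g{i}": km_grid(np.random.default_rng(i).normal(size=(4, 4)))
                 for i in range(3)}
        stack = align_stack(grids, template)
        assert all(g.transform == template.transform for g in stack.grids.values())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_stack({}, km_grid(np.ones((2, 2))))


class TestIO:
    def test_ascii_grid_round_trip(self, tmp_path):
        vals = np.random.default_rng(1).normal(size=(5, 7))
        vals[0, 0] = np.nan
        g = Grid(vals, GridTransform(36.0, 10.0, 0.05, 0.05), crs="EPSG:4326")
        path = tmp_path / "g.asc"
        write_ascii_grid(g, path)
        back = read_ascii_grid(path)
        np.testing.assert_allclose(back.values[back.mask], vals[np.isfinite(vals)])
        assert np.isnan(back.values[0, 0])
        assert back.transform == g.transform and back.crs == g.crs

    def test_zone_round_trip_and_rasterize(self, tmp_path):
        zones = [("west", box(0.0, 0.0, 2.05, 4.0)), ("east", box(2.05, 0.0, 4.0, 4.0))]
        path = tmp_path / "zones.geojson"
        write_zones(zones, path)
        back = read_zones(path)
        assert [z[0] for z in back] == ["west", "east"]
        template = km_grid(np.zeros((4, 4)))
        ids = zone_id_grid(template, back)
        assert (ids == "west").sum() == 8 and (ids == "east").sum() == 8

    def test_great_circle_known_distance(self):
        # one degree of latitude is ~111.2 km
        assert great_circle_km(38.0, 9.0, 38.0, 10.0) == pytest.approx(111.2, abs=0.5)
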