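import numpy as np
import pytest

from orbitseg.graphsearch import (
    GraphSearchConfig,
    PolarGrid,
    dijkstra_path,
    edge_weight,
    extract_boundary,
    from_polar,
    pad_columns,
    strip_padding,
    to_polar,
)
from orbitseg.localize import RoiSpec
from orbitseg.metrics import dice
from orbitseg.raster import boundary_ring

from conftest import make_ring_map


def brute_force_min_path(values):
    """Exhaustive minimum over all simple corner-to-corner 4-connected paths.

    Depth-first enumeration of self-avoiding walks with sound cost pruning
    (edge weights are nonnegative, so a partial path already costing more
    than the best complete path cannot improve).
    """
    nr, nc = values.shape
    best = [np.inf]
    target = (nr - 1, nc - 1)
    visited = np.zeros((nr, nc), bool)

    def visit(r, c, cost):
        if cost >= best[0]:
            return
        if (r, c) == target:
            best[0] = cost
            return
        visited[r, c] = True
        for dr, dc in ((-1, 0), (0, -1), (1, 0), (0, 1)):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and not visited[r2, c2]:
                visit(r2, c2, cost + 2.0 - (values[r, c] + values[r2, c2]))
        visited[r, c] = False

    visit(0, 0, 0.0)
    return best[0]


def grid_from_values(values, max_radius=None):
    values = np.asarray(values, float)
    return PolarGrid(values=values, center=(0.0, 0.0),
                     max_radius=max_radius or float(values.shape[0]))


class TestEdgeWeight:
    def test_printed_formula_cases(self):
        assert edge_weight(1.0, 1.0) == 0.0
        assert edge_weight(0.0, 0.0) == 2.0
        assert edge_weight(0.6, 0.3) == pytest.approx(1.1)

    def test_bounds_and_symmetry(self, rng):
        for _ in range(100):
            a, b = rng.random(2)
            w = edge_weight(a, b)
            assert 0.0 <= w <= 2.0
            assert w == edge_weight(b, a)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            edge_weight(1.2, 0.0)


class TestToPolar:
    def test_ring_becomes_horizontal_band(self):
        m = make_ring_map((128, 128), (64, 64), 20.0, blur=0.0)
        grid = to_polar(m, (64, 64), n_angles=180, n_radii=90, max_radius=90)
        band_bin = int(round(20 / (90 / 90))) - 1
        band = grid.values[band_bin - 1 : band_bin + 2]
        off_band = np.delete(grid.values, range(band_bin - 2, band_bin + 3), axis=0)
        assert band.max(axis=0).min() > 0.5
        assert off_band.max() < 0.5

    def test_constant_map_constant_grid(self):
        grid = to_polar(np.full((64, 64), 0.7), (32, 32), 90, 30, 30)
        assert np.allclose(grid.values, 0.7, atol=1e-9)

    def test_point_probe_inverse_mapping(self):
        # pixel at center + r0 along theta=0 lands at (radius bin of r0, angle bin 0)
        m = np.zeros((64, 64))
        m[32, 32 + 20] = 1.0
        grid = to_polar(m, (32, 32), n_angles=360, n_radii=40, max_radius=40)
        k = np.unravel_index(np.argmax(grid.values), grid.values.shape)
        assert k[1] == 0
        assert grid.radius_of_bin(k[0]) == pytest.approx(20, abs=1.0)

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError):
            to_polar(np.zeros((10, 10)), (20, 5))


class TestPadColumns:
    def test_width_grows_by_two_pads_per_side(self, rng):
        grid = grid_from_values(rng.random((5, 8)))
        padded = pad_columns(grid, 2)
        assert padded.values.shape == (5, 12)
        assert padded.n_angles == 8

    def test_padded_edge_weight_near_zero(self):
        grid = grid_from_values(np.zeros((3, 3)))
        p = 1.0 - 1e-5
        padded = pad_columns(grid, 2, p)
        w = edge_weight(padded.values[0, 0], padded.values[1, 0])
        assert w == pytest.approx(2 * (1 - p), abs=1e-12)

    def test_path_endpoints_inside_padded_columns(self, rng):
        grid = grid_from_values(rng.random((4, 6)))
        padded = pad_columns(grid)
        path = dijkstra_path(padded)
        assert tuple(path.nodes[0]) == (0, 0)
        assert tuple(path.nodes[-1]) == (3, padded.values.shape[1] - 1)
        assert path.nodes[0, 1] < padded.pad_cols
        assert path.nodes[-1, 1] >= padded.pad_cols + grid.n_angles


class TestDijkstra:
    def test_uniform_grid_matches_any_monotone_path(self):
        vals = np.full((3, 3), 0.4)
        path = dijkstra_path(grid_from_values(vals))
        # all minimal corner-to-corner paths have 4 edges of equal weight
        assert path.cost == pytest.approx(4 * (2 - 0.8))

    @pytest.mark.parametrize("shape", [(3, 3), (4, 4), (3, 5), (5, 4)])
    def test_matches_brute_force_enumeration(self, shape, rng):
        for _ in range(10):
            vals = rng.random(shape)
            got = dijkstra_path(grid_from_values(vals))
            assert got.cost == pytest.approx(brute_force_min_path(vals), abs=1e-9)

    def test_matches_scipy_on_larger_grids(self, rng):
        # independent cross-check against scipy's sparse-graph Dijkstra
        from scipy.sparse import lil_matrix
        from scipy.sparse.csgraph import dijkstra as sp_dijkstra

        vals = rng.random((12, 20))
        nr, nc = vals.shape
        n = nr * nc
        g = lil_matrix((n, n))
        for r in range(nr):
            for c in range(nc):
                for dr, dc in ((0, 1), (1, 0)):
                    r2, c2 = r + dr, c + dc
                    if r2 < nr and c2 < nc:
                        w = 2.0 - (vals[r, c] + vals[r2, c2])
                        g[r * nc + c, r2 * nc + c2] = w
                        g[r2 * nc + c2, r * nc + c] = w
        d = sp_dijkstra(g.tocsr(), indices=0)[n - 1]
        assert dijkstra_path(grid_from_values(vals)).cost == pytest.approx(d, abs=1e-9)

    def test_bright_band_row_is_followed(self):
        vals = np.full((7, 10), 0.05)
        vals[4, :] = 1.0
        padded = pad_columns(grid_from_values(vals))
        path = strip_padding(dijkstra_path(padded), padded)
        assert np.all(path.radius_bins == 4)

    def test_deterministic_across_runs(self, rng):
        vals = rng.random((6, 9))
        a = dijkstra_path(grid_from_values(vals))
        b = dijkstra_path(grid_from_values(vals.copy()))
        assert np.array_equal(a.nodes, b.nodes)
        assert a.cost == b.cost

    def test_monotone_in_on_path_probability(self, rng):
        vals = rng.random((5, 7))
        base = dijkstra_path(grid_from_values(vals))
        node = tuple(base.nodes[len(base.nodes) // 2])
        raised = vals.copy()
        raised[node] = min(1.0, raised[node] + 0.3)
        assert dijkstra_path(grid_from_values(raised)).cost <= base.cost + 1e-12


class TestFromPolar:
    def test_constant_radius_path_maps_to_circle(self):
        grid = grid_from_values(np.zeros((40, 90)), max_radius=40)
        from orbitseg.graphsearch import PolarPath

        path = PolarPath(radius_bins=np.full(90, 19), cost=0.0, nodes=np.zeros((1, 2), int))
        contour = from_polar(path, grid)
        radii = np.hypot(contour[:, 0], contour[:, 1])
        assert np.allclose(radii, grid.radius_of_bin(19), atol=1e-9)

    def test_roi_offset_translates_contour(self):
        grid = grid_from_values(np.zeros((10, 12)), max_radius=10)
        from orbitseg.graphsearch import PolarPath

        path = PolarPath(radius_bins=np.full(12, 4), cost=0.0, nodes=np.zeros((1, 2), int))
        spec = RoiSpec(center=(100.0, 60.0), offset=(36, 0))
        a = from_polar(path, grid)
        b = from_polar(path, grid, spec)
        assert np.allclose(b - a, [36, 0])

    def test_circle_roundtrip_subpixel(self):
        # unwrap a blurred circle, follow the band, map back: radial error small
        r0 = 20.0
        m = make_ring_map((128, 128), (64, 64), r0, thickness=3, blur=1.0)
        contour, _, low = extract_boundary(m, (64.0, 64.0), GraphSearchConfig(smooth_sigma_px=0))
        radii = np.hypot(contour[:, 0] - 64, contour[:, 1] - 64)
        assert abs(radii.mean() - r0) <= 0.5
        assert not low


class TestExtractBoundary:
    def test_ideal_ring_accuracy(self):
        r0 = 22.0
        m = make_ring_map((128, 128), (64, 64), r0, thickness=3, blur=1.0)
        contour, mask, low = extract_boundary(m, (64.0, 64.0))
        radii = np.hypot(contour[:, 0] - 64, contour[:, 1] - 64)
        assert np.abs(radii - r0).mean() <= 1.0
        truth = np.hypot(*np.mgrid[0:128, 0:128] - np.array([64, 64])[:, None, None]) <= r0
        assert dice(mask, truth) >= 0.95
        assert not low

    def test_phantom_triangle_slice(self, ct_volume):
        # hardest case: the smallest, most triangular posterior slice
        s = ct_volume.n_slices - 1
        truth = ct_volume.region_masks[s][:, :128]
        center = tuple(ct_volume.centers[s])
        ring = boundary_ring(truth, 3).astype(float)
        _, mask, _ = extract_boundary(ring, center)
        assert dice(mask, truth) >= 0.95

    def test_flat_map_flagged_low_confidence(self):
        contour, mask, low = extract_boundary(np.zeros((64, 64)), (32.0, 32.0))
        assert low
        assert contour.shape[1] == 2

    def test_contour_never_references_padded_bins(self, rng):
        m = rng.random((64, 64)) * 0.3
        cfg = GraphSearchConfig(n_angles=90)
        contour, _, _ = extract_boundary(m, (32.0, 32.0), cfg)
        assert len(contour) == cfg.n_angles
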