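"""Shape morphometrics against analytic and brute-force oracles."""

import math

import numpy as np
import pytest
from shapely.geometry import MultiPoint

from dolina.delineation import SinkholeInventory, SinkholeRecord, rank_sinkholes
from dolina.grid import ElevationGrid
from dolina.morphometry import (DEFAULT_KERNEL_RADIUS, attach_morphometrics,
                                circularity_index, classify_shape, density_summary,
                                depth_and_volume, elongation_ratio, hull_polygon,
                                kernel_density, min_bounding_box, orientation,
                                orientation_histogram, radius_for_area,
                                recomputed_density_column)
from dolina.synthetic import SinkholeSpec, TerrainTruth, generate_terrain
from tests.conftest import disc_mask


def ellipse_points(a, b, azimuth_deg, n=720, centre=(0.0, 0.0)):
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    x0, y0 = a * np.cos(t), b * np.sin(t)
    th = math.radians(azimuth_deg)
    # rotate so the major axis points at the given azimuth (cw from north)
    x = x0 * math.sin(th) + y0 * math.cos(th) + centre[0]
    y = x0 * math.cos(th) - y0 * math.sin(th) + centre[1]
    return np.column_stack([x, y])


class TestHullPolygon:
    def test_single_cell_unit_square(self):
        cells = np.zeros((3, 3), dtype=bool)
        cells[1, 1] = True
        hull = hull_polygon(cells, 1.0)
        assert hull.area == pytest.approx(1.0)
        assert hull.length == pytest.approx(4.0)

    def test_rectangular_block(self):
        cells = np.zeros((5, 6), dtype=bool)
        cells[1:3, 2:5] = True  # 2 rows x 3 cols
        hull = hull_polygon(cells, 1.0)
        assert hull.area == pytest.approx(6.0)
        assert hull.length == pytest.approx(10.0)

    def test_rasterised_disc_perimeter_near_circumference(self):
        cells = disc_mask((70, 70), 35, 35, 30)
        hull = hull_polygon(cells, 1.0)
        assert hull.length == pytest.approx(2 * math.pi * 30, rel=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hull_polygon(np.zeros((3, 3), dtype=bool), 1.0)


class TestMinBoundingBox:
    def test_axis_aligned_rectangle(self):
        pts = MultiPoint([(0, 0), (10, 0), (10, 20), (0, 20)]).convex_hull
        width, length, az = min_bounding_box(pts)
        assert (width, length) == pytest.approx((10.0, 20.0))
        assert az == pytest.approx(0.0, abs=1e-9)

    def test_unit_square_tie(self):
        pts = MultiPoint([(0, 0), (1, 0), (1, 1), (0, 1)]).convex_hull
        width, length, _ = min_bounding_box(pts)
        assert width == pytest.approx(1.0)
        assert length == pytest.approx(1.0)

    @pytest.mark.parametrize("azimuth", [0.0, 30.0, 77.5, 120.0])
    def test_rotated_ellipse_against_brute_force(self, azimuth):
        poly = MultiPoint(ellipse_points(40, 15, azimuth)).convex_hull
        width, length, az = min_bounding_box(poly)
        # brute force: rotate in 0.1 degree steps, take the min-area AABB
        pts = np.asarray(poly.exterior.coords)
        best = None
        for ang in np.arange(0, 90, 0.1):
            t = math.radians(ang)
            rot = pts @ np.array([[math.cos(t), -math.sin(t)],
                                  [math.sin(t), math.cos(t)]]).T
            ext = rot.max(axis=0) - rot.min(axis=0)
            area = ext[0] * ext[1]
            if best is None or area < best[0]:
                best = (area, min(ext), max(ext))
        assert width == pytest.approx(best[1], rel=1e-3)
        assert length == pytest.approx(best[2], rel=1e-3)
        assert min(abs(az - azimuth), 180 - abs(az - azimuth)) < 1.0

    def test_collinear_degenerates_to_zero_width(self):
        poly = MultiPoint([(0, 0), (1, 1), (3, 3)]).convex_hull
        width, length, az = min_bounding_box(poly)
        assert width == 0.0
        assert length == pytest.approx(math.hypot(3, 3))
        assert az == pytest.approx(45.0)


class TestOrientation:
    @pytest.mark.parametrize("points,expected", [
        ([(0, 0), (0, 5)], 0.0),        # due north-south
        ([(0, 0), (5, 0)], 90.0),       # due east-west
        ([(0, 0), (-3, 3)], 135.0),     # NW-SE
        ([(0, 0), (3, 3)], 45.0),
    ])
    def test_cardinal_conventions(self, points, expected):
        geom = MultiPoint(points).convex_hull
        assert orientation(geom) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-10, 10, size=(20, 2))
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        az = orientation(hull)
        best_d, best_az = -1.0, None
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = math.hypot(*(pts[i] - pts[j]))
                if d > best_d + 1e-12:
                    best_d = d
                    dx, dy = pts[j] - pts[i]
                    best_az = math.degrees(math.atan2(dx, dy)) % 180.0
        assert az == pytest.approx(best_az, abs=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            orientation(MultiPoint([(1, 1)]).convex_hull)


class TestDepthAndVolume:
    def test_three_cell_arithmetic(self):
        dem = ElevationGrid(np.array([[10.0, 9.0, 8.0]]))
        cells = np.ones((1, 3), dtype=bool)
        depth, vol = depth_and_volume(cells, dem, effluent=10.0)
        assert vol == pytest.approx(3.0)
        assert depth == pytest.approx(2.0)

    def test_flat_cells_zero_volume(self):
        dem = ElevationGrid(np.full((4, 4), 7.0))
        cells = np.ones((4, 4), dtype=bool)
        _, vol = depth_and_volume(cells, dem, effluent=9.0)
        assert vol == 0.0

    def test_paraboloid_volume_matches_analytic(self):
        spec = SinkholeSpec(60, 60, 20, 20, 5.0)
        truth = TerrainTruth(specs=[spec], shape=(120, 120), gradient=(0, 0))
        dem = generate_terrain(truth)
        inv = rank_sinkholes(dem)
        assert len(inv) == 1
        rec = inv.records[0]
        _, vol = depth_and_volume(rec.cells, dem, rec.effluent_level)
        analytic = math.pi * 20 * 20 * 5.0 / 2
        assert vol == pytest.approx(analytic, rel=0.05)


class TestIndices:
    def test_elongation_ratio(self):
        assert elongation_ratio(20.0, 10.0) == 2.0
        with pytest.raises(ValueError):
            elongation_ratio(5.0, 0.0)

    def test_circularity_closed_forms(self):
        r = 3.7
        assert circularity_index(math.pi * r * r, 2 * math.pi * r) == pytest.approx(1.0)
        a = 2.0
        assert circularity_index(a * a, 4 * a) == pytest.approx(4 / math.pi)
        assert circularity_index(2 * a * a, 6 * a) == pytest.approx(9 / (2 * math.pi))

    def test_rasterised_disc_circularity_near_one(self):
        cells = disc_mask((70, 70), 35, 35, 30)
        hull = hull_polygon(cells, 1.0)
        circ = circularity_index(float(cells.sum()), hull.length)
        assert 1.0 <= circ <= 1.05

    @pytest.mark.parametrize("r_e,expected", [
        (1.0, "circular"), (1.21, "circular"),
        (1.2100001, "elliptical"), (1.5, "elliptical"), (1.65, "elliptical"),
        (1.66, "sub-elliptical"), (1.8, "sub-elliptical"),
        (1.81, "elongated"), (5.0, "elongated"),
    ])
    def test_shape_class_boundaries(self, r_e, expected):
        assert classify_shape(r_e) == expected

    def test_shape_class_below_one_rejected(self):
        with pytest.raises(ValueError):
            classify_shape(0.9)


class TestEllipseRecovery:
    @pytest.mark.parametrize("azimuth", [30.0, 150.0])
    def test_orientation_and_elongation_from_raster(self, azimuth):
        spec = SinkholeSpec(80, 80, 40, 15, 6.0, azimuth=azimuth)
        truth = TerrainTruth(specs=[spec], shape=(160, 160), gradient=(0, 0))
        dem = generate_terrain(truth)
        inv = rank_sinkholes(dem)
        attach_morphometrics(inv)
        m = inv.records[0].morphometrics
        err = abs(m["orientation"] - azimuth)
        assert min(err, 180 - err) <= 3.0
        assert m["R_e"] == pytest.approx(40 / 15, rel=0.05)


class TestKernelDensity:
    def test_search_radius_for_one_square_km(self):
        assert radius_for_area(1e6) == pytest.approx(564.19, abs=0.01)

    def test_peak_value_at_point(self):
        surf = kernel_density(np.array([[0.0, 0.0]]), out_cell=10.0,
                              extent=(-605, -605, 605, 605))
        # odd cell count: the central cell centre coincides with the point,
        # so the value is K(0) = 3/(pi r^2) = 3.0 per km^2 at the default radius
        r0, c0 = surf.values.shape[0] // 2, surf.values.shape[1] // 2
        assert surf.values.shape[0] % 2 == 1
        assert surf.values[r0, c0] == pytest.approx(3.0, rel=1e-9)

    def test_compact_support(self):
        surf = kernel_density(np.array([[0.0, 0.0]]), radius=100.0,
                              out_cell=10.0, extent=(-300, -300, 300, 300))
        x, y = np.meshgrid(
            surf.origin[0] + (np.arange(surf.values.shape[1]) + 0.5) * 10.0,
            surf.origin[1] - (np.arange(surf.values.shape[0]) + 0.5) * 10.0)
        outside = np.hypot(x, y) >= 100.0
        assert np.all(surf.values[outside] == 0.0)

    def test_unit_mass_numerical_integration(self):
        surf = kernel_density(np.array([[0.0, 0.0]]), out_cell=5.0,
                              extent=(-600, -600, 600, 600))
        mass = surf.values.sum() * (5.0 ** 2) / 1e6  # km^-2 x km^2
        assert mass == pytest.approx(1.0, abs=0.01)

    def test_no_points_zero_surface(self):
        surf = kernel_density(np.empty((0, 2)), extent=(0, 0, 100, 100))
        assert np.all(surf.values == 0.0)


class TestDensitySummary:
    def _fake_inventory(self, centroids, areas):
        dem = ElevationGrid(np.zeros((10, 10)))
        records = []
        for i, ((x, y), area) in enumerate(zip(centroids, areas), start=1):
            cells = np.zeros((10, 10), dtype=bool)
            cells[0, 0] = True
            rec = SinkholeRecord(id=i, rank=1, cells=cells, effluent_level=1.0,
                                 min_elevation=0.0)
            rec.morphometrics = {"centroid_x": x, "centroid_y": y, "S_area": area}
            records.append(rec)
        return SinkholeInventory(records=records, dem=dem)

    def test_densities_recomputed_from_counts_and_areas(self):
        # printed-table consistency: density column equals count / zone area
        counts = np.array([410, 104, 2095])
        areas = np.array([26.09, 0.63, 52.14])
        dens = recomputed_density_column(counts, areas)
        assert np.round(dens, 1).tolist() == [15.7, 165.1, 40.2]

    def test_summary_table_internal_consistency(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(100, 900, size=(40, 2))
        inv = self._fake_inventory([tuple(p) for p in pts], [500.0] * 40)
        surf = kernel_density(pts, radius=200.0, out_cell=20.0,
                              extent=(0, 0, 1000, 1000))
        table = density_summary(surf, inv, class_breaks=(0, 1, 50, 150, 1e6))
        body = table.iloc[:-1]
        total = table.iloc[-1]
        assert body["n_sinkholes"].sum() == 40
        assert total["n_sinkholes"] == 40
        recomputed = recomputed_density_column(body["n_sinkholes"],
                                               body["zone_area_km2"])
        np.testing.assert_allclose(body["density_km2"], recomputed)
        assert total["zone_area_pct"] == pytest.approx(100.0)

    def test_empty_zone_zero_density(self):
        inv = self._fake_inventory([(50.0, 50.0)], [100.0])
        surf = kernel_density(np.array([[50.0, 50.0]]), radius=30.0,
                              out_cell=10.0, extent=(0, 0, 100, 100))
        table = density_summary(surf, inv, class_breaks=(0.0, 1e9, 2e9))
        assert table.iloc[1]["density_km2"] == 0.0

    def test_non_increasing_breaks_rejected(self):
        inv = self._fake_inventory([(1.0, 1.0)], [1.0])
        surf = kernel_density(np.array([[1.0, 1.0]]), radius=10.0,
                              out_cell=5.0, extent=(0, 0, 10, 10))
        with pytest.raises(ValueError):
            density_summary(surf, inv, class_breaks=(0, 5, 5, 10))


class TestOrientationHistogram:
    def _inventory_with_orientations(self, angles):
        dem = ElevationGrid(np.zeros((5, 5)))
        records = []
        for i, ang in enumerate(angles, start=1):
            cells = np.zeros((5, 5), dtype=bool)
            cells[0, 0] = True
            rec = SinkholeRecord(id=i, rank=1, cells=cells, effluent_level=1.0,
                                 min_elevation=0.0)
            rec.morphometrics = {"orientation": ang}
            records.append(rec)
        return SinkholeInventory(records=records, dem=dem)

    def test_counts_conserved_and_binned(self):
        inv = self._inventory_with_orientations([135.0, 135.0, 10.0, 95.0])
        edges, counts = orientation_histogram(inv, bin_width=10.0)
        assert counts.sum() == 4
        assert counts[13] == 2  # [130, 140)
        assert len(edges) == 19

    def test_invalid_bin_width_rejected(self):
        inv = self._inventory_with_orientations([10.0])
        with pytest.raises(ValueError):
            orientation_histogram(inv, bin_width=7.0)

    def test_generator_preferred_azimuth_is_modal(self):
        from dolina.cli import random_specs
        specs = random_specs(40, size=900, seed=3, preferred_azimuth=135.0,
                             azimuth_spread=15.0)
        angles = [s.azimuth for s in specs]
        inv = self._inventory_with_orientations(angles)
        _, counts = orientation_histogram(inv, bin_width=20.0)
        assert np.argmax(counts) == 6  # [120, 140) contains 135
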