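"""Per-sinkhole shape morphometry and landscape density surfaces.

Each confined sinkhole is vectorised to the convex hull of its member-cell
corner points (cells are unit squares).  The minimum-area bounding box of
the hull gives length (major axis) and width (minor axis); their ratio is
the elongation ratio R_e.  The circularity index compares the measured area
with the area of a circle of equal perimeter: Circ_i = A_m / (pi * (2*A_m /
P_m)**2), which equals P_m**2 / (4*pi*A_m) — exactly 1 for a circle and
larger for any other shape.  Orientation is the azimuth (clockwise from
grid north, folded to [0, 180)) of the line joining the two farthest hull
points.

The landscape density surface spreads a quartic (biweight) kernel of unit
mass around each sinkhole centroid:

    K(d) = 3 / (pi * r**2) * (1 - d**2 / r**2)**2   for d < r, else 0

with the search radius r defaulting to the radius of a 1 km**2 circle
(564.2 m), so densities are read directly in sinkholes per km**2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon

from .delineation import SinkholeInventory, SinkholeRecord
from .grid import ElevationGrid

__all__ = [
    "DensitySurface",
    "hull_polygon",
    "min_bounding_box",
    "orientation",
    "depth_and_volume",
    "elongation_ratio",
    "circularity_index",
    "classify_shape",
    "attach_morphometrics",
    "kernel_density",
    "radius_for_area",
    "density_summary",
    "recomputed_density_column",
    "orientation_histogram",
]

#: Search radius (m) of a circular window with area 1 km**2.
DEFAULT_KERNEL_RADIUS = math.sqrt(1e6 / math.pi)

SHAPE_CLASS_BREAKS = (1.21, 1.65, 1.8)


@dataclass
class DensitySurface:
    """Sinkhole density raster in counts per km**2."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    radius: float
    kernel: str = "quartic"

    def as_grid(self) -> ElevationGrid:
        return ElevationGrid(self.values, self.cell_size, self.origin)


def hull_polygon(cells: np.ndarray, cell_size: float,
                 origin: tuple[float, float] = (0.0, 0.0)) -> Polygon:
    """Convex hull of the member cells' outer corner points.

    Cells are treated as squares of side ``cell_size``; all four corners of
    every member cell enter the hull, so a single cell yields its square.
    """
    cells = np.asarray(cells, dtype=bool)
    rows, cols = np.nonzero(cells)
    if rows.size == 0:
        raise ValueError("empty cell set")
    x0, y0 = origin
    cs = cell_size
    xs = np.concatenate([cols * cs, (cols + 1) * cs, cols * cs, (cols + 1) * cs]) + x0
    ys = y0 - np.concatenate([rows * cs, rows * cs, (rows + 1) * cs, (rows + 1) * cs])
    return MultiPoint(np.column_stack([xs, ys])).convex_hull


def _as_polygon(poly: Polygon) -> np.ndarray:
    """Vertex array of a hull, tolerating degenerate (point/line) hulls."""
    if poly.geom_type == "Polygon":
        return np.asarray(poly.exterior.coords)[:-1]
    return np.asarray(poly.coords)


def min_bounding_box(polygon: Polygon) -> tuple[float, float, float]:
    """Minimum-area bounding rectangle (rotating calipers).

    Returns (S_width, S_length, box_azimuth): the shorter and longer side
    lengths and the azimuth (degrees clockwise from north, in [0, 180)) of
    the long side.  Degenerate inputs give width 0 and length = extent.
    """
    verts = _as_polygon(polygon)
    if verts.shape[0] == 1:
        return 0.0, 0.0, 0.0
    rect = shapely.oriented_envelope(polygon)
    coords = _as_polygon(rect)
    if coords.shape[0] < 4:  # collinear input: envelope degenerates to a line
        p, q = coords[0], coords[-1]
        return 0.0, float(np.hypot(*(q - p))), _azimuth(q - p)
    e1 = coords[1] - coords[0]
    e2 = coords[2] - coords[1]
    l1, l2 = float(np.hypot(*e1)), float(np.hypot(*e2))
    if l1 >= l2:
        length, width, axis = l1, l2, e1
    else:
        length, width, axis = l2, l1, e2
    return width, length, _azimuth(axis)


def _azimuth(vec: np.ndarray) -> float:
    """Azimuth of a direction vector, clockwise from north in [0, 180)."""
    az = math.degrees(math.atan2(float(vec[0]), float(vec[1]))) % 180.0
    return az


def orientation(polygon: Polygon) -> float:
    """Azimuth of the hull diameter (line joining the two farthest points).

    Folded to [0, 180) clockwise from grid north; exact north-south is 0.
    Ties between equally long diameters break toward the smaller azimuth.
    """
    verts = _as_polygon(polygon)
    uniq = np.unique(verts, axis=0)
    if uniq.shape[0] < 2:
        raise ValueError("orientation requires at least two distinct points")
    diff = uniq[:, None, :] - uniq[None, :, :]
    d2 = (diff ** 2).sum(axis=2)
    dmax = d2.max()
    best_az = None
    ii, jj = np.nonzero(np.isclose(d2, dmax))
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        az = _azimuth(uniq[j] - uniq[i])
        if best_az is None or az < best_az:
            best_az = az
    assert best_az is not None
    return best_az


def depth_and_volume(cells: np.ndarray, dem: ElevationGrid,
                     effluent: float) -> tuple[float, float]:
    """Sinkhole depth and volume from the original (unfilled) surface.

    Depth is the effluent level minus the minimum member elevation.  Volume
    sums, over member cells, the difference between the maximum member
    elevation and each cell's elevation, times the cell area.
    """
    cells = np.asarray(cells, dtype=bool)
    if not cells.any():
        raise ValueError("empty cell set")
    z = dem.values[cells]
    z_ref = float(np.nanmax(z))
    cell_area = dem.cell_size ** 2
    volume = float(np.nansum(z_ref - z) * cell_area)
    depth = float(effluent - np.nanmin(z))
    return depth, volume


def elongation_ratio(s_length: float, s_width: float) -> float:
    """R_e = S_length / S_width (major over minor axis, >= 1)."""
    if s_width <= 0:
        raise ValueError("width must be positive")
    return s_length / s_width


def circularity_index(area: float, perimeter: float) -> float:
    """Circ_i = A_m / (pi * (2*A_m/P_m)**2); 1 for a perfect circle."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return area / (math.pi * (2.0 * area / perimeter) ** 2)


def classify_shape(r_e: float) -> str:
    """Elongation-ratio shape class.

    circular/sub-circular (R_e <= 1.21), elliptical (1.21 < R_e <= 1.65),
    sub-elliptical (1.65 < R_e <= 1.8), elongated (R_e > 1.8).
    """
    if r_e < 1:
        raise ValueError("elongation ratio must be >= 1")
    if r_e <= SHAPE_CLASS_BREAKS[0]:
        return "circular"
    if r_e <= SHAPE_CLASS_BREAKS[1]:
        return "elliptical"
    if r_e <= SHAPE_CLASS_BREAKS[2]:
        return "sub-elliptical"
    return "elongated"


def attach_morphometrics(inventory: SinkholeInventory) -> SinkholeInventory:
    """Compute and attach all per-record morphometric attributes in place."""
    dem = inventory.dem
    for rec in inventory.records:
        rec.morphometrics = record_morphometrics(rec, dem)
    return inventory


def record_morphometrics(rec: SinkholeRecord, dem: ElevationGrid) -> dict:
    hull = hull_polygon(rec.cells, dem.cell_size, dem.origin)
    width, length, _ = min_bounding_box(hull)
    area = rec.n_cells * dem.cell_size ** 2
    perimeter = float(hull.length) if hull.geom_type == "Polygon" else 0.0
    depth, volume = depth_and_volume(rec.cells, dem, rec.effluent_level)
    out = {
        "S_width": width,
        "S_length": length,
        "S_area": area,
        "S_depth": depth,
        "S_vol": volume,
        "perimeter": perimeter,
        "centroid_x": float(hull.centroid.x),
        "centroid_y": float(hull.centroid.y),
    }
    if width > 0 and perimeter > 0:
        r_e = elongation_ratio(length, width)
        out["R_e"] = r_e
        out["Circ_i"] = circularity_index(area, perimeter)
        out["orientation"] = orientation(hull)
        out["shape_class"] = classify_shape(max(r_e, 1.0))
    return out


def radius_for_area(window_area_m2: float = 1e6) -> float:
    """Search radius (m) of a circular window with the given area (m**2)."""
    if window_area_m2 <= 0:
        raise ValueError("window area must be positive")
    return math.sqrt(window_area_m2 / math.pi)


def kernel_density(points: np.ndarray, radius: float = DEFAULT_KERNEL_RADIUS,
                   out_cell: float = 10.0,
                   extent: tuple[float, float, float, float] | None = None
                   ) -> DensitySurface:
    """Quartic-kernel density surface of sinkhole centroids.

    Each point spreads unit mass over a disc of the search radius with the
    quartic kernel, highest at the point and tapering to zero at the radius.
    Values are reported in counts per km**2.

    Parameters
    ----------
    points
        (n, 2) array of (x, y) centroids in grid CRS metres.
    radius
        Search radius in metres; default is the 1 km**2 window radius.
    out_cell
        Output cell size in metres.
    extent
        (xmin, ymin, xmax, ymax); defaults to the point bounding box padded
        by the radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if extent is None:
        if points.shape[0] == 0:
            raise ValueError("extent required when there are no points")
        xmin, ymin = points.min(axis=0) - radius
        xmax, ymax = points.max(axis=0) + radius
    else:
        xmin, ymin, xmax, ymax = extent
    ncols = max(1, int(math.ceil((xmax - xmin) / out_cell)))
    nrows = max(1, int(math.ceil((ymax - ymin) / out_cell)))
    xs = xmin + (np.arange(ncols) + 0.5) * out_cell
    ys = (ymin + nrows * out_cell) - (np.arange(nrows) + 0.5) * out_cell
    density = np.zeros((nrows, ncols))
    norm = 3.0 / (math.pi * radius ** 2)  # kernel peak; unit total mass
    for px, py in points:
        c0 = max(0, int((px - radius - xmin) / out_cell))
        c1 = min(ncols, int((px + radius - xmin) / out_cell) + 1)
        r0 = max(0, int((ys[0] + out_cell / 2 - (py + radius)) / out_cell))
        r1 = min(nrows, int((ys[0] + out_cell / 2 - (py - radius)) / out_cell) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = xs[c0:c1] - px
        dy = ys[r0:r1] - py
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        u = d2 / radius ** 2
        contrib = np.where(u < 1.0, norm * (1.0 - u) ** 2, 0.0)
        density[r0:r1, c0:c1] += contrib
    density *= 1e6  # per m**2 -> per km**2
    origin = (xmin, ymin + nrows * out_cell)
    return DensitySurface(values=density, cell_size=out_cell, origin=origin,
                          radius=radius)


DEFAULT_DENSITY_BREAKS = (0.0, 1.0, 26.0, 51.0, 76.0, 101.0, 126.0, 151.0)


def density_summary(surface: DensitySurface, inventory: SinkholeInventory,
                    class_breaks: tuple[float, ...] = DEFAULT_DENSITY_BREAKS,
                    rank: int = 1) -> pd.DataFrame:
    """Zonal summary of the density surface against rank-1 sinkholes.

    For each density class: zone area (km**2), share of total area, number
    of rank-``rank`` sinkhole centroids falling in the zone, their density
    (count / zone area), summed sinkhole area (km**2) and its share of the
    zone.  The density column is recomputed from the table's own count and
    area columns.
    """
    breaks = np.asarray(class_breaks, dtype=float)
    if np.any(np.diff(breaks) <= 0):
        raise ValueError("class breaks must be strictly increasing")
    vals = surface.values
    cell_km2 = (surface.cell_size ** 2) / 1e6
    # zone index per surface cell; class i covers [breaks[i], breaks[i+1])
    zone = np.digitize(vals, breaks[1:], right=False)
    nclass = len(breaks) - 1
    records = [r for r in inventory.records if r.rank == rank]
    rows = []
    total_area = vals.size * cell_km2
    for i in range(nclass):
        mask = zone == i
        zone_area = float(mask.sum()) * cell_km2
        count = 0
        sink_area = 0.0
        for rec in records:
            cx = rec.morphometrics.get("centroid_x")
            cy = rec.morphometrics.get("centroid_y")
            if cx is None:
                continue
            col = int((cx - surface.origin[0]) / surface.cell_size)
            row = int((surface.origin[1] - cy) / surface.cell_size)
            if 0 <= row < vals.shape[0] and 0 <= col < vals.shape[1] and mask[row, col]:
                count += 1
                sink_area += rec.morphometrics.get("S_area", 0.0) / 1e6
        rows.append({
            "class_low": breaks[i],
            "class_high": breaks[i + 1],
            "zone_area_km2": zone_area,
            "zone_area_pct": 100.0 * zone_area / total_area if total_area else 0.0,
            "n_sinkholes": count,
            "density_km2": count / zone_area if zone_area > 0 else 0.0,
            "sinkhole_area_km2": sink_area,
            "sinkhole_area_pct": 100.0 * sink_area / zone_area if zone_area > 0 else 0.0,
        })
    total_count = sum(r["n_sinkholes"] for r in rows)
    total_sink = sum(r["sinkhole_area_km2"] for r in rows)
    rows.append({
        "class_low": breaks[0], "class_high": breaks[-1],
        "zone_area_km2": total_area, "zone_area_pct": 100.0,
        "n_sinkholes": total_count,
        "density_km2": total_count / total_area if total_area else 0.0,
        "sinkhole_area_km2": total_sink,
        "sinkhole_area_pct": 100.0 * total_sink / total_area if total_area else 0.0,
    })
    return pd.DataFrame(rows)


def recomputed_density_column(counts, areas_km2) -> np.ndarray:
    """Density (per km**2) recomputed from count and zone-area columns."""
    counts = np.asarray(counts, dtype=float)
    areas = np.asarray(areas_km2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(areas > 0, counts / areas, 0.0)
    return dens


def orientation_histogram(inventory: SinkholeInventory,
                          bin_width: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of record orientations over [0, 180).

    Returns (bin_edges, counts); the bin width must divide 180 evenly.
    """
    nbins = 180.0 / bin_width
    if bin_width <= 0 or abs(nbins - round(nbins)) > 1e-9:
        raise ValueError("bin width must divide 180")
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    angles = [r.morphometrics["orientation"] for r in inventory.records
              if "orientation" in r.morphometrics]
    counts, _ = np.histogram(angles, bins=edges)
    return edges, counts
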