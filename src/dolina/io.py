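"""Serialisation of inventories, truth tables and vegetation surveys.

Inventories are written as GeoJSON (one feature per sinkhole, hull polygon
geometry, all morphometrics as properties; coordinates stay in the DEM's
projected CRS) and as a flat CSV.  Vegetation surveys round-trip through a
long-format CSV (plot_id, location, material, species, proportion).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping

from .delineation import SinkholeInventory
from .morphometry import hull_polygon
from .synthetic import PlotSurvey, TerrainTruth

__all__ = [
    "inventory_to_geojson",
    "inventory_to_dataframe",
    "write_inventory",
    "vegetation_to_dataframe",
    "write_vegetation",
    "read_vegetation",
    "truth_to_dataframe",
    "write_truth",
]

_SCALAR_FIELDS = (
    "S_width", "S_length", "S_area", "S_depth", "S_vol", "R_e", "Circ_i",
    "orientation", "shape_class", "perimeter", "centroid_x", "centroid_y",
)


def inventory_to_geojson(inventory: SinkholeInventory) -> dict:
    dem = inventory.dem
    features = []
    for rec in inventory.records:
        hull = hull_polygon(rec.cells, dem.cell_size, dem.origin)
        props = {
            "id": rec.id,
            "rank": rec.rank,
            "parent_id": rec.parent_id,
            "effluent_level": rec.effluent_level,
            "min_elevation": rec.min_elevation,
            "n_cells": rec.n_cells,
        }
        for key in _SCALAR_FIELDS:
            if key in rec.morphometrics:
                props[key] = rec.morphometrics[key]
        features.append({
            "type": "Feature",
            "geometry": mapping(hull),
            "properties": props,
        })
    return {
        "type": "FeatureCollection",
        "features": features,
        "provenance": dict(inventory.provenance),
    }


def inventory_to_dataframe(inventory: SinkholeInventory) -> pd.DataFrame:
    rows = []
    for rec in inventory.records:
        row = {
            "id": rec.id,
            "rank": rec.rank,
            "parent_id": rec.parent_id,
            "effluent_level": rec.effluent_level,
            "min_elevation": rec.min_elevation,
            "n_cells": rec.n_cells,
        }
        for key in _SCALAR_FIELDS:
            row[key] = rec.morphometrics.get(key)
        rows.append(row)
    columns = ["id", "rank", "parent_id", "effluent_level", "min_elevation",
               "n_cells", *_SCALAR_FIELDS]
    return pd.DataFrame(rows, columns=columns)


def write_inventory(inventory: SinkholeInventory, geojson_path: str | Path,
                    csv_path: str | Path) -> None:
    Path(geojson_path).write_text(
        json.dumps(inventory_to_geojson(inventory), indent=1, default=float))
    inventory_to_dataframe(inventory).to_csv(csv_path, index=False)


def vegetation_to_dataframe(plots: list[PlotSurvey]) -> pd.DataFrame:
    rows = [
        {"plot_id": p.plot_id, "location": p.location, "material": p.material,
         "species": sp, "proportion": prop}
        for p in plots for sp, prop in sorted(p.abundances.items())
    ]
    return pd.DataFrame(rows)


def write_vegetation(plots: list[PlotSurvey], path: str | Path) -> None:
    vegetation_to_dataframe(plots).to_csv(path, index=False)


def read_vegetation(path: str | Path) -> list[PlotSurvey]:
    df = pd.read_csv(path)
    required = {"plot_id", "location", "material", "species", "proportion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"vegetation CSV missing columns {sorted(missing)}")
    plots = []
    for (pid, loc, mat), sub in df.groupby(["plot_id", "location", "material"],
                                           sort=True):
        plots.append(PlotSurvey(
            plot_id=str(pid), location=str(loc), material=str(mat),
            abundances=dict(zip(sub["species"], sub["proportion"]))))
    return plots


def truth_to_dataframe(truth: TerrainTruth) -> pd.DataFrame:
    rows = []
    for i, spec in enumerate(truth.all_specs()):
        rows.append({
            "spec_id": i,
            "centre_x": spec.centre_x,
            "centre_y": spec.centre_y,
            "semi_major": spec.semi_major,
            "semi_minor": spec.semi_minor,
            "depth": spec.depth,
            "azimuth": spec.azimuth,
            "profile": spec.profile,
            "expected_rank": spec.expected_rank,
            "n_children": len(spec.children),
        })
    return pd.DataFrame(rows)


def write_truth(truth: TerrainTruth, geojson_path: str | Path,
                csv_path: str | Path) -> None:
    features = []
    for i, spec in enumerate(truth.all_specs()):
        features.append({
            "type": "Feature",
            "geometry": mapping(spec.footprint()),
            "properties": {"spec_id": i, "depth": spec.depth,
                           "expected_rank": spec.expected_rank},
        })
    Path(geojson_path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, default=float))
    truth_to_dataframe(truth).to_csv(csv_path, index=False)
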