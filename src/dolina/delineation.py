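"""Sinkhole confinement, hierarchical ranking, and the karst filter.

The extraction loop works on water-flow simulation over the DEM:

1. delineate drainage basins of the current surface (one per pit);
2. for each basin, the *effluent level* is the lowest elevation among its
   boundary cells — water above this level spills into the next basin;
3. the cells strictly below the effluent level, in the connected component
   containing the basin minimum, form a confined sinkhole;
4. each confined sinkhole is raised to its effluent level and the loop
   repeats, so depressions that only appear once their inner sinkholes are
   filled are found at the next *rank* — rank 1 sinkholes are the innermost,
   rank k+1 sinkholes contain at least one rank-k sinkhole.

The loop terminates when no basin yields a confined sinkhole (water flow is
then equivalent everywhere).  A final filter removes non-karst depressions
(DEM artefacts and surface noise) below a minimum depth and minimum width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .grid import ElevationGrid
from .hydrology import NEIGHBOURS, delineate_watersheds

__all__ = [
    "SinkholeRecord",
    "SinkholeInventory",
    "effluent_level",
    "confine_sinkhole",
    "rank_sinkholes",
    "filter_karst",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class SinkholeRecord:
    """One confined depression.

    ``cells`` is a boolean mask over the DEM (True = member cell).  Elevation
    attributes refer to the original, unfilled surface; ``effluent_level`` is
    the spill elevation of the basin on the surface at the iteration where
    the record was confined.  Morphometrics are attached later by the
    morphometry module.
    """

    id: int
    rank: int
    cells: np.ndarray
    effluent_level: float
    min_elevation: float
    parent_id: int | None = None
    morphometrics: dict[str, Any] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())


@dataclass
class SinkholeInventory:
    """The ranked sinkhole set for one DEM, plus provenance."""

    records: list[SinkholeRecord]
    dem: ElevationGrid
    provenance: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def by_rank(self, rank: int) -> list[SinkholeRecord]:
        return [r for r in self.records if r.rank == rank]

    def get(self, record_id: int) -> SinkholeRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)


def _boundary_mask(members: np.ndarray) -> np.ndarray:
    """Member cells 8-adjacent to a non-member cell or to the raster edge."""
    interior = ndimage.binary_erosion(members, structure=_STRUCT8, border_value=0)
    return members & ~interior


def effluent_level(watershed_cells: np.ndarray, values: np.ndarray) -> float:
    """Spill (pour-point) elevation of a watershed.

    The effluent level is taken over the watershed's boundary cells (member
    cells 8-adjacent to a non-member or to the raster edge): for each
    boundary cell paired with an adjacent outside cell the water must reach
    ``max(z_member, z_outside)`` to spill there, and a member on the raster
    edge (or beside nodata) spills off-map at its own elevation.  The
    effluent is the minimum over these pour candidates.  When the divide is
    locally symmetric this is exactly the lowest boundary-cell elevation.
    """
    members = np.asarray(watershed_cells, dtype=bool)
    if not members.any():
        raise ValueError("empty watershed")
    z = np.asarray(values, dtype=float)
    nrows, ncols = z.shape
    pad_m = np.zeros((nrows + 2, ncols + 2), dtype=bool)
    pad_m[1:-1, 1:-1] = members
    pad_z = np.full((nrows + 2, ncols + 2), -np.inf)
    pad_z[1:-1, 1:-1] = np.where(np.isnan(z), -np.inf, z)
    best = np.full(z.shape, np.inf)
    for dr, dc in NEIGHBOURS:
        n_member = pad_m[1 + dr: 1 + dr + nrows, 1 + dc: 1 + dc + ncols]
        n_z = pad_z[1 + dr: 1 + dr + nrows, 1 + dc: 1 + dc + ncols]
        pour = np.where(~n_member, np.maximum(z, n_z), np.inf)
        best = np.minimum(best, pour)
    best = np.where(members, best, np.inf)
    eff = float(best.min())
    if not np.isfinite(eff):
        raise ValueError("watershed has no boundary cell")
    return eff


def confine_sinkhole(
    watershed_cells: np.ndarray, values: np.ndarray, effluent: float
) -> np.ndarray:
    """Member cells strictly below the effluent level, restricted to the
    connected component containing the watershed minimum.

    Returns an all-False mask when no cell lies below the effluent.
    """
    watershed_cells = np.asarray(watershed_cells, dtype=bool)
    values = np.asarray(values, dtype=float)
    if not watershed_cells.any():
        raise ValueError("empty watershed")
    with np.errstate(invalid="ignore"):
        below = watershed_cells & (values < effluent)
    if not below.any():
        return below
    masked = np.where(watershed_cells, values, np.inf)
    rmin, cmin = np.unravel_index(np.argmin(masked), values.shape)
    comp, _ = ndimage.label(below, structure=_STRUCT8)
    target = comp[rmin, cmin]
    if target == 0:  # minimum not below effluent: cannot happen if below.any()
        return np.zeros_like(below)
    return comp == target


def rank_sinkholes(dem: ElevationGrid, max_iterations: int | None = None) -> SinkholeInventory:
    """Iteratively confine and fill sinkholes, assigning hierarchy ranks.

    Iteration k delineates watersheds on the current surface, confines each
    basin's sinkhole at its effluent level, assigns those records rank k, and
    raises their cells to the effluent.  Terminates when no basin confines a
    sinkhole.  Parent links are set afterwards by footprint containment.
    """
    values = dem.values
    surface = values.copy()
    n_cells = values.size
    limit = max_iterations if max_iterations is not None else n_cells
    records: list[SinkholeRecord] = []
    next_id = 1
    iteration = 0
    while True:
        iteration += 1
        if iteration > limit:
            raise RuntimeError("sinkhole ranking did not terminate")
        ws = delineate_watersheds(surface)
        found: list[SinkholeRecord] = []
        for lab in ws.pit_cells:
            members = ws.label == lab
            eff = effluent_level(members, surface)
            cells = confine_sinkhole(members, surface, eff)
            if not cells.any():
                continue
            found.append(
                SinkholeRecord(
                    id=next_id,
                    rank=iteration,
                    cells=cells,
                    effluent_level=eff,
                    min_elevation=float(np.nanmin(values[cells])),
                )
            )
            next_id += 1
        if not found:
            break
        for rec in found:
            surface[rec.cells] = rec.effluent_level
        records.extend(found)
    _assign_parents(records)
    return SinkholeInventory(records=records, dem=dem,
                             provenance={"iterations": iteration - 1})


def _assign_parents(records: list[SinkholeRecord]) -> None:
    """Link each record to the lowest-rank higher-rank record containing it."""
    by_rank: dict[int, list[SinkholeRecord]] = {}
    for rec in records:
        by_rank.setdefault(rec.rank, []).append(rec)
    ranks = sorted(by_rank)
    for rec in records:
        rec.parent_id = None
        # representative member cell: any True cell
        rows, cols = np.nonzero(rec.cells)
        rrep, crep = int(rows[0]), int(cols[0])
        for rank in ranks:
            if rank <= rec.rank:
                continue
            for cand in by_rank[rank]:
                if cand.cells[rrep, crep]:
                    rec.parent_id = cand.id
                    break
            if rec.parent_id is not None:
                break


def filter_karst(
    inventory: SinkholeInventory,
    min_depth: float = 2.0,
    min_width: float = 10.0,
) -> SinkholeInventory:
    """Remove non-karst depressions: keep records with depth >= ``min_depth``
    (metres) and minimum-bounding-box width >= ``min_width`` (metres).

    Thresholds are inclusive.  A record whose footprint contains surviving
    nested sinkholes must additionally add at least ``min_depth`` of closure
    of its own — its effluent level minus the minimum original elevation over
    its cells *outside* all surviving nested records.  Without this marginal
    test, every true sinkhole on noisy terrain is shadowed by a near-identical
    higher-rank duplicate created when a sub-threshold noise pit beside the
    spill is merged in (the pour rises by centimetres, so the raw depth still
    passes); a genuine higher-rank sinkhole, by contrast, closes metres of
    relief beyond its nested members.  The surviving records are re-linked
    and their ranks renumbered from the surviving containment hierarchy (a
    surviving record with no surviving nested sinkhole is rank 1); the
    delineation itself is not re-run.
    """
    if min_depth < 0 or min_width < 0:
        raise ValueError("thresholds must be non-negative")
    candidates: list[SinkholeRecord] = []
    for rec in inventory.records:
        depth = rec.morphometrics.get("S_depth")
        width = rec.morphometrics.get("S_width")
        if depth is None or width is None:
            raise ValueError(
                f"record {rec.id} lacks morphometrics; compute them before filtering"
            )
        if depth >= min_depth and width >= min_width:
            candidates.append(rec)
    # marginal-closure test, processed innermost first so that removed
    # shadows never shield their own parents
    values = inventory.dem.values
    kept: list[SinkholeRecord] = []
    for rec in sorted(candidates, key=lambda r: r.n_cells):
        inside = [k for k in kept if rec.cells[np.nonzero(k.cells)[0][0],
                                              np.nonzero(k.cells)[1][0]]]
        if inside:
            covered = np.zeros_like(rec.cells)
            for k in inside:
                covered |= k.cells
            own = rec.cells & ~covered
            if not own.any():
                continue
            if rec.effluent_level - float(np.nanmin(values[own])) < min_depth:
                continue
        kept.append(rec)
    _assign_parents(kept)
    # renumber ranks bottom-up: leaf survivor = 1, parent = 1 + max child rank
    children: dict[int | None, list[SinkholeRecord]] = {}
    for rec in kept:
        children.setdefault(rec.parent_id, []).append(rec)

    def depth_rank(rec: SinkholeRecord) -> int:
        kids = children.get(rec.id, [])
        if not kids:
            return 1
        return 1 + max(depth_rank(k) for k in kids)

    for rec in kept:
        rec.rank = depth_rank(rec)
    prov = dict(inventory.provenance)
    prov.update({"min_depth": min_depth, "min_width": min_width})
    return SinkholeInventory(records=kept, dem=inventory.dem, provenance=prov)
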