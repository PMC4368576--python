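"""Raster hydrology: depression filling, D8 routing, accumulation, watersheds.

Depression filling uses the priority-flood algorithm: cells are processed
outward from the raster boundary in elevation order, so every cell ends up
with a non-ascending 8-connected path to the edge and is raised by the
minimum amount that achieves this.  A small epsilon increment is applied on
flats so the filled surface drains unambiguously; sinkhole depths are always
measured on the *original* surface, so the epsilon never touches morphometry.

Flow routing is D8 (single steepest-descent neighbour, drop divided by
centre-to-centre distance).  Ties between equally steep neighbours break by
the fixed order E, SE, S, SW, W, NW, N, NE.  Nodata cells are treated as
off-map; edge cells with no lower in-map neighbour drain off-map (OUTLET).
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "OUTLET",
    "PIT",
    "FlowField",
    "WatershedLabels",
    "fill_depressions",
    "flow_direction",
    "flow_accumulation",
    "delineate_watersheds",
]

# neighbour offsets in tie-break order: E, SE, S, SW, W, NW, N, NE
NEIGHBOURS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)
_DIAG = (False, True, False, True, False, True, False, True)

OUTLET: int = -1  # direction code: drains off-map
PIT: int = -2     # direction code: interior cell with no descent (unfilled surfaces)


@dataclass
class FlowField:
    """Per-cell D8 direction codes and upstream-cell counts.

    ``direction`` holds, per cell, an index into ``NEIGHBOURS`` (0..7),
    ``OUTLET`` for cells draining off-map, or ``PIT`` for interior cells with
    no strictly lower neighbour (only on unfilled surfaces).
    """

    direction: np.ndarray
    accumulation: np.ndarray | None = None


@dataclass
class WatershedLabels:
    """Per-cell basin ids.  Label 0 is the off-map (OUTLET) basin; labels
    1..n_basins are closed-depression basins, each with a recorded pit cell."""

    label: np.ndarray
    pit_cells: dict[int, tuple[int, int]]

    @property
    def n_basins(self) -> int:
        return len(self.pit_cells)


def _validated(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("elevation array must be 2-D")
    if np.all(np.isnan(values)):
        raise ValueError("all cells are nodata")
    return values


def fill_depressions(values: np.ndarray, epsilon: float = 1e-5) -> tuple[np.ndarray, np.ndarray]:
    """Fill closed depressions to their hydrologic spill point (priority flood).

    Parameters
    ----------
    values
        Elevations (2-D, NaN = nodata/off-map).
    epsilon
        Increment imposed on flats so the filled surface drains everywhere.
        Pass 0 for the exact minimal fill (the filled surface then contains
        flats and is not directly routable).

    Returns
    -------
    filled, raised_mask
        Filled surface (>= input everywhere) and a boolean mask of cells that
        were strictly raised.
    """
    values = _validated(values)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    nrows, ncols = values.shape
    filled = np.full_like(values, np.inf)
    closed = np.zeros(values.shape, dtype=bool)
    nan_mask = np.isnan(values)
    # seed: edge cells and cells adjacent to nodata (nodata = off-map)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    edge = np.zeros(values.shape, dtype=bool)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    if nan_mask.any():
        near_nan = ndimage.binary_dilation(
            nan_mask, structure=np.ones((3, 3), dtype=bool))
        edge |= near_nan
    seeds = edge & ~nan_mask
    for r, c in zip(*np.nonzero(seeds)):
        filled[r, c] = values[r, c]
        closed[r, c] = True
        heapq.heappush(heap, (values[r, c], counter, int(r), int(c)))
        counter += 1
    closed[nan_mask] = True
    filled[nan_mask] = np.nan
    while heap:
        z, _, r, c = heapq.heappop(heap)
        for dr, dc in NEIGHBOURS:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < nrows and 0 <= nc < ncols) or closed[nr, nc]:
                continue
            closed[nr, nc] = True
            zn = values[nr, nc]
            if zn <= z:  # inside a depression or flat: raise
                zn = z + epsilon
            filled[nr, nc] = zn
            heapq.heappush(heap, (zn, counter, nr, nc))
            counter += 1
    raised = (filled > values) & ~nan_mask
    return filled, raised


def _steepest_descent(values: np.ndarray) -> np.ndarray:
    """Vectorised D8 direction codes on a surface (NaN = off-map).

    Off-map (beyond the raster or nodata) never captures flow except as the
    OUTLET fallback for cells with no strictly lower in-map neighbour that
    touch the raster edge or a nodata cell.
    """
    nrows, ncols = values.shape
    padded = np.full((nrows + 2, ncols + 2), np.nan)
    padded[1:-1, 1:-1] = values
    drops = np.full((8, nrows, ncols), -np.inf)
    touches_offmap = np.zeros(values.shape, dtype=bool)
    for k, (dr, dc) in enumerate(NEIGHBOURS):
        zn = padded[1 + dr: 1 + dr + nrows, 1 + dc: 1 + dc + ncols]
        offmap = np.isnan(zn)
        touches_offmap |= offmap
        dist = np.sqrt(2.0) if _DIAG[k] else 1.0
        with np.errstate(invalid="ignore"):
            drops[k] = np.where(offmap, -np.inf, (values - zn) / dist)
    best = np.argmax(drops, axis=0)  # first max wins: tie-break order E..NE
    best_drop = np.take_along_axis(drops, best[None], axis=0)[0]
    direction = np.where(best_drop > 0, best, np.where(touches_offmap, OUTLET, PIT))
    direction[np.isnan(values)] = OUTLET
    return direction.astype(np.int8)


def flow_direction(filled_values: np.ndarray) -> np.ndarray:
    """D8 direction codes for a filled (everywhere-draining) surface.

    Raises if any interior cell has no strictly lower neighbour, which cannot
    happen after epsilon filling.
    """
    filled_values = _validated(filled_values)
    direction = _steepest_descent(filled_values)
    if np.any(direction == PIT):
        raise RuntimeError("unresolvable flat or pit on a supposedly filled surface")
    return direction


def flow_accumulation(direction: np.ndarray) -> np.ndarray:
    """Upstream cell counts from a D8 direction field (topological order).

    A cell with no inflow has accumulation 0; each cell's count is the sum of
    (count + 1) over its immediate upstream neighbours.
    """
    direction = np.asarray(direction)
    if np.any(direction == PIT):
        raise ValueError("direction field contains pits; fill the surface first")
    nrows, ncols = direction.shape
    n = nrows * ncols
    flat_dir = direction.ravel()
    downstream = np.full(n, -1, dtype=np.int64)
    rr, cc = np.divmod(np.arange(n), ncols)
    valid = flat_dir >= 0
    drs = np.array([d[0] for d in NEIGHBOURS])
    dcs = np.array([d[1] for d in NEIGHBOURS])
    nr = rr[valid] + drs[flat_dir[valid]]
    nc = cc[valid] + dcs[flat_dir[valid]]
    if np.any((nr < 0) | (nr >= nrows) | (nc < 0) | (nc >= ncols)):
        raise ValueError("direction points off the raster")
    downstream[valid] = nr * ncols + nc
    indegree = np.bincount(downstream[downstream >= 0], minlength=n)
    acc = np.zeros(n, dtype=np.int64)
    queue = deque(np.nonzero(indegree == 0)[0].tolist())
    processed = 0
    while queue:
        i = queue.popleft()
        processed += 1
        j = downstream[i]
        if j >= 0:
            acc[j] += acc[i] + 1
            indegree[j] -= 1
            if indegree[j] == 0:
                queue.append(j)
    if processed != n:
        raise ValueError("cycle detected in direction field")
    return acc.reshape(nrows, ncols)


def delineate_watersheds(values: np.ndarray) -> WatershedLabels:
    """Label drainage basins of the (unfilled) surface.

    Every cell is assigned to the basin of the depression minimum — or the
    off-map OUTLET, label 0 — that its steepest-descent path reaches.  Flat
    regions drain toward any adjacent equal-elevation cell that itself
    drains (breadth-first from the flat's outlets); flats with no such exit
    are pits and seed new basins.
    """
    values = _validated(values)
    nrows, ncols = values.shape
    direction = _steepest_descent(values)
    label = np.full(values.shape, -1, dtype=np.int64)
    nan_mask = np.isnan(values)
    label[nan_mask] = 0
    label[direction == OUTLET] = 0
    drs = np.array([d[0] for d in NEIGHBOURS])
    dcs = np.array([d[1] for d in NEIGHBOURS])

    # Flat cells (no strictly lower neighbour, interior).  Adjacent flat
    # cells necessarily share one elevation, so plain connected components
    # are flat components.  A component with no member adjacent to an
    # equal-elevation draining cell is a true pit and seeds a basin; all
    # other flats drain through their equal-elevation exits.
    pit_cells: dict[int, tuple[int, int]] = {}
    flat_mask = direction == PIT
    if flat_mask.any():
        comp, n_comp = ndimage.label(flat_mask, structure=np.ones((3, 3)))
        next_label = 1
        for k in range(1, n_comp + 1):
            rows_k, cols_k = np.nonzero(comp == k)
            z_flat = values[rows_k[0], cols_k[0]]
            has_exit = False
            for r, c in zip(rows_k, cols_k):
                for dr, dc in NEIGHBOURS:
                    nr, nc = r + dr, c + dc
                    if (0 <= nr < nrows and 0 <= nc < ncols
                            and not flat_mask[nr, nc]
                            and values[nr, nc] == z_flat):
                        has_exit = True
                        break
                if has_exit:
                    break
            if not has_exit:
                lab = next_label
                next_label += 1
                label[rows_k, cols_k] = lab
                pit_cells[lab] = (int(rows_k[0]), int(cols_k[0]))

    # Ascending sweep: a cell with a strictly lower steepest neighbour takes
    # that neighbour's label, which is already set unless the neighbour is an
    # unresolved flat; leftovers (draining flats and their dependants) are
    # resolved by breadth-first adoption afterwards.
    order = np.argsort(values, axis=None, kind="stable")
    for idx in order:
        r, c = divmod(int(idx), ncols)
        if label[r, c] >= 0:
            continue
        d = direction[r, c]
        if d >= 0:
            label[r, c] = label[r + drs[d], c + dcs[d]]

    unresolved = np.nonzero(label.ravel() < 0)[0]
    queue = deque(int(i) for i in unresolved)
    stall = 0
    limit = 8 * nrows * ncols
    while queue:
        if stall > limit:
            raise RuntimeError("watershed labelling failed to converge")
        idx = queue.popleft()
        r, c = divmod(idx, ncols)
        if label[r, c] >= 0:
            continue
        d = direction[r, c]
        adopted = -1
        if d >= 0:
            adopted = label[r + drs[d], c + dcs[d]]
        else:  # draining flat: adopt from an equal-elevation labelled cell
            for dr, dc in NEIGHBOURS:
                nr, nc = r + dr, c + dc
                if (0 <= nr < nrows and 0 <= nc < ncols
                        and label[nr, nc] >= 0
                        and values[nr, nc] == values[r, c]):
                    adopted = label[nr, nc]
                    break
        if adopted >= 0:
            label[r, c] = adopted
            stall = 0
        else:
            queue.append(idx)
            stall += 1
    return WatershedLabels(label=label, pit_cells=pit_cells)
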