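import numpy as np
import pytest

from dolina.grid import ElevationGrid


def disc_mask(shape, centre_row, centre_col, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - centre_row) ** 2 + (cc - centre_col) ** 2 <= radius ** 2


@pytest.fixture
def two_pit_bowl():
    """Two pits (3, 4) sharing a saddle (5) inside a bowl (ring 7, border 10).

    Expected extraction: two rank-1 records confined at the saddle, then one
    rank-2 record for the whole bowl.
    """
    values = np.array([
        [10, 10, 10, 10, 10, 10, 10],
        [10, 7, 7, 7, 7, 7, 10],
        [10, 7, 3, 5, 4, 7, 10],
        [10, 7, 7, 7, 7, 7, 10],
        [10, 10, 10, 10, 10, 10, 10],
    ], dtype=float)
    return ElevationGrid(values)


@pytest.fixture
def three_level_nest():
    """Outer bowl containing two sub-bowls joined by a low ridge.

    Sub-bowl B1 (floor 5, spill over the 7.5 ridge) holds two karst pits
    (floor 2.5, saddle 5).  Sub-bowl B2 (floor 6.5, same ridge) holds two
    centimetre-scale pits (floor 6.3) — everything on the B2 side is below
    the 2 m karst depth criterion.  The outer bowl (floor 8, rim 10) closes
    both.  Raw ranking yields ranks {1, 1, 1, 1, 2, 2, 3}; the karst filter
    removes the B2-side records (sub-threshold depth / marginal closure) and
    the surviving hierarchy renumbers to {1, 1, 2, 3}.
    """
    values = np.full((101, 141), 10.0)
    values[disc_mask(values.shape, 50, 70, 45)] = 8.0   # outer bowl floor
    values[disc_mask(values.shape, 50, 45, 16)] = 5.0   # B1 floor
    values[disc_mask(values.shape, 50, 95, 16)] = 6.5   # B2 floor
    values[disc_mask(values.shape, 42, 45, 6)] = 2.5    # karst pit 1
    values[disc_mask(values.shape, 58, 45, 6)] = 2.5    # karst pit 2
    values[disc_mask(values.shape, 44, 95, 4)] = 6.3    # noise pit 1
    values[disc_mask(values.shape, 56, 95, 4)] = 6.3    # noise pit 2
    values[50, 62:79] = 7.5                             # ridge channel B1-B2
    return ElevationGrid(values)


@pytest.fixture
def fill_oracle():
    """Exhaustive depression-filling oracle: iterate "lower every cell to
    max(own elevation, lowest filled neighbour)" from +inf to the fixpoint.

    Independent of the priority-flood implementation; O(n^2) but fine for
    the small grids used in tests.
    """

    def _fill(values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        nrows, ncols = values.shape
        filled = np.full_like(values, np.inf)
        filled[0, :] = values[0, :]
        filled[-1, :] = values[-1, :]
        filled[:, 0] = values[:, 0]
        filled[:, -1] = values[:, -1]
        changed = True
        while changed:
            changed = False
            for r in range(nrows):
                for c in range(ncols):
                    lowest = np.inf
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            if dr == dc == 0:
                                continue
                            nr, nc = r + dr, c + dc
                            if 0 <= nr < nrows and 0 <= nc < ncols:
                                lowest = min(lowest, filled[nr, nc])
                    new = max(values[r, c], lowest)
                    if new < filled[r, c]:
                        filled[r, c] = new
                        changed = True
        return filled

    return _fill
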