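"""D8 / MFD flow direction, flow accumulation, and upstream tracing.

Neighbor order is fixed as (E, SE, S, SW, W, NW, N, NE), index 0-7; ties in
steepest descent are broken by the lowest neighbor index. Diagonal neighbors
use a flow distance of ``cell_size * sqrt(2)``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid

#: (drow, dcol) offsets in neighbor order E, SE, S, SW, W, NW, N, NE
OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)
_DIAG = np.array([1.0, np.sqrt(2.0), 1.0, np.sqrt(2.0), 1.0, np.sqrt(2.0), 1.0, np.sqrt(2.0)])

#: default Freeman (1991) MFD slope exponent
MFD_EXPONENT = 1.1


class FlowError(ValueError):
    pass


@dataclass
class FlowDirGrid:
    """Per-cell flow directions.

    ``d8[r, c]`` holds the neighbor index 0-7 of the steepest-descent target,
    or -1 for outlets (boundary / nodata-adjacent cells with no lower
    neighbor) and nodata cells. ``mfd`` (if present) holds the slope-weighted
    fraction of the cell's outflow sent to each of the 8 neighbors.
    """

    d8: np.ndarray
    valid: np.ndarray
    cell_size: float
    mfd: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.d8.shape

    def d8_target(self, row: int, col: int) -> tuple[int, int] | None:
        k = self.d8[row, col]
        if k < 0:
            return None
        dr, dc = OFFSETS[k]
        return row + dr, col + dc


@dataclass
class AccumGrid:
    """Per-cell accumulated area in cells, including the cell itself."""

    values: np.ndarray
    mode: str = "d8"


def _neighbor_drops(dem: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    """Stack of (8, nrows, ncols) elevation drops per unit distance.

    Off-grid and nodata neighbors get -inf. Second return: mask of cells
    adjacent to the grid edge or to a nodata cell (candidate outlets).
    """
    z = dem.values
    nrows, ncols = z.shape
    pad = np.pad(z, 1, constant_values=np.nan)
    drops = np.empty((8, nrows, ncols))
    at_rim = np.zeros((nrows, ncols), dtype=bool)
    for k, (dr, dc) in enumerate(OFFSETS):
        nz = pad[1 + dr : 1 + dr + nrows, 1 + dc : 1 + dc + ncols]
        nan = np.isnan(nz)
        at_rim |= nan
        d = (z - nz) / (_DIAG[k] * dem.cell_size)
        drops[k] = np.where(nan, -np.inf, d)
    return drops, at_rim


def _check_interior_flats(dem: RasterGrid, no_descent: np.ndarray, at_rim: np.ndarray) -> None:
    bad = no_descent & dem.valid & ~at_rim
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FlowError(
            f"cell ({r}, {c}) has no downslope neighbor and is not at a drainage "
            "boundary; run fill_depressions on the DEM first"
        )


def d8_directions(dem: RasterGrid) -> FlowDirGrid:
    """Steepest-descent single flow direction on a depression-filled DEM."""
    drops, at_rim = _neighbor_drops(dem)
    best = np.argmax(drops, axis=0)  # first max wins -> lowest neighbor index
    maxdrop = np.take_along_axis(drops, best[None], axis=0)[0]
    has_descent = maxdrop > 0
    _check_interior_flats(dem, ~has_descent, at_rim)
    d8 = np.where(dem.valid & has_descent, best, -1).astype(np.int8)
    return FlowDirGrid(d8=d8, valid=dem.valid, cell_size=dem.cell_size)


def mfd_directions(dem: RasterGrid, exponent: float = MFD_EXPONENT) -> FlowDirGrid:
    """Freeman-style multiple flow directions: weight to each strictly lower
    neighbor proportional to (slope to that neighbor) ** exponent."""
    drops, at_rim = _neighbor_drops(dem)
    best = np.argmax(drops, axis=0)
    maxdrop = np.take_along_axis(drops, best[None], axis=0)[0]
    has_descent = maxdrop > 0
    _check_interior_flats(dem, ~has_descent, at_rim)
    pos = np.where(drops > 0, drops, 0.0)
    w = pos ** exponent
    tot = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(tot > 0, w / tot, 0.0)
    w = np.moveaxis(w, 0, -1)
    w[~dem.valid] = 0.0
    d8 = np.where(dem.valid & has_descent, best, -1).astype(np.int8)
    return FlowDirGrid(d8=d8, valid=dem.valid, cell_size=dem.cell_size, mfd=w)


def accumulate(fd: FlowDirGrid, mode: str = "d8") -> AccumGrid:
    """Topological-order flow accumulation.

    ``value(cell) = 1 + sum of inflowing contributions`` — whole upstream
    cells for D8, slope-weighted fractions for MFD. nodata cells are NaN.
    """
    if mode not in ("d8", "mfd"):
        raise ValueError(f"unknown accumulation mode {mode!r}")
    if mode == "mfd" and fd.mfd is None:
        raise FlowError("accumulate(mode='mfd') requires MFD weights (use mfd_directions)")
    nrows, ncols = fd.shape
    valid = fd.valid
    acc = np.where(valid, 1.0, np.nan)

    # out_w[k, r, c]: fraction of (r, c)'s outflow sent to neighbor k
    if mode == "d8":
        out_w = np.zeros((8, nrows, ncols))
        for k in range(8):
            out_w[k] = (fd.d8 == k).astype(float)
    else:
        out_w = np.moveaxis(fd.mfd, -1, 0).copy()

    indeg = np.zeros((nrows, ncols), dtype=np.int32)
    for k, (dr, dc) in enumerate(OFFSETS):
        src = out_w[k] > 0
        if dr >= 0:
            rs, rd = slice(0, nrows - dr), slice(dr, nrows)
        else:
            rs, rd = slice(-dr, nrows), slice(0, nrows + dr)
        if dc >= 0:
            cs_, cd = slice(0, ncols - dc), slice(dc, ncols)
        else:
            cs_, cd = slice(-dc, ncols), slice(0, ncols + dc)
        contrib = np.zeros((nrows, ncols), dtype=np.int32)
        contrib[rd, cd] = src[rs, cs_]
        indeg += contrib

    queue: deque[tuple[int, int]] = deque(
        (int(r), int(c)) for r, c in np.argwhere(valid & (indeg == 0))
    )
    processed = 0
    n_valid = int(valid.sum())
    while queue:
        r, c = queue.popleft()
        processed += 1
        for k, (dr, dc) in enumerate(OFFSETS):
            w = out_w[k, r, c]
            if w <= 0:
                continue
            nr, nc = r + dr, c + dc
            if not (0 <= nr < nrows and 0 <= nc < ncols) or not valid[nr, nc]:
                continue
            acc[nr, nc] += acc[r, c] * w
            indeg[nr, nc] -= 1
            if indeg[nr, nc] == 0:
                queue.append((nr, nc))
    if processed != n_valid:
        raise FlowError("cycle detected in flow directions (internal invariant breach)")
    return AccumGrid(values=acc, mode=mode)


def upstream_cells(fd: FlowDirGrid, seed: tuple[int, int]) -> set[tuple[int, int]]:
    """D8 reverse-reachability set of ``seed`` (the exact catchment), seed
    included."""
    r0, c0 = seed
    nrows, ncols = fd.shape
    if not (0 <= r0 < nrows and 0 <= c0 < ncols) or not fd.valid[r0, c0]:
        raise FlowError(f"upstream_cells: seed {seed} is off-grid or nodata")
    out: set[tuple[int, int]] = {(r0, c0)}
    stack = [(r0, c0)]
    while stack:
        r, c = stack.pop()
        for k, (dr, dc) in enumerate(OFFSETS):
            # neighbor in direction k drains to (r, c) iff its d8 points back
            nr, nc = r + dr, c + dc
            if not (0 <= nr < nrows and 0 <= nc < ncols):
                continue
            back = fd.d8[nr, nc]
            if back < 0:
                continue
            br, bc = OFFSETS[back]
            if nr + br == r and nc + bc == c and (nr, nc) not in out:
                out.add((nr, nc))
                stack.append((nr, nc))
    return out


def d8_outlets(fd: FlowDirGrid) -> list[tuple[int, int]]:
    """Cells with no D8 target (basin outlets)."""
    return [tuple(rc) for rc in np.argwhere(fd.valid & (fd.d8 == -1))]
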