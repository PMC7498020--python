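"""Georeferenced raster grids, raster I/O, stream burning and depression filling.

Conventions (fixed throughout the package):

* row 0 is the northernmost row; cell centers sit at
  ``(origin_x + (col + 0.5) * cell_size, origin_y - (row + 0.5) * cell_size)``
  where ``(origin_x, origin_y)`` is the outer (north-west) corner of cell
  ``(0, 0)``.
* cells are square; rasters with differing x/y resolution are rejected.
* nodata cells are held as NaN in :attr:`RasterGrid.values`; the ``nodata``
  attribute only records the sentinel used on disk.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely


class GridError(ValueError):
    """Raised for malformed rasters or grid-incompatible inputs."""


@dataclass
class RasterGrid:
    """A single-band, north-up, square-cell georeferenced raster."""

    values: np.ndarray
    cell_size: float
    origin_x: float
    origin_y: float
    crs_tag: str = ""
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GridError("raster values must be a 2-D matrix")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise GridError("raster must have at least one cell")
        if not (np.isfinite(self.cell_size) and self.cell_size > 0):
            raise GridError("cell_size must be a positive finite number")

    # -- basic geometry ----------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return ~np.isnan(self.values)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size * self.cell_size / 1e6

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Grid cell containing map point (x, y). May fall outside the grid."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        return row, col

    def contains_cell(self, row: int, col: int) -> bool:
        return 0 <= row < self.nrows and 0 <= col < self.ncols

    def like(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this grid's georeferencing."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise GridError("shape mismatch in RasterGrid.like")
        return replace(self, values=values)

    def copy(self) -> "RasterGrid":
        return replace(self, values=self.values.copy())

    def assert_compatible(self, other: "RasterGrid") -> None:
        """All grids in one run must share shape, resolution, origin and CRS."""
        if self.shape != other.shape:
            raise GridError(f"grid shape mismatch: {self.shape} vs {other.shape}")
        if abs(self.cell_size - other.cell_size) > 1e-9 * self.cell_size:
            raise GridError("grid cell_size mismatch")
        tol = 1e-6 * self.cell_size
        if abs(self.origin_x - other.origin_x) > tol or abs(self.origin_y - other.origin_y) > tol:
            raise GridError("grid origin mismatch")
        if self.crs_tag and other.crs_tag and self.crs_tag != other.crs_tag:
            raise GridError("grid CRS mismatch")


@dataclass
class BurnSpec:
    """Stream polylines to carve into a DEM by ``burn_depth`` meters."""

    streams: list = field(default_factory=list)
    burn_depth: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.burn_depth) or self.burn_depth < 0:
            raise GridError("burn_depth must be finite and >= 0")


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def _read_prj_sidecar(path: Path) -> str:
    prj = path.with_suffix(".prj")
    if prj.exists():
        return prj.read_text().strip()
    return ""


def _read_ascii_grid(path: Path, crs_tag: str | None) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise GridError(f"{path}: truncated ASCII grid")
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh, dtype=float, ndmin=2)

    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridError(f"{path}: ASCII grid header missing '{key}'")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (nrows, ncols):
        raise GridError(f"{path}: body shape {body.shape} != header ({nrows}, {ncols})")
    cell = float(header["cellsize"])
    if "xllcorner" in header:
        ox = header["xllcorner"]
    elif "xllcenter" in header:
        ox = header["xllcenter"] - cell / 2.0
    else:
        raise GridError(f"{path}: ASCII grid header missing xllcorner/xllcenter")
    if "yllcorner" in header:
        oy = header["yllcorner"] + nrows * cell
    elif "yllcenter" in header:
        oy = header["yllcenter"] - cell / 2.0 + nrows * cell
    else:
        raise GridError(f"{path}: ASCII grid header missing yllcorner/yllcenter")
    nodata = float(header.get("nodata_value", -9999.0))
    values = body.copy()
    values[values == nodata] = np.nan
    if crs_tag is None:
        crs_tag = _read_prj_sidecar(path)
    if not crs_tag:
        raise GridError(f"{path}: missing CRS (provide a .prj sidecar or crs_tag=)")
    return RasterGrid(values, cell, ox, oy, crs_tag=crs_tag, nodata=nodata)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_geotiff(path: Path, crs_tag: str | None) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        arr = np.asarray(page.asarray(), dtype=float)
        if arr.ndim != 2:
            raise GridError(f"{path}: expected a single-band raster, got shape {arr.shape}")
        tags = {tag.name: tag.value for tag in page.tags.values()}
    scale = tags.get("ModelPixelScaleTag")
    tie = tags.get("ModelTiepointTag")
    if scale is None or tie is None:
        raise GridError(f"{path}: GeoTIFF lacks geo-referencing tags")
    sx, sy = float(scale[0]), float(scale[1])
    if abs(sx - sy) > 1e-9 * max(sx, sy):
        raise GridError(f"{path}: non-square cells ({sx} x {sy})")
    i, j = float(tie[0]), float(tie[1])
    ox = float(tie[3]) - i * sx
    oy = float(tie[4]) + j * sy
    nodata = -9999.0
    if "GDAL_NODATA" in tags:
        nodata = float(str(tags["GDAL_NODATA"]).strip("\x00 "))
        arr[arr == nodata] = np.nan
    if crs_tag is None:
        crs_tag = str(tags.get("GeoAsciiParamsTag", "")).strip("\x00|").strip()
        if not crs_tag:
            crs_tag = _read_prj_sidecar(path)
    if not crs_tag:
        raise GridError(f"{path}: missing CRS (no GeoAsciiParams tag or .prj sidecar)")
    return RasterGrid(arr, sx, ox, oy, crs_tag=crs_tag, nodata=nodata)


def read_raster(path: str | Path, crs_tag: str | None = None) -> RasterGrid:
    """Read a GeoTIFF or ESRI ASCII grid into a :class:`RasterGrid`.

    ``crs_tag`` overrides the CRS found on disk; a raster without any CRS
    information is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise GridError(f"raster file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt", ".agr"):
        return _read_ascii_grid(path, crs_tag)
    if suffix in (".tif", ".tiff"):
        return _read_geotiff(path, crs_tag)
    raise GridError(f"{path}: unsupported raster format '{suffix}' (use .asc or .tif)")


def write_raster(grid: RasterGrid, path: str | Path) -> Path:
    """Write a grid as ESRI ASCII (.asc, with .prj sidecar) or GeoTIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt"):
        vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
        with open(path, "w") as fh:
            fh.write(f"ncols {grid.ncols}\n")
            fh.write(f"nrows {grid.nrows}\n")
            fh.write(f"xllcorner {grid.origin_x!r}\n")
            fh.write(f"yllcorner {grid.origin_y - grid.nrows * grid.cell_size!r}\n")
            fh.write(f"cellsize {grid.cell_size!r}\n")
            fh.write(f"NODATA_value {grid.nodata!r}\n")
            np.savetxt(fh, vals, fmt="%.8g")
        if grid.crs_tag:
            path.with_suffix(".prj").write_text(grid.crs_tag + "\n")
        return path
    if suffix in (".tif", ".tiff"):
        import tifffile

        vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
        extratags = [
            (33550, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
            (33922, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
            (42113, "s", 0, str(grid.nodata)),
        ]
        if grid.crs_tag:
            extratags.append((34737, "s", 0, grid.crs_tag + "|"))
        tifffile.imwrite(str(path), vals, extratags=extratags)
        return path
    raise GridError(f"unsupported raster output format '{suffix}'")


# ---------------------------------------------------------------------------
# stream burning
# ---------------------------------------------------------------------------

def burn_streams(dem: RasterGrid, spec: BurnSpec) -> RasterGrid:
    """Lower DEM cells traversed by the burn polylines by ``burn_depth`` m.

    A cell is burned when its square intersects any polyline (all-touched
    rasterization, which keeps the carved channel D8-connected). Each burned
    cell is lowered exactly once regardless of how many lines cross it.
    """
    lines = [shapely.geometry.shape(g) if isinstance(g, dict) else g for g in spec.streams]
    lines = [g for g in lines if g is not None and not g.is_empty]
    if not lines:
        warnings.warn("burn_streams: empty stream set, DEM returned unchanged")
        return dem.copy()
    mask = np.zeros(dem.shape, dtype=bool)
    cs = dem.cell_size
    for line in lines:
        minx, miny, maxx, maxy = line.bounds
        c0 = max(0, int(np.floor((minx - dem.origin_x) / cs)))
        c1 = min(dem.ncols - 1, int(np.floor((maxx - dem.origin_x) / cs)))
        r0 = max(0, int(np.floor((dem.origin_y - maxy) / cs)))
        r1 = min(dem.nrows - 1, int(np.floor((dem.origin_y - miny) / cs)))
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                if mask[r, c]:
                    continue
                x0 = dem.origin_x + c * cs
                y1 = dem.origin_y - r * cs
                cell_box = shapely.box(x0, y1 - cs, x0 + cs, y1)
                if line.intersects(cell_box):
                    mask[r, c] = True
    mask &= dem.valid
    out = dem.values.copy()
    out[mask] -= spec.burn_depth
    return dem.like(out)


# ---------------------------------------------------------------------------
# depression filling
# ---------------------------------------------------------------------------

#: minimal elevation increment used to impose drainage across filled areas
FILL_EPSILON = 1e-5

_NEIGH8 = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


def fill_depressions(dem: RasterGrid, epsilon: float = FILL_EPSILON) -> RasterGrid:
    """Priority-flood depression filling with an epsilon gradient.

    After filling, every non-nodata cell has a strictly descending D8 path to
    a grid-boundary (or nodata-adjacent) cell. No cell is ever lowered.
    nodata cells act as off-grid: flow may exit into them.
    """
    z = dem.values
    nrows, ncols = z.shape
    valid = dem.valid
    if not valid.any():
        raise GridError("fill_depressions: all-nodata grid")

    filled = np.full_like(z, np.nan)
    closed = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0

    isnan = ~valid
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            boundary = r == 0 or c == 0 or r == nrows - 1 or c == ncols - 1
            if not boundary:
                for dr, dc in _NEIGH8:
                    if isnan[r + dr, c + dc]:
                        boundary = True
                        break
            if boundary:
                filled[r, c] = z[r, c]
                closed[r, c] = True
                heapq.heappush(heap, (z[r, c], counter, r, c))
                counter += 1

    if not heap:
        raise GridError("fill_depressions: no drainable boundary cell on the grid")

    while heap:
        elev, _, r, c = heapq.heappop(heap)
        for dr, dc in _NEIGH8:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < nrows and 0 <= nc < ncols):
                continue
            if closed[nr, nc] or not valid[nr, nc]:
                continue
            filled[nr, nc] = max(z[nr, nc], elev + epsilon)
            closed[nr, nc] = True
            heapq.heappush(heap, (filled[nr, nc], counter, nr, nc))
            counter += 1

    return dem.like(filled)
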