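"""Deterministic synthetic inputs: DEMs, sites, land use, measurements.

Every generator takes an explicit seed through :class:`FixtureSpec`; the
same spec always produces bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from . import vecio
from .flow import accumulate, d8_directions, mfd_directions
from .grid import RasterGrid, fill_depressions, write_raster
from .network import StreamNetwork, extract_streams, vectorize

#: placeholder projected CRS tag used by all fixtures (meters, local origin)
LOCAL_CRS = 'LOCAL_CS["synthetic cartesian meters",UNIT["metre",1.0]]'

RELIEFS = ("tilted_plane", "twin_valley", "random_smooth", "triple_junction")


@dataclass
class FixtureSpec:
    nrows: int = 60
    ncols: int = 60
    cell_size: float = 10.0
    relief: str = "twin_valley"
    noise_sd: float = 0.0
    n_sites: int = 20
    site_jitter_m: float = 5.0
    n_classes: int = 3
    seed: int = 42
    accum_threshold: int = 20
    min_stream_length: int = 16
    routing: str = "mfd"  # accumulation mode for stream extraction

    def __post_init__(self) -> None:
        if self.nrows < 5 or self.ncols < 5:
            raise ValueError("fixture DEM must be at least 5x5")
        if self.relief not in RELIEFS:
            raise ValueError(f"unknown relief {self.relief!r}; choose from {RELIEFS}")


# ---------------------------------------------------------------------------
# DEM synthesis
# ---------------------------------------------------------------------------

def _tilted_plane(n: int, m: int) -> np.ndarray:
    r, c = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    # strictly monotone toward the SE corner; every row drains E along the
    # row, the east column collects and drains S -> a single outlet
    return 200.0 - 1.0 * c - 0.2 * r


def _twin_valley(n: int, m: int) -> np.ndarray:
    # two V-shaped valleys converging to a single southward channel; with
    # the default thresholds (accum_threshold=20, min_stream_length=16 on
    # 60x60) this yields a single network of 3-9 edges including complex
    # confluences under MFD accumulation
    r = np.arange(n)[:, None].astype(float)
    c = np.arange(m)[None, :].astype(float)
    merge = int(0.55 * n)
    cm = m // 2
    c1, c2 = m // 4, (3 * m) // 4
    t = np.clip(r / merge, 0.0, 1.0)
    v1 = c1 + (cm - c1) * t
    v2 = c2 + (cm - c2) * t
    d = np.minimum(np.abs(c - v1), np.abs(c - v2))
    d = np.where(r >= merge, np.abs(c - cm), d)
    return 2.0 * d + 0.6 * (n - 1 - r)


def _random_smooth(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    rough = rng.standard_normal((n, m))
    smooth = gaussian_filter(rough, sigma=max(2.0, min(n, m) / 10.0))
    r = np.arange(n)[:, None].astype(float)
    c = np.arange(m)[None, :].astype(float)
    return smooth * 15.0 + 0.6 * (n - 1 - r) + 0.1 * c


def _triple_junction(n: int, m: int) -> np.ndarray:
    """Three channels (from N, W and NW) meeting in one cell: a guaranteed
    3-inflow confluence with a single outflow channel to the south edge."""
    r0, c0 = n // 2, m // 2
    z = np.full((n, m), 0.0)
    chan = np.zeros((n, m), dtype=bool)
    for r in range(2, r0):  # channel A, from the north
        z[r, c0] = 50.0 + 0.5 * (r0 - r)
        chan[r, c0] = True
    for c in range(2, c0):  # channel B, from the west
        z[r0, c] = 50.0 + 0.5 * (c0 - c)
        chan[r0, c] = True
    for k in range(1, min(r0, c0) - 2):  # channel C, diagonal from the NW
        z[r0 - k, c0 - k] = 50.0 + 0.5 * k
        chan[r0 - k, c0 - k] = True
    z[r0, c0] = 50.0
    chan[r0, c0] = True
    for r in range(r0 + 1, n):  # outflow channel D, to the south edge
        z[r, c0] = 50.0 - 0.2 * (r - r0)
        chan[r, c0] = True
    # hillslopes: high ground sloping gently toward the nearest channel cell
    cr, cc = np.nonzero(chan)
    tree = cKDTree(np.column_stack([cr, cc]))
    rr, cc2 = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    dist, _ = tree.query(np.column_stack([rr.ravel(), cc2.ravel()]))
    hills = 80.0 + 0.8 * dist.reshape(n, m) + 0.01 * rr
    return np.where(chan, z, hills)


def make_dem(spec: FixtureSpec) -> RasterGrid:
    rng = np.random.default_rng(spec.seed)
    n, m = spec.nrows, spec.ncols
    if spec.relief == "tilted_plane":
        z = _tilted_plane(n, m)
    elif spec.relief == "twin_valley":
        z = _twin_valley(n, m)
    elif spec.relief == "random_smooth":
        z = _random_smooth(n, m, rng)
    else:
        z = _triple_junction(n, m)
    if spec.noise_sd > 0:
        z = z + rng.normal(0.0, spec.noise_sd, size=z.shape)
    return RasterGrid(
        z, cell_size=spec.cell_size, origin_x=0.0,
        origin_y=n * spec.cell_size, crs_tag=LOCAL_CRS,
    )


def derive_network(spec: FixtureSpec, dem: RasterGrid | None = None):
    """Run the standard pipeline (fill -> directions -> accumulation ->
    extraction -> vectorize) on a fixture DEM. Returns (net, fd, filled)."""
    if dem is None:
        dem = make_dem(spec)
    filled = fill_depressions(dem)
    if spec.routing == "mfd":
        fd = mfd_directions(filled)
    else:
        fd = d8_directions(filled)
    acc = accumulate(fd, mode=spec.routing)
    labels = extract_streams(acc, fd, spec.accum_threshold, spec.min_stream_length)
    net = vectorize(labels, fd, filled)
    return net, fd, filled


# ---------------------------------------------------------------------------
# sites and land use
# ---------------------------------------------------------------------------

def make_sites(spec: FixtureSpec, net: StreamNetwork) -> list[dict]:
    """Points jittered off the stream lines with known true (rid, ratio).

    Sampling is uniform along the total (non-artificial) network length;
    per-coordinate jitter is N(0, site_jitter_m^2).
    """
    rng = np.random.default_rng(spec.seed + 1)
    edges = [e for e in net.edges.values() if not e.artificial and e.length_m > 0]
    if not edges:
        raise ValueError("make_sites: network has no usable edges")
    lengths = np.array([e.length_m for e in edges])
    cum = np.cumsum(lengths)
    total = cum[-1]
    out = []
    for i in range(spec.n_sites):
        u = rng.uniform(0, total)
        idx = int(np.searchsorted(cum, u))
        idx = min(idx, len(edges) - 1)
        e = edges[idx]
        along = u - (cum[idx] - lengths[idx])  # distance from upstream end
        pt = e.line().interpolate(along)
        ratio = 1.0 - along / e.length_m
        jx, jy = rng.normal(0.0, spec.site_jitter_m, size=2) if spec.site_jitter_m > 0 else (0.0, 0.0)
        out.append(
            {
                "x": pt.x + jx,
                "y": pt.y + jy,
                "site_id": i + 1,
                "true_rid": e.rid,
                "true_ratio": float(ratio),
            }
        )
    return out


def make_landuse(spec: FixtureSpec, dem: RasterGrid):
    """Seeded Voronoi land-use patches.

    Returns ``(grid, features)`` where the categorical raster (class codes
    1..n_classes) and the polygon layer (per-class union of cell squares)
    are cell-for-cell consistent, so raster and vector predictor paths can
    be cross-checked.
    """
    if spec.n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    rng = np.random.default_rng(spec.seed + 2)
    n_seeds = max(spec.n_classes * 4, 8)
    pts = rng.uniform(0, 1, size=(n_seeds, 2)) * [spec.ncols, spec.nrows]
    classes = np.concatenate(
        [np.arange(1, spec.n_classes + 1), rng.integers(1, spec.n_classes + 1, n_seeds - spec.n_classes)]
    )
    tree = cKDTree(pts)
    rr, cc = np.meshgrid(np.arange(spec.nrows), np.arange(spec.ncols), indexing="ij")
    cells = np.column_stack([cc.ravel() + 0.5, rr.ravel() + 0.5])
    _, nearest = tree.query(cells)
    codes = classes[nearest].reshape(spec.nrows, spec.ncols).astype(float)
    grid = dem.like(codes)

    cs = dem.cell_size
    features = []
    for cls in range(1, spec.n_classes + 1):
        boxes = [
            shapely.box(
                dem.origin_x + c * cs,
                dem.origin_y - (r + 1) * cs,
                dem.origin_x + (c + 1) * cs,
                dem.origin_y - r * cs,
            )
            for r, c in np.argwhere(codes == cls)
        ]
        if boxes:
            features.append((shapely.union_all(boxes), {"class": int(cls)}))
    return grid, features


def make_measurements(spec: FixtureSpec, site_ids: list[int]) -> pd.DataFrame:
    """Repeated-measurements table keyed by site_id (1-3 rows per site)."""
    rng = np.random.default_rng(spec.seed + 3)
    rows = []
    for sid in site_ids:
        for rep in range(int(rng.integers(1, 4))):
            rows.append(
                {"site_id": sid, "sample": rep + 1, "value": float(np.round(rng.normal(10, 2), 4))}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk fixture bundles
# ---------------------------------------------------------------------------

def write_fixture_dir(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a complete input bundle in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dem = make_dem(spec)
    paths = {"dem": write_raster(dem, outdir / "dem.asc")}

    net, _, _ = derive_network(spec, dem)
    pts = make_sites(spec, net)
    feats = [
        (shapely.Point(p["x"], p["y"]),
         {k: v for k, v in p.items() if k not in ("x", "y")})
        for p in pts
    ]
    paths["sites"] = vecio.write_features(outdir / "sites.geojson", feats)

    lu_grid, lu_feats = make_landuse(spec, dem)
    paths["landuse_raster"] = write_raster(lu_grid, outdir / "landuse.asc")
    paths["landuse_polygons"] = vecio.write_features(
        outdir / "landuse.geojson",
        [(g, props) for g, props in lu_feats],
    )

    meas = make_measurements(spec, [p["site_id"] for p in pts])
    paths["measurements"] = outdir / "measurements.csv"
    meas.to_csv(paths["measurements"], index=False)

    paths["spec"] = outdir / "fixture.json"
    paths["spec"].write_text(json.dumps(asdict(spec), indent=1))
    return paths
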