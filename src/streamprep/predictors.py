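"""Predictor summarization over RCAs, catchments and sites.

Edge attribution follows the additive scheme: a per-edge summary over its
own RCA cells, and a cumulative summary over the catchment draining through
the edge's downstream node, obtained by aggregating RCA sums upstream-down.
Approximate site attribution interpolates the edge's RCA linearly in the
site's ``ratio``; exact attribution traces the per-site D8 catchment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .flow import FlowDirGrid, upstream_cells
from .grid import RasterGrid
from .network import StreamNetwork
from .sites import Site

_STATS = ("mean", "sum", "percent", "area_km2")
_PRED_KEY = "_pred"  # internal per-edge store of raw sums/counts


class PredictorError(ValueError):
    pass


@dataclass
class PredictorLayer:
    """A continuous or categorical predictor, raster- or polygon-backed.

    Polygon sources are rasterized (cell-center-in-polygon) to the DEM grid
    before any summarization so raster and vector inputs follow one code
    path.
    """

    name: str
    kind: str  # 'continuous' | 'categorical'
    stats: list[str]
    grid: RasterGrid | None = None
    polygons: list[tuple] | None = None  # (shapely geometry, numeric value)
    _rasterized: RasterGrid | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise PredictorError(f"unknown layer kind {self.kind!r}")
        bad = [s for s in self.stats if s not in _STATS]
        if bad:
            raise PredictorError(f"unsupported stats {bad}; choose from {_STATS}")
        if (self.grid is None) == (self.polygons is None):
            raise PredictorError("give exactly one of grid / polygons")
        if self.kind == "continuous" and "percent" in self.stats:
            raise PredictorError("'percent' is only defined for categorical layers")

    def rasterized(self, template: RasterGrid) -> RasterGrid:
        if self.grid is not None:
            template.assert_compatible(self.grid)
            return self.grid
        if self._rasterized is None:
            self._rasterized = rasterize_polygons(self.polygons, template)
        return self._rasterized

    def classes(self, template: RasterGrid) -> list[int]:
        vals = self.rasterized(template).values
        return sorted(int(v) for v in np.unique(vals[~np.isnan(vals)]))


def rasterize_polygons(features, template: RasterGrid) -> RasterGrid:
    """Burn (geometry, value) features onto the template grid by
    cell-center-in-polygon; cells covered by no feature stay nodata."""
    xs = template.origin_x + (np.arange(template.ncols) + 0.5) * template.cell_size
    ys = template.origin_y - (np.arange(template.nrows) + 0.5) * template.cell_size
    xx, yy = np.meshgrid(xs, ys)
    out = np.full(template.shape, np.nan)
    for geom, value in features:
        g = shapely.geometry.shape(geom) if isinstance(geom, dict) else geom
        hit = shapely.contains_xy(g, xx.ravel(), yy.ravel()).reshape(template.shape)
        out[hit] = float(value)
    return template.like(out)


# ---------------------------------------------------------------------------
# raw aggregation helpers
# ---------------------------------------------------------------------------

def _cell_values(grid: RasterGrid, cells: np.ndarray) -> np.ndarray:
    if len(cells) == 0:
        return np.empty(0)
    return grid.values[cells[:, 0], cells[:, 1]]


def _raw_over_cells(layer: PredictorLayer, grid: RasterGrid, cells: np.ndarray) -> dict:
    vals = _cell_values(grid, cells)
    vals = vals[~np.isnan(vals)]
    if layer.kind == "continuous":
        return {"sum": float(vals.sum()), "cnt": int(vals.size)}
    codes, counts = np.unique(vals.astype(int), return_counts=True)
    return {"cls": dict(zip(codes.tolist(), counts.tolist())), "cnt": int(vals.size)}


def _add_raw(a: dict, b: dict, kind: str) -> dict:
    if kind == "continuous":
        return {"sum": a["sum"] + b["sum"], "cnt": a["cnt"] + b["cnt"]}
    cls = dict(a["cls"])
    for k, v in b["cls"].items():
        cls[k] = cls.get(k, 0) + v
    return {"cls": cls, "cnt": a["cnt"] + b["cnt"]}


def _public_columns(layer: PredictorLayer, raw: dict, scope: str, cell_km2: float,
                    classes: list[int]) -> dict:
    cols: dict[str, float] = {}
    suffix = f"_{scope}"
    if layer.kind == "continuous":
        if "mean" in layer.stats:
            cols[f"{layer.name}_mean{suffix}"] = (
                raw["sum"] / raw["cnt"] if raw["cnt"] else np.nan
            )
        if "sum" in layer.stats:
            cols[f"{layer.name}_sum{suffix}"] = raw["sum"]
        if "area_km2" in layer.stats:
            cols[f"{layer.name}_akm2{suffix}"] = raw["cnt"] * cell_km2
    else:
        total = raw["cnt"]
        for c in classes:
            n = raw["cls"].get(c, 0)
            if "percent" in layer.stats:
                cols[f"{layer.name}_p{c}{suffix}"] = 100.0 * n / total if total else np.nan
            if "area_km2" in layer.stats:
                cols[f"{layer.name}_a{c}{suffix}"] = n * cell_km2
    return cols


# ---------------------------------------------------------------------------
# edge attribution
# ---------------------------------------------------------------------------

def attach_edge_attributes(
    net: StreamNetwork, layers: list[PredictorLayer], dem: RasterGrid
) -> StreamNetwork:
    """Summarize each layer over every edge's RCA and downstream-node
    catchment; results land in ``edge.attributes``.

    Cumulative sums are aggregated upstream-down over the edge tree:
    ``cum(e) = rca(e) + sum(cum over upstream edges)``, which matches a
    direct summation over the catchment cells because RCA cell sets are
    disjoint.
    """
    for layer in layers:
        grid = layer.rasterized(dem)
        dem.assert_compatible(grid)
        classes = layer.classes(dem) if layer.kind == "categorical" else []
        raws: dict[int, dict] = {}
        for rid in net.postorder():  # upstream edges first
            e = net.edges[rid]
            rca_raw = _raw_over_cells(layer, grid, e.rca_cells)
            cum_raw = rca_raw
            for u in net.upstream_rids(rid):
                cum_raw = _add_raw(cum_raw, raws[u], layer.kind)
            raws[rid] = cum_raw
            store = e.attributes.setdefault(_PRED_KEY, {})
            store[layer.name] = {"rca": rca_raw, "cum": cum_raw, "classes": classes}
            e.attributes.update(
                _public_columns(layer, rca_raw, "rca", dem.cell_area_km2, classes)
            )
            e.attributes.update(
                _public_columns(layer, cum_raw, "cum", dem.cell_area_km2, classes)
            )
    return net


# ---------------------------------------------------------------------------
# site attribution
# ---------------------------------------------------------------------------

def _interp_raw(rca: dict, cum: dict, ratio: float, kind: str) -> dict:
    """Linear-in-ratio removal of the edge's own RCA share from the
    cumulative raw sums: value = cum - ratio * rca."""
    if kind == "continuous":
        return {
            "sum": cum["sum"] - ratio * rca["sum"],
            "cnt": cum["cnt"] - ratio * rca["cnt"],
        }
    cls = {c: cum["cls"].get(c, 0) - ratio * rca["cls"].get(c, 0) for c in cum["cls"]}
    return {"cls": cls, "cnt": cum["cnt"] - ratio * rca["cnt"]}


def sites_attributes_approx(
    sites: list[Site], net: StreamNetwork, layers: list[PredictorLayer],
    dem: RasterGrid,
) -> list[Site]:
    """Approximate (edge-interpolated) site attribution.

    Requires :func:`attach_edge_attributes` to have run. Every site also
    receives ``areaKm2``, the interpolated catchment area
    ``h2o(edge) - ratio * rca(edge)``.
    """
    out = []
    for s in sites:
        e = net.edges[s.rid]
        rec = s.copy()
        rec.attributes["areaKm2"] = e.h2o_km2 - s.ratio * e.rca_km2
        if layers and _PRED_KEY not in e.attributes:
            raise PredictorError(
                "edge attributes missing; run attach_edge_attributes first"
            )
        for layer in layers:
            stored = e.attributes[_PRED_KEY].get(layer.name)
            if stored is None:
                raise PredictorError(
                    f"edge {e.rid} lacks attributes for layer {layer.name!r}"
                )
            raw = _interp_raw(stored["rca"], stored["cum"], s.ratio, layer.kind)
            cols = _public_columns(layer, raw, "app", dem.cell_area_km2, stored["classes"])
            rec.attributes.update({k.removesuffix("_app"): v for k, v in cols.items()})
        out.append(rec)
    return out


def sites_attributes_exact(
    sites: list[Site],
    fd: FlowDirGrid,
    layers: list[PredictorLayer],
    dem: RasterGrid,
    net: StreamNetwork | None = None,
) -> list[Site]:
    """Exact site attribution over per-site D8 catchments.

    The catchment seed is the stream cell of the site's edge nearest to the
    snapped point when ``net`` is given (keeping the seed on the reach the
    site references); otherwise the raster cell containing the point is
    used, with a warning if it does not belong to the referenced edge.
    Attribute names carry an ``_ex`` suffix, plus ``areaKm2_ex``.
    """
    out = []
    for s in sites:
        seed = None
        if net is not None:
            e = net.edges[s.rid]
            if len(e.cells) > 0:
                centers = np.array([dem.cell_center(r, c) for r, c in e.cells])
                d2 = ((centers - [s.x, s.y]) ** 2).sum(axis=1)
                seed = tuple(int(v) for v in e.cells[int(np.argmin(d2))])
        if seed is None:
            seed = dem.cell_of(s.x, s.y)
            warnings.warn(
                f"site pid={s.pid}: catchment seeded at the raw containing cell "
                f"{seed}, which may sit off the stream path"
            )
        catch = upstream_cells(fd, seed)
        cells = np.array(sorted(catch), dtype=np.int32)
        rec = s.copy()
        rec.attributes["areaKm2_ex"] = len(cells) * dem.cell_area_km2
        for layer in layers:
            grid = layer.rasterized(dem)
            classes = layer.classes(dem) if layer.kind == "categorical" else []
            raw = _raw_over_cells(layer, grid, cells)
            rec.attributes.update(
                _public_columns(layer, raw, "ex", dem.cell_area_km2, classes)
            )
        out.append(rec)
    return out
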