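"""GeoJSON feature I/O (points, lines, polygons) on top of shapely."""

from __future__ import annotations

import json
from pathlib import Path

import shapely
import shapely.geometry


class VectorError(ValueError):
    pass


def read_features(path: str | Path) -> list[tuple[shapely.Geometry, dict]]:
    """Read a GeoJSON (.geojson/.json) or shapefile (.shp) into a list of
    (shapely geometry, properties) pairs."""
    path = Path(path)
    if not path.exists():
        raise VectorError(f"vector file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".geojson", ".json"):
        doc = json.loads(path.read_text())
        if doc.get("type") == "FeatureCollection":
            feats = doc.get("features", [])
        elif doc.get("type") == "Feature":
            feats = [doc]
        else:  # bare geometry
            feats = [{"geometry": doc, "properties": {}}]
        return [
            (shapely.geometry.shape(f["geometry"]), dict(f.get("properties") or {}))
            for f in feats
        ]
    if suffix == ".shp":
        from . import shp as shpio

        shape_type, geoms, records, _ = shpio.read_shapefile(path)
        out = []
        for g, rec in zip(geoms, records):
            if g is None:
                continue
            if shape_type == shpio.SHP_POINT:
                out.append((shapely.Point(g), rec))
            else:
                out.append((shapely.LineString(g), rec))
        return out
    if suffix == ".gpkg":
        raise VectorError(
            f"{path}: GeoPackage is not supported in this build (no GDAL stack); "
            "use GeoJSON or shapefile"
        )
    raise VectorError(f"{path}: unsupported vector format '{suffix}'")


def write_features(path: str | Path, features) -> Path:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    path = Path(path)
    out = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": shapely.geometry.mapping(
                    shapely.geometry.shape(g) if isinstance(g, dict) else g
                ),
                "properties": props,
            }
            for g, props in features
        ],
    }
    path.write_text(json.dumps(out, indent=1, default=_json_default))
    return path


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
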