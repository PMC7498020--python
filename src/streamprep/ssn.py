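"""Write and re-read `.ssn` directories.

Layout: ``<root>.ssn/`` holding ``edges.shp``, ``sites.shp``, optional
``preds.shp`` (with .shx/.dbf/.prj sidecars; GeoJSON available as an
alternate dialect), one comma-separated topology table per network
(``netID<k>.dat`` by default, ``net<k>.dat`` as a dialect), and an
``ssn_fields.json`` sidecar recording the shapefile field-name abbreviation
map and run metadata.
"""

from __future__ import annotations

import json
import shutil
from pathlib import Path

import numpy as np

from . import shp as shpio
from . import vecio
from .network import Edge, NetworkError, StreamNetwork
from .sites import Site


class SSNExportError(ValueError):
    pass


class SSNValidationError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("SSN validation failed:\n  " + "\n  ".join(errors))


_EDGE_BASE_FIELDS = [
    "rid", "netID", "binaryID", "Length", "upDist", "rcaAreaKm2",
    "H2OAreaKm2", "shreve", "prev_str01", "prev_str02", "artif",
]
_SITE_BASE_FIELDS = [
    "pid", "locID", "rid", "netID", "ratio", "upDist", "dist", "X", "Y",
]


def shorten_field_names(names: list[str]) -> dict[str, str]:
    """Deterministic 10-character abbreviation map (shapefile DBF limit)."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        cand = name if len(name) <= 10 else name[:10]
        if cand in used:
            i = 1
            while f"{name[:8]}{i:02d}" in used:
                i += 1
            cand = f"{name[:8]}{i:02d}"
        mapping[name] = cand
        used.add(cand)
    return mapping


def _field_spec(name: str, values: list) -> tuple[str, str, int, int]:
    """Pick a DBF field definition from the column's values."""
    ints = all(
        v is None or (isinstance(v, (int, np.integer)) and not isinstance(v, bool))
        for v in values
    )
    numeric = all(
        v is None
        or isinstance(v, (int, float, np.integer, np.floating))
        and not isinstance(v, bool)
        for v in values
    )
    if ints:
        return (name, "N", 10, 0)
    if numeric:
        return (name, "N", 19, 8)
    width = max([len(str(v)) for v in values if v is not None] + [1])
    return (name, "C", min(max(width, 1), 254), 0)


def _edge_records(net: StreamNetwork):
    geoms, recs = [], []
    extra_cols: list[str] = []
    for e in net.edges.values():
        for k in e.attributes:
            if not k.startswith("_") and k not in extra_cols:
                extra_cols.append(k)
    for rid in sorted(net.edges):
        e = net.edges[rid]
        prev = sorted(e.prev_rids)
        rec = {
            "rid": e.rid,
            "netID": e.netID,
            "binaryID": e.binaryID,
            "Length": e.length_m,
            "upDist": e.upDist_m,
            "rcaAreaKm2": e.rca_km2,
            "H2OAreaKm2": e.h2o_km2,
            "shreve": e.shreve,
            "prev_str01": prev[0] if len(prev) > 0 else -1,
            "prev_str02": prev[1] if len(prev) > 1 else -1,
            "artif": int(e.artificial),
        }
        for col in extra_cols:
            v = e.attributes.get(col)
            rec[col] = None if v is None or (isinstance(v, float) and np.isnan(v)) else v
        recs.append(rec)
        geoms.append(e.geometry)
    return geoms, recs, extra_cols


def _site_records(sites: list[Site]):
    geoms, recs = [], []
    extra_cols: list[str] = []
    for s in sites:
        for k in s.attributes:
            if not k.startswith("_") and k not in extra_cols:
                extra_cols.append(k)
    for s in sites:
        rec = {
            "pid": s.pid,
            "locID": s.locID,
            "rid": s.rid,
            "netID": s.netID,
            "ratio": s.ratio,
            "upDist": s.upDist_m,
            "dist": s.dist_moved,
            "X": s.x,
            "Y": s.y,
        }
        for col in extra_cols:
            v = s.attributes.get(col)
            rec[col] = None if isinstance(v, float) and np.isnan(v) else v
        recs.append(rec)
        geoms.append(np.array([s.x, s.y]))
    return geoms, recs, extra_cols


def _write_layer(root: Path, name: str, shape_type: int, geoms, recs, cols,
                 crs_tag: str, layer_format: str) -> dict[str, str]:
    if layer_format == "geojson":
        import shapely

        feats = []
        for g, rec in zip(geoms, recs):
            geom = shapely.Point(g) if shape_type == shpio.SHP_POINT else shapely.LineString(g)
            feats.append((geom, rec))
        vecio.write_features(root / f"{name}.geojson", feats)
        return {c: c for c in cols}
    name_map = shorten_field_names(cols)
    fields = []
    for col in cols:
        values = [rec.get(col) for rec in recs]
        short = name_map[col]
        fields.append(_field_spec(short, values))
    out_recs = [{name_map[c]: rec.get(c) for c in cols} for rec in recs]
    shpio.write_shapefile(
        root / name, shape_type, geoms, fields, out_recs, crs_tag=crs_tag
    )
    return name_map


def export_ssn(
    net: StreamNetwork,
    sites: list[Site],
    preds: list[Site] | None,
    root: str | Path,
    overwrite: bool = False,
    layer_format: str = "shp",
    net_file_style: str = "netID",
    metadata: dict | None = None,
) -> Path:
    """Write the `.ssn` directory. The network must be admissible."""
    if layer_format not in ("shp", "geojson"):
        raise SSNExportError(f"unknown layer_format {layer_format!r}")
    if net_file_style not in ("netID", "net"):
        raise SSNExportError(f"unknown net_file_style {net_file_style!r}")
    census = net.admissibility_census()
    bad = {k: v for k, v in census.items() if v}
    if bad:
        raise SSNExportError(f"network topology is inadmissible: {bad}")
    try:
        outlet = net.outlet_rids()
    except NetworkError as exc:
        raise SSNExportError(str(exc)) from exc

    root = Path(root)
    if root.suffix != ".ssn":
        raise SSNExportError(f"output directory must end in '.ssn' (got {root})")
    if root.exists() and any(root.iterdir()):
        if not overwrite:
            raise SSNExportError(f"{root} exists and is not empty (use overwrite)")
        shutil.rmtree(root)
    root.mkdir(parents=True, exist_ok=True)

    edge_cols = _EDGE_BASE_FIELDS.copy()
    geoms, recs, extra = _edge_records(net)
    edge_map = _write_layer(
        root, "edges", shpio.SHP_POLYLINE, geoms, recs, edge_cols + extra,
        net.crs_tag, layer_format,
    )
    sgeoms, srecs, sextra = _site_records(sites)
    site_map = _write_layer(
        root, "sites", shpio.SHP_POINT, sgeoms, srecs, _SITE_BASE_FIELDS + sextra,
        net.crs_tag, layer_format,
    )
    pred_map = {}
    if preds is not None:
        pgeoms, precs, pextra = _site_records(preds)
        pred_map = _write_layer(
            root, "preds", shpio.SHP_POINT, pgeoms, precs,
            _SITE_BASE_FIELDS + pextra, net.crs_tag, layer_format,
        )

    prefix = "netID" if net_file_style == "netID" else "net"
    for netID in sorted(outlet):
        rows = sorted(
            (e.rid, e.binaryID) for e in net.edges.values() if e.netID == netID
        )
        with open(root / f"{prefix}{netID}.dat", "w", newline="") as fh:
            fh.write('"rid","binaryID"\n')
            for rid, bid in rows:
                fh.write(f'{rid},"{bid}"\n')

    sidecar = {
        "layer_format": layer_format,
        "net_file_style": net_file_style,
        "crs_tag": net.crs_tag,
        "cell_size": net.cell_size,
        "field_maps": {"edges": edge_map, "sites": site_map, "preds": pred_map},
        "metadata": metadata or {},
    }
    (root / "ssn_fields.json").write_text(json.dumps(sidecar, indent=1))
    return root


# ---------------------------------------------------------------------------
# reading / validation
# ---------------------------------------------------------------------------

def _read_layer(root: Path, name: str, rename: dict[str, str]):
    """Returns (geoms, records) with original (long) field names restored."""
    shp = root / f"{name}.shp"
    gj = root / f"{name}.geojson"
    if shp.exists():
        _, geoms, recs, _ = shpio.read_shapefile(shp)
    elif gj.exists():
        feats = vecio.read_features(gj)
        geoms = [
            np.asarray(g.coords) if g.geom_type == "LineString" else np.array([g.x, g.y])
            for g, _ in feats
        ]
        recs = [props for _, props in feats]
    else:
        return None, None
    back = {short: long for long, short in rename.items()}
    recs = [{back.get(k, k): v for k, v in rec.items()} for rec in recs]
    return geoms, recs


def read_ssn(root: str | Path):
    """Re-read an exported `.ssn` directory.

    Returns ``(net, sites, preds)``; raises :class:`SSNValidationError` when
    structural invariants are violated (orphan rids, missing topology
    tables, missing outlet binaryID, duplicate binaryIDs, broken chains).
    """
    root = Path(root)
    if not root.is_dir():
        raise SSNValidationError([f"{root} is not a directory"])
    sidecar = {}
    sc = root / "ssn_fields.json"
    if sc.exists():
        sidecar = json.loads(sc.read_text())
    fmaps = sidecar.get("field_maps", {})

    geoms, recs = _read_layer(root, "edges", fmaps.get("edges", {}))
    if geoms is None:
        raise SSNValidationError(["missing edges layer (edges.shp / edges.geojson)"])

    net = StreamNetwork(
        cell_size=float(sidecar.get("cell_size", 1.0)),
        crs_tag=sidecar.get("crs_tag", ""),
    )
    errors: list[str] = []
    node_at: dict[tuple[float, float], int] = {}

    def node_for(xy) -> int:
        key = (round(float(xy[0]), 6), round(float(xy[1]), 6))
        if key not in node_at:
            node_at[key] = net.add_node(float(xy[0]), float(xy[1]), "pseudo")
        return node_at[key]

    required = {"rid", "netID", "binaryID", "Length", "upDist"}
    for geom, rec in zip(geoms, recs):
        missing = [k for k in sorted(required) if rec.get(k) is None]
        if missing:
            errors.append(f"edge record missing fields {missing}")
            continue
        prev = [p for p in (rec.get("prev_str01", -1), rec.get("prev_str02", -1))
                if p is not None and p >= 0]
        e = Edge(
            rid=int(rec["rid"]),
            netID=int(rec["netID"]),
            from_node=node_for(geom[0]),
            to_node=node_for(geom[-1]),
            geometry=np.asarray(geom, dtype=float),
            cells=np.empty((0, 2), dtype=np.int32),
            rca_cells=np.empty((0, 2), dtype=np.int32),
            length_m=float(rec["Length"]),
            upDist_m=float(rec["upDist"]),
            rca_km2=float(rec.get("rcaAreaKm2") or 0.0),
            h2o_km2=float(rec.get("H2OAreaKm2") or 0.0),
            binaryID=str(rec["binaryID"]),
            prev_rids=prev,
            shreve=int(rec.get("shreve") or 1),
            artificial=bool(rec.get("artif") or 0),
            attributes={
                k: v for k, v in rec.items()
                if k not in _EDGE_BASE_FIELDS and v is not None
            },
        )
        net.add_edge(e)

    # classify nodes now that the full edge set is known
    out, inn = net.outflow_map(), net.inflow_map()
    for nid, node in net.nodes.items():
        if not out.get(nid):
            node.kind = "outlet"
        elif len(inn.get(nid, [])) >= 2:
            node.kind = "confluence"
        elif not inn.get(nid):
            node.kind = "source"

    def read_sites(name):
        g, r = _read_layer(root, name, fmaps.get(name, {}))
        if g is None:
            return None
        result = []
        for geom, rec in zip(g, r):
            result.append(
                Site(
                    pid=int(rec["pid"]),
                    locID=int(rec["locID"]),
                    rid=int(rec["rid"]),
                    netID=int(rec["netID"]),
                    x=float(rec["X"]),
                    y=float(rec["Y"]),
                    orig_x=float(rec["X"]),
                    orig_y=float(rec["Y"]),
                    dist_moved=float(rec.get("dist") or 0.0),
                    ratio=float(rec["ratio"]),
                    upDist_m=float(rec["upDist"]),
                    attributes={
                        k: v for k, v in rec.items()
                        if k not in _SITE_BASE_FIELDS and v is not None
                    },
                )
            )
        return result

    sites = read_sites("sites")
    if sites is None:
        errors.append("missing sites layer (sites.shp / sites.geojson)")
        sites = []
    preds = read_sites("preds")

    errors.extend(_validate(net, sites, preds, root, sidecar))
    if errors:
        raise SSNValidationError(errors)
    return net, sites, preds


def _validate(net, sites, preds, root: Path, sidecar: dict) -> list[str]:
    errors: list[str] = []
    prefix = "netID" if sidecar.get("net_file_style", "netID") == "netID" else "net"
    by_net: dict[int, list[Edge]] = {}
    for e in net.edges.values():
        by_net.setdefault(e.netID, []).append(e)

    for netID, edges in sorted(by_net.items()):
        dat = root / f"{prefix}{netID}.dat"
        if not dat.exists():
            errors.append(f"missing topology table {dat.name}")
            continue
        rows = dat.read_text().strip().splitlines()
        if not rows or rows[0].replace(" ", "") != '"rid","binaryID"':
            errors.append(f"{dat.name}: malformed header")
            continue
        table: dict[int, str] = {}
        for line in rows[1:]:
            rid_s, bid_s = line.split(",", 1)
            table[int(rid_s)] = bid_s.strip().strip('"')
        rids = {e.rid for e in edges}
        for rid in sorted(set(table) - rids):
            errors.append(f"{dat.name}: orphan rid {rid} (not in edges layer)")
        for rid in sorted(rids - set(table)):
            errors.append(f"{dat.name}: edge rid {rid} missing from table")
        for rid in sorted(rids & set(table)):
            if table[rid] != net.edges[rid].binaryID:
                errors.append(f"{dat.name}: binaryID mismatch for rid {rid}")
        bids = [e.binaryID for e in edges]
        if "1" not in bids:
            errors.append(f"netID {netID}: no outlet edge (binaryID '1' missing)")
        if len(set(bids)) != len(bids):
            errors.append(f"netID {netID}: duplicate binaryIDs")
        bidset = set(bids)
        for bid in bids:
            if len(bid) > 1 and bid[:-1] not in bidset:
                errors.append(f"netID {netID}: broken binaryID chain at '{bid}'")

    for label, pts in (("sites", sites), ("preds", preds or [])):
        for s in pts:
            if s.rid not in net.edges:
                errors.append(f"{label}: pid {s.pid} references unknown rid {s.rid}")
            elif net.edges[s.rid].netID != s.netID:
                errors.append(f"{label}: pid {s.pid} netID mismatch")
            if not (0.0 <= s.ratio <= 1.0):
                errors.append(f"{label}: pid {s.pid} ratio out of [0, 1]")
    return errors
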