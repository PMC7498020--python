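"""Minimal ESRI shapefile reader/writer (Point and PolyLine, 2-D).

Only what the .ssn exporter needs: single-part polylines, points, and DBF
attribute tables with C (text), N (numeric) fields. Deterministic output —
the DBF "last update" stamp is fixed so identical data yields identical
bytes.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

SHP_POINT = 1
SHP_POLYLINE = 3

_DBF_STAMP = (20, 1, 1)  # fixed YY MM DD for reproducible output


class ShapefileError(ValueError):
    pass


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _dbf_format(value, ftype: str, width: int, decimals: int) -> bytes:
    if ftype == "C":
        s = "" if value is None else str(value)
        return s[:width].ljust(width).encode("ascii", "replace")
    if ftype == "N":
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return b" " * width
        if decimals > 0:
            s = f"{float(value):{width}.{decimals}f}"
        else:
            s = f"{int(value):{width}d}"
        if len(s) > width:
            raise ShapefileError(f"numeric value {value!r} overflows width {width}")
        return s.encode("ascii")
    raise ShapefileError(f"unsupported DBF field type {ftype!r}")


def _write_dbf(path: Path, fields, records) -> None:
    """fields: list of (name, type, width, decimals); records: list of dicts."""
    nfields = len(fields)
    header_size = 32 + 32 * nfields + 1
    record_size = 1 + sum(f[2] for f in fields)
    with open(path, "wb") as fh:
        fh.write(
            struct.pack(
                "<BBBBIHH20x",
                0x03, *_DBF_STAMP, len(records), header_size, record_size,
            )
        )
        for name, ftype, width, decimals in fields:
            if len(name) > 10:
                raise ShapefileError(f"DBF field name too long: {name!r}")
            fh.write(
                struct.pack(
                    "<11sc4xBB14x",
                    name.encode("ascii"), ftype.encode("ascii"), width, decimals,
                )
            )
        fh.write(b"\x0d")
        for rec in records:
            fh.write(b" ")
            for name, ftype, width, decimals in fields:
                fh.write(_dbf_format(rec.get(name), ftype, width, decimals))
        fh.write(b"\x1a")


def _shp_record_bytes(shape_type: int, geom: np.ndarray) -> bytes:
    if shape_type == SHP_POINT:
        x, y = float(geom[0]), float(geom[1])
        return struct.pack("<idd", SHP_POINT, x, y)
    if shape_type == SHP_POLYLINE:
        pts = np.asarray(geom, dtype=float)
        xs, ys = pts[:, 0], pts[:, 1]
        head = struct.pack(
            "<idddd", SHP_POLYLINE, xs.min(), ys.min(), xs.max(), ys.max()
        )
        head += struct.pack("<iii", 1, len(pts), 0)
        body = b"".join(struct.pack("<dd", x, y) for x, y in pts)
        return head + body
    raise ShapefileError(f"unsupported shape type {shape_type}")


def write_shapefile(path_base: str | Path, shape_type: int, geoms, fields, records,
                    crs_tag: str = "") -> None:
    """Write <base>.shp/.shx/.dbf (and .prj when a CRS tag is given).

    ``geoms``: per-record (x, y) for points or an (n, 2) vertex array for
    polylines, order matching ``records``.
    """
    base = Path(path_base)
    if len(geoms) != len(records):
        raise ShapefileError("geometry/record count mismatch")
    contents = [_shp_record_bytes(shape_type, g) for g in geoms]

    offsets = []
    pos = 100
    for content in contents:
        offsets.append(pos)
        pos += 8 + len(content)
    file_len_words = pos // 2

    all_pts = []
    for g in geoms:
        arr = np.atleast_2d(np.asarray(g, dtype=float))
        all_pts.append(arr)
    stacked = np.vstack(all_pts) if all_pts else np.zeros((1, 2))
    bbox = (
        float(stacked[:, 0].min()), float(stacked[:, 1].min()),
        float(stacked[:, 0].max()), float(stacked[:, 1].max()),
    )

    def header(length_words: int) -> bytes:
        return (
            struct.pack(">i", 9994)
            + b"\x00" * 20
            + struct.pack(">i", length_words)
            + struct.pack("<ii", 1000, shape_type)
            + struct.pack("<4d", *bbox)
            + struct.pack("<4d", 0, 0, 0, 0)
        )

    with open(base.with_suffix(".shp"), "wb") as fh:
        fh.write(header(file_len_words))
        for i, content in enumerate(contents):
            fh.write(struct.pack(">ii", i + 1, len(content) // 2))
            fh.write(content)

    with open(base.with_suffix(".shx"), "wb") as fh:
        fh.write(header((100 + 8 * len(contents)) // 2))
        for off, content in zip(offsets, contents):
            fh.write(struct.pack(">ii", off // 2, len(content) // 2))

    _write_dbf(base.with_suffix(".dbf"), fields, records)
    if crs_tag:
        base.with_suffix(".prj").write_text(crs_tag + "\n")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_dbf(path: Path):
    data = path.read_bytes()
    nrec, header_size, record_size = struct.unpack("<IHH", data[4:12])
    fields = []
    pos = 32
    while data[pos] != 0x0D:
        name = data[pos : pos + 11].split(b"\x00")[0].decode("ascii")
        ftype = chr(data[pos + 11])
        width = data[pos + 16]
        decimals = data[pos + 17]
        fields.append((name, ftype, width, decimals))
        pos += 32
    records = []
    pos = header_size
    for _ in range(nrec):
        if data[pos : pos + 1] == b"*":  # deleted record
            pos += record_size
            continue
        off = pos + 1
        rec = {}
        for name, ftype, width, decimals in fields:
            raw = data[off : off + width].decode("ascii", "replace")
            off += width
            if ftype == "C":
                rec[name] = raw.strip()
            elif ftype in ("N", "F"):
                token = raw.strip()
                if not token:
                    rec[name] = None
                elif decimals > 0 or ftype == "F" or "." in token:
                    rec[name] = float(token)
                else:
                    rec[name] = int(token)
            else:
                rec[name] = raw.strip()
        records.append(rec)
        pos += record_size
    return fields, records


def read_shapefile(path_base: str | Path):
    """Read <base>.shp + .dbf. Returns (shape_type, geoms, records, crs_tag)."""
    base = Path(path_base)
    shp = base.with_suffix(".shp")
    if not shp.exists():
        raise ShapefileError(f"missing shapefile: {shp}")
    data = shp.read_bytes()
    if struct.unpack(">i", data[:4])[0] != 9994:
        raise ShapefileError(f"{shp}: not a shapefile")
    shape_type = struct.unpack("<i", data[32:36])[0]
    geoms = []
    pos = 100
    while pos < len(data):
        _, content_words = struct.unpack(">ii", data[pos : pos + 8])
        content = data[pos + 8 : pos + 8 + content_words * 2]
        pos += 8 + content_words * 2
        rtype = struct.unpack("<i", content[:4])[0]
        if rtype == SHP_POINT:
            geoms.append(np.array(struct.unpack("<dd", content[4:20])))
        elif rtype == SHP_POLYLINE:
            nparts, npoints = struct.unpack("<ii", content[36:44])
            if nparts != 1:
                raise ShapefileError("multi-part polylines are not supported")
            start = 44 + 4 * nparts
            pts = np.frombuffer(content[start : start + 16 * npoints], dtype="<f8")
            geoms.append(pts.reshape(-1, 2).copy())
        elif rtype == 0:  # null shape
            geoms.append(None)
        else:
            raise ShapefileError(f"unsupported shape type {rtype} in {shp}")
    _, records = _read_dbf(base.with_suffix(".dbf"))
    if len(records) != len(geoms):
        raise ShapefileError(f"{base}: .shp/.dbf record count mismatch")
    prj = base.with_suffix(".prj")
    crs_tag = prj.read_text().strip() if prj.exists() else ""
    return shape_type, geoms, records, crs_tag
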