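"""Site snapping, prediction-site generation, and measurement expansion.

The ``ratio`` of a site is measured from the **downstream** junction of its
edge: 0 at the downstream node, 1 at the upstream node. Along-network
distance of a site is ``upDist(edge) - (1 - ratio) * length(edge)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely

from .network import StreamNetwork


class SiteError(ValueError):
    pass


@dataclass
class Site:
    pid: int
    locID: int
    rid: int
    netID: int
    x: float
    y: float
    orig_x: float
    orig_y: float
    dist_moved: float
    ratio: float
    upDist_m: float
    attributes: dict = field(default_factory=dict)

    def copy(self) -> "Site":
        return replace(self, attributes=dict(self.attributes))


def _snappable_lines(net: StreamNetwork) -> dict[int, shapely.LineString]:
    # artificial stubs are topological fictions; sites never attach to them
    return {rid: e.line() for rid, e in net.edges.items() if not e.artificial}


def _site_updist(net: StreamNetwork, rid: int, ratio: float) -> float:
    e = net.edges[rid]
    return (e.upDist_m - e.length_m) + ratio * e.length_m


def snap_sites(
    points, net: StreamNetwork, max_dist: float
) -> tuple[list[Site], list[int]]:
    """Snap points to the nearest edge polyline.

    ``points`` is a sequence of ``(x, y)`` pairs or of mappings with ``x``
    and ``y`` keys (extra keys become site attributes). Points farther than
    ``max_dist`` from every edge are dropped; the second return value lists
    their 0-based input indices. Kept sites get ``locID`` (= ``pid``)
    numbered 1..n in input order. Equidistant edges tie-break to the
    smaller rid.
    """
    if not max_dist > 0:
        raise SiteError("max_dist must be > 0")
    if not net.edges:
        raise SiteError("snap_sites: empty network")
    lines = _snappable_lines(net)
    if not lines:
        raise SiteError("snap_sites: network has only artificial edges")
    sites: list[Site] = []
    dropped: list[int] = []
    loc = 0
    for i, p in enumerate(points):
        if isinstance(p, dict):
            x, y = float(p["x"]), float(p["y"])
            attrs = {k: v for k, v in p.items() if k not in ("x", "y")}
        else:
            x, y = float(p[0]), float(p[1])
            attrs = {}
        pt = shapely.Point(x, y)
        best_rid, best_dist = None, np.inf
        for rid in sorted(lines):
            d = lines[rid].distance(pt)
            if d < best_dist - 1e-9:
                best_rid, best_dist = rid, d
        if best_dist > max_dist:
            dropped.append(i)
            continue
        line = lines[best_rid]
        proj = line.project(pt)
        snapped = line.interpolate(proj)
        e = net.edges[best_rid]
        ratio = 1.0 - proj / e.length_m if e.length_m > 0 else 0.0
        ratio = min(max(ratio, 0.0), 1.0)
        loc += 1
        sites.append(
            Site(
                pid=loc,
                locID=loc,
                rid=best_rid,
                netID=e.netID,
                x=snapped.x,
                y=snapped.y,
                orig_x=x,
                orig_y=y,
                dist_moved=float(pt.distance(snapped)),
                ratio=float(ratio),
                upDist_m=_site_updist(net, best_rid, ratio),
                attributes=attrs,
            )
        )
    return sites, dropped


def generate_prediction_sites(
    net: StreamNetwork,
    n_sites: int | None = None,
    spacing_m: float | None = None,
    netIDs=None,
) -> list[Site]:
    """Evenly spaced prediction sites along the selected networks.

    Each network is walked from its outlet upstream through all branches
    (depth-first, so every outlet-to-leaf path along first-visited children
    is traversed contiguously); sites are dropped every ``spacing`` meters
    of walked length, starting half a spacing in from the outlet (the phase
    keeps sites off junction nodes). With ``n_sites`` given the spacing is
    ``total selected stream length / n_sites``, which makes the requested
    count exact whenever the spacing divides the total length. Exactly one
    of ``n_sites`` / ``spacing_m`` must be given.
    """
    if (n_sites is None) == (spacing_m is None):
        raise SiteError("give exactly one of n_sites or spacing_m")
    sel = set(netIDs) if netIDs is not None else set(net.netIDs())
    total = net.total_length(sel)
    if total <= 0:
        raise SiteError("selected networks have zero length")
    if n_sites is not None:
        if n_sites < 1:
            raise SiteError("n_sites must be >= 1")
        spacing = total / n_sites
    else:
        if not spacing_m > 0:
            raise SiteError("spacing_m must be > 0")
        spacing = float(spacing_m)
        max_updist = max(
            (e.upDist_m for e in net.edges.values() if e.netID in sel), default=0.0
        )
        if spacing > max_updist:
            warnings.warn(
                "prediction-site spacing exceeds the longest network; zero or "
                "few sites will be generated"
            )

    inflows = net.inflow_map()
    outlets = net.outlet_rids()
    sites: list[Site] = []
    pid = 0
    walked = 0.0  # cumulative walked length, continuous across the whole run
    for netID in sorted(sel):
        stack = [outlets[netID]]
        while stack:
            rid = stack.pop()
            e = net.edges[rid]
            # walk this edge from its downstream node to its upstream node
            t = (spacing / 2.0 - walked) % spacing
            if t < 1e-9:
                t = spacing
            while t <= e.length_m + 1e-9:
                ratio = min(t / e.length_m, 1.0) if e.length_m > 0 else 0.0
                pt = e.line().interpolate((1.0 - ratio) * e.length_m)
                pid += 1
                sites.append(
                    Site(
                        pid=pid,
                        locID=pid,
                        rid=rid,
                        netID=netID,
                        x=pt.x,
                        y=pt.y,
                        orig_x=pt.x,
                        orig_y=pt.y,
                        dist_moved=0.0,
                        ratio=float(ratio),
                        upDist_m=(e.upDist_m - e.length_m) + float(t),
                        attributes={},
                    )
                )
                t += spacing
            walked += e.length_m
            # smaller-rid child continues the contiguous walk next
            for child in sorted(inflows.get(e.from_node, []), reverse=True):
                stack.append(child)
    return sites


def merge_sites_with_measurements(
    sites: list[Site], table: pd.DataFrame, site_key: str
) -> list[Site]:
    """Expand sites into one record per measurement row.

    ``site_key`` names the table column holding site identifiers. A site
    matches a row when its attribute of the same name (falling back to its
    ``locID``) equals the row key. Output records duplicate the location's
    position/topology and static attributes, carry the measurement columns
    as extra attributes, share the location's ``locID`` and get fresh pids.
    Unmatched table rows are reported with a warning.
    """
    if site_key not in table.columns:
        raise SiteError(f"measurement table has no column {site_key!r}")
    by_key: dict = {}
    for s in sites:
        key = s.attributes.get(site_key, s.locID)
        by_key.setdefault(key, s)
    out: list[Site] = []
    unmatched = []
    pid = 0
    for _, row in table.iterrows():
        key = row[site_key]
        site = by_key.get(key)
        if site is None:
            unmatched.append(key)
            continue
        pid += 1
        rec = site.copy()
        rec.pid = pid
        for col in table.columns:
            if col != site_key:
                rec.attributes[col] = row[col]
        out.append(rec)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} measurement rows had no matching site: "
            f"{sorted(set(map(str, unmatched)))[:10]}"
        )
    return out
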