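"""Stream network extraction, topology construction and correction.

The stream raster is carved out of the flow-accumulation grid, partitioned
into segments between topological breakpoints, and vectorized into directed
edges (flow from the upstream node to the downstream node). Confluence cells
belong to their *downstream* segment, so the catchment draining through an
edge's downstream node is exactly the union of the edge's own reach
contributing area (RCA) and the RCAs of all edges upstream of it.
"""

from __future__ import annotations

import copy
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import shapely

from .flow import OFFSETS, AccumGrid, FlowDirGrid
from .grid import RasterGrid


class NetworkError(ValueError):
    pass


@dataclass
class Node:
    node_id: int
    x: float
    y: float
    kind: str  # source | confluence | outlet | pseudo


@dataclass
class Edge:
    """A directed stream segment between topological breakpoints."""

    rid: int
    netID: int
    from_node: int
    to_node: int
    geometry: np.ndarray               # (n, 2) vertices, upstream -> downstream
    cells: np.ndarray                  # (k, 2) int (row, col) along the segment
    rca_cells: np.ndarray              # (m, 2) int (row, col), disjoint across edges
    length_m: float = 0.0
    upDist_m: float = 0.0              # outlet -> this edge's UPSTREAM node
    rca_km2: float = 0.0
    h2o_km2: float = 0.0
    binaryID: str = ""
    prev_rids: list[int] = field(default_factory=list)
    shreve: int = 1
    artificial: bool = False
    attributes: dict = field(default_factory=dict)

    def recompute_length(self) -> None:
        diffs = np.diff(self.geometry, axis=0)
        self.length_m = float(np.sqrt((diffs ** 2).sum(axis=1)).sum())

    def line(self) -> shapely.LineString:
        return shapely.LineString(self.geometry)


class StreamNetwork:
    """A forest of directed in-tree stream networks (one outlet per netID)."""

    def __init__(
        self,
        cell_size: float,
        origin_x: float = 0.0,
        origin_y: float = 0.0,
        crs_tag: str = "",
        grid_shape: tuple[int, int] | None = None,
    ) -> None:
        self.cell_size = cell_size
        self.origin_x = origin_x
        self.origin_y = origin_y
        self.crs_tag = crs_tag
        self.grid_shape = grid_shape
        self.edges: dict[int, Edge] = {}
        self.nodes: dict[int, Node] = {}
        self._next_rid = 0
        self._next_node = 0

    # -- bookkeeping -------------------------------------------------------
    def add_node(self, x: float, y: float, kind: str) -> int:
        nid = self._next_node
        self._next_node += 1
        self.nodes[nid] = Node(nid, x, y, kind)
        return nid

    def add_edge(self, edge: Edge) -> None:
        if edge.rid in self.edges:
            raise NetworkError(f"duplicate rid {edge.rid}")
        self.edges[edge.rid] = edge
        self._next_rid = max(self._next_rid, edge.rid + 1)
        self._next_node = max(self._next_node, edge.from_node + 1, edge.to_node + 1)

    def new_rid(self) -> int:
        rid = self._next_rid
        self._next_rid += 1
        return rid

    def copy(self) -> "StreamNetwork":
        return copy.deepcopy(self)

    # -- topology queries --------------------------------------------------
    def outflow_map(self) -> dict[int, list[int]]:
        """node_id -> rids of edges leaving that node."""
        out: dict[int, list[int]] = defaultdict(list)
        for e in self.edges.values():
            out[e.from_node].append(e.rid)
        return out

    def inflow_map(self) -> dict[int, list[int]]:
        """node_id -> rids of edges entering that node."""
        inn: dict[int, list[int]] = defaultdict(list)
        for e in self.edges.values():
            inn[e.to_node].append(e.rid)
        return inn

    def upstream_rids(self, rid: int) -> list[int]:
        e = self.edges[rid]
        return sorted(self.inflow_map().get(e.from_node, []))

    def outlet_rids(self) -> dict[int, int]:
        """netID -> rid of the outlet edge (the edge whose downstream node
        has no outgoing edge)."""
        out = self.outflow_map()
        res: dict[int, int] = {}
        for e in self.edges.values():
            if not out.get(e.to_node):
                if e.netID in res:
                    raise NetworkError(f"netID {e.netID} has multiple outlet edges")
                res[e.netID] = e.rid
        return res

    def netIDs(self) -> list[int]:
        return sorted({e.netID for e in self.edges.values()})

    def total_length(self, netIDs=None) -> float:
        sel = set(netIDs) if netIDs is not None else None
        return sum(e.length_m for e in self.edges.values() if sel is None or e.netID in sel)

    def postorder(self) -> list[int]:
        """rids with every edge preceded by all edges upstream of it."""
        inn = self.inflow_map()
        order: list[int] = []
        for rid in self.outlet_rids().values():
            stack: list[tuple[int, bool]] = [(rid, False)]
            while stack:
                r, expanded = stack.pop()
                if expanded:
                    order.append(r)
                    continue
                stack.append((r, True))
                for child in sorted(inn.get(self.edges[r].from_node, [])):
                    stack.append((child, False))
        return order

    def admissibility_census(self) -> dict[str, list[int]]:
        """Nodes violating SSN topology rules.

        * diverging: more than one outgoing edge;
        * complex: three or more incoming edges;
        * converging_no_outflow: >= 2 incoming edges but no outgoing edge.
        """
        out, inn = self.outflow_map(), self.inflow_map()
        census = {"diverging": [], "complex": [], "converging_no_outflow": []}
        for nid in self.nodes:
            n_out, n_in = len(out.get(nid, [])), len(inn.get(nid, []))
            if n_out > 1:
                census["diverging"].append(nid)
            if n_in >= 3:
                census["complex"].append(nid)
            if n_in >= 2 and n_out == 0:
                census["converging_no_outflow"].append(nid)
        return census

    def is_admissible(self) -> bool:
        return not any(self.admissibility_census().values())

    # -- derived attributes ------------------------------------------------
    def recompute_derived(self) -> None:
        """Recompute h2o_km2, shreve, prev_rids, binaryID and upDist_m from the
        edge graph, RCA areas and lengths."""
        inn = self.inflow_map()
        complex_nets = {
            self.edges[rids[0]].netID for rids in inn.values() if len(rids) >= 3
        }
        order = self.postorder()
        seen = set(order)
        missing = set(self.edges) - seen
        if missing:
            raise NetworkError(f"edges unreachable from any outlet: {sorted(missing)}")

        for rid in order:  # children before parents
            e = self.edges[rid]
            ups = sorted(inn.get(e.from_node, []))
            e.prev_rids = ups
            if ups:
                e.h2o_km2 = e.rca_km2 + sum(self.edges[u].h2o_km2 for u in ups)
                e.shreve = sum(self.edges[u].shreve for u in ups)
            else:
                e.h2o_km2 = e.rca_km2
                e.shreve = 1

        outlet = self.outlet_rids()
        for netID, root in outlet.items():
            degenerate = netID in complex_nets
            if degenerate:
                warnings.warn(
                    f"netID {netID} contains complex confluences; binaryIDs left "
                    "blank until correct_complex_confluences is run"
                )
            stack = [root]
            e0 = self.edges[root]
            e0.binaryID = "1"
            e0.upDist_m = e0.length_m
            while stack:
                rid = stack.pop()
                e = self.edges[rid]
                ups = inn.get(e.from_node, [])
                # larger cumulative area gets "1"; tie -> smaller rid
                ups = sorted(ups, key=lambda u: (-self.edges[u].h2o_km2, u))
                for i, u in enumerate(ups):
                    ue = self.edges[u]
                    if degenerate:
                        ue.binaryID = ""
                    else:
                        ue.binaryID = e.binaryID + ("1" if i == 0 else "0")
                    ue.upDist_m = e.upDist_m + ue.length_m
                    stack.append(u)


# ---------------------------------------------------------------------------
# stream raster extraction
# ---------------------------------------------------------------------------

def _segment_stream_cells(mask: np.ndarray, fd: FlowDirGrid):
    """Partition stream cells into maximal D8 paths between breakpoints.

    Returns (segments, seg_index) where each segment is an ordered list of
    (row, col) running downstream, and seg_index maps a stream cell to its
    segment's position in the list. Breakpoints are headwater cells
    (no stream inflow) and junction cells (>= 2 stream inflows); a junction
    cell opens the downstream segment.
    """
    nrows, ncols = mask.shape
    indeg = np.zeros(mask.shape, dtype=np.int16)
    for r, c in np.argwhere(mask):
        t = fd.d8_target(r, c)
        if t is not None and mask[t]:
            indeg[t] += 1
    starts = [
        (int(r), int(c))
        for r, c in np.argwhere(mask)
        if indeg[r, c] == 0 or indeg[r, c] >= 2
    ]
    startset = set(starts)
    segments: list[list[tuple[int, int]]] = []
    seg_index: dict[tuple[int, int], int] = {}
    for start in starts:
        cells = [start]
        cur = start
        while True:
            t = fd.d8_target(*cur)
            if t is None or not mask[t] or (int(t[0]), int(t[1])) in startset:
                break
            cur = (int(t[0]), int(t[1]))
            cells.append(cur)
        idx = len(segments)
        segments.append(cells)
        for cell in cells:
            seg_index[cell] = idx
    return segments, seg_index, indeg


def extract_streams(
    acc: AccumGrid,
    fd: FlowDirGrid,
    accum_threshold: int,
    min_stream_length: int = 0,
) -> np.ndarray:
    """Stream raster: per-cell segment id (1-based) or 0.

    Stream cells are those whose accumulation reaches ``accum_threshold``;
    headwater segments shorter than ``min_stream_length`` cells are pruned
    iteratively until stable.
    """
    if accum_threshold < 1:
        raise NetworkError("accum_threshold must be >= 1")
    if min_stream_length < 0:
        raise NetworkError("min_stream_length must be >= 0")
    with np.errstate(invalid="ignore"):
        mask = np.where(np.isnan(acc.values), False, acc.values >= accum_threshold)
    if not mask.any():
        raise NetworkError(f"no streams at this threshold ({accum_threshold})")
    # enforce D8 continuity: MFD accumulation can dip below the threshold
    # along a D8 path, leaving a stream dead-end mid-grid; carry every such
    # dead-end downstream until it rejoins the stream or exits the grid
    for r, c in np.argwhere(mask):
        cur = (int(r), int(c))
        while True:
            t = fd.d8_target(*cur)
            if t is None or not fd.valid[t] or mask[t]:
                break
            mask[t] = True
            cur = t
    while True:
        segments, _, indeg = _segment_stream_cells(mask, fd)
        removed = False
        for cells in segments:
            if indeg[cells[0]] == 0 and len(cells) < min_stream_length:
                for rc in cells:
                    mask[rc] = False
                removed = True
        if not removed:
            break
        if not mask.any():
            raise NetworkError(
                "no streams left after min_stream_length pruning; lower the thresholds"
            )
    labels = np.zeros(mask.shape, dtype=np.int32)
    segments, _, _ = _segment_stream_cells(mask, fd)
    for i, cells in enumerate(segments, start=1):
        for rc in cells:
            labels[rc] = i
    return labels


# ---------------------------------------------------------------------------
# vectorization
# ---------------------------------------------------------------------------

def _rca_assignment(fd: FlowDirGrid, seg_of_cell: np.ndarray) -> np.ndarray:
    """For every valid cell, the segment index its water first reaches along
    its D8 path (-1 when the path leaves the grid without touching a stream).
    Memoized pointer chasing."""
    nrows, ncols = fd.shape
    res = np.full((nrows, ncols), -2, dtype=np.int32)
    res[~fd.valid] = -1
    for r0 in range(nrows):
        for c0 in range(ncols):
            if res[r0, c0] != -2:
                continue
            path = []
            cur = (r0, c0)
            val = -1
            while True:
                if res[cur] != -2:
                    val = res[cur]
                    break
                if seg_of_cell[cur] >= 0:
                    val = seg_of_cell[cur]
                    res[cur] = val  # stream cells belong to their own segment
                    break
                path.append(cur)
                t = fd.d8_target(*cur)
                if t is None or not fd.valid[t]:
                    val = -1
                    break
                cur = t
            for rc in path:
                res[rc] = val
    return res


def _boundary_extension(dem: RasterGrid, r: int, c: int) -> tuple[float, float]:
    """Half-cell extension point for an outlet edge whose last cell drains
    off-grid (or into nodata)."""
    x, y = dem.cell_center(r, c)
    h = dem.cell_size / 2.0
    # prefer the adjacent nodata/off-grid direction in neighbor order
    for dr, dc in OFFSETS:
        nr, nc = r + dr, c + dc
        if not dem.contains_cell(nr, nc) or not dem.valid[nr, nc]:
            return (x + dc * h, y - dr * h)
    return (x, y - h)


def vectorize(stream_labels: np.ndarray, fd: FlowDirGrid, dem: RasterGrid) -> StreamNetwork:
    """Build the directed edge/node network from a labeled stream raster.

    Edge geometries run through cell centers from upstream to downstream; an
    inflow edge's last vertex is the center of the junction cell that opens
    its downstream segment. netIDs are numbered by outlet position
    (south-most, then west-most, first); rids follow the scan order of each
    segment's head cell.
    """
    mask = stream_labels > 0
    if not mask.any():
        raise NetworkError("vectorize: empty stream raster")
    segments, seg_index, indeg = _segment_stream_cells(mask, fd)

    # deterministic rid order: scan order of the head cell
    order = sorted(range(len(segments)), key=lambda i: segments[i][0])
    rid_of_seg = {seg: rid for rid, seg in enumerate(order)}

    seg_of_cell = np.full(mask.shape, -1, dtype=np.int32)
    for i, cells in enumerate(segments):
        for rc in cells:
            seg_of_cell[rc] = i

    basin = _rca_assignment(fd, seg_of_cell)
    rca_lists: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for r, c in np.argwhere(basin >= 0):
        rca_lists[rid_of_seg[basin[r, c]]].append((int(r), int(c)))

    net = StreamNetwork(
        cell_size=dem.cell_size,
        origin_x=dem.origin_x,
        origin_y=dem.origin_y,
        crs_tag=dem.crs_tag,
        grid_shape=dem.shape,
    )
    cell_km2 = dem.cell_area_km2

    node_at: dict[tuple[float, float], int] = {}

    def node_for(xy: tuple[float, float], kind: str) -> int:
        key = (round(xy[0], 6), round(xy[1], 6))
        if key not in node_at:
            node_at[key] = net.add_node(xy[0], xy[1], kind)
        return node_at[key]

    downstream_seg: dict[int, int] = {}
    for rid in range(len(order)):
        seg = order[rid]
        cells = segments[seg]
        head, tail = cells[0], cells[-1]
        coords = [dem.cell_center(r, c) for r, c in cells]
        t = fd.d8_target(*tail)
        if t is not None and mask[t]:
            downstream_seg[rid] = rid_of_seg[seg_index[(int(t[0]), int(t[1]))]]
            coords.append(dem.cell_center(*t))
            to_kind = "confluence"
            to_xy = coords[-1]
        elif t is not None and fd.valid[t]:
            # stream ends on a non-stream cell (possible when extraction used
            # MFD accumulation): treat as a network outlet there
            coords.append(dem.cell_center(*t))
            to_kind = "outlet"
            to_xy = coords[-1]
        else:
            if len(coords) == 1:
                coords.append(_boundary_extension(dem, *tail))
            to_kind = "outlet"
            to_xy = coords[-1]

        from_kind = "confluence" if indeg[head] >= 2 else "source"
        rca = rca_lists.get(rid, [])
        edge = Edge(
            rid=rid,
            netID=0,
            from_node=node_for(coords[0], from_kind),
            to_node=node_for(to_xy, to_kind),
            geometry=np.asarray(coords, dtype=float),
            cells=np.asarray(cells, dtype=np.int32),
            rca_cells=np.asarray(rca, dtype=np.int32).reshape(-1, 2),
            rca_km2=len(rca) * cell_km2,
        )
        edge.recompute_length()
        net.add_edge(edge)

    # netID grouping by terminal segment, ordered south-most then west-most
    root_of: dict[int, int] = {}
    for rid in net.edges:
        cur = rid
        chain = []
        while cur in downstream_seg and cur not in root_of:
            chain.append(cur)
            cur = downstream_seg[cur]
        root = root_of.get(cur, cur)
        for r in chain:
            root_of[r] = root
        root_of[rid] = root
    roots = sorted(
        {root_of[rid] for rid in net.edges},
        key=lambda r: (net.nodes[net.edges[r].to_node].y, net.nodes[net.edges[r].to_node].x),
    )
    netid_of_root = {root: i + 1 for i, root in enumerate(roots)}
    for rid, e in net.edges.items():
        e.netID = netid_of_root[root_of[rid]]

    net.recompute_derived()
    return net


# ---------------------------------------------------------------------------
# topology checks and corrections
# ---------------------------------------------------------------------------

def check_complex_confluences(net: StreamNetwork) -> list[int]:
    """Node ids receiving three or more inflowing edges."""
    inn = net.inflow_map()
    return sorted(nid for nid, rids in inn.items() if len(rids) >= 3)


def _point_upstream_of_end(geometry: np.ndarray, dist: float) -> tuple[np.ndarray, np.ndarray]:
    """Split a polyline ``dist`` before its last vertex.

    Returns (truncated_geometry, cut_point). ``dist`` is clamped to half the
    polyline length so very short edges stay usable.
    """
    diffs = np.diff(geometry, axis=0)
    seglen = np.sqrt((diffs ** 2).sum(axis=1))
    total = seglen.sum()
    dist = min(dist, total / 2.0)
    remaining = dist
    i = len(seglen) - 1
    while i >= 0 and remaining > seglen[i]:
        remaining -= seglen[i]
        i -= 1
    i = max(i, 0)
    frac = 1.0 - remaining / seglen[i] if seglen[i] > 0 else 0.0
    cut = geometry[i] + frac * (geometry[i + 1] - geometry[i])
    trunc = np.vstack([geometry[: i + 1], cut])
    return trunc, cut


def correct_complex_confluences(net: StreamNetwork, offset_fraction: float = 0.25) -> StreamNetwork:
    """Split complex confluences into chains of two-inflow junctions.

    At each node with >= 3 inflows the two smallest-rid inflows are
    reconnected to a new pseudo node placed ``offset_fraction * cell_size``
    upstream along the smallest-rid inflow's geometry; a tiny artificial edge
    (empty RCA) joins the pseudo node to the old node. Repeats until every
    confluence has exactly two inflows, then recomputes derived attributes.
    """
    if not (0 < offset_fraction <= 0.5):
        raise NetworkError("offset_fraction must be in (0, 0.5]")
    net = net.copy()
    stub = offset_fraction * net.cell_size
    for nid in check_complex_confluences(net):
        while True:
            inflows = sorted(net.inflow_map().get(nid, []))
            if len(inflows) <= 2:
                break
            e1 = net.edges[inflows[0]]
            e2 = net.edges[inflows[1]]
            old = net.nodes[nid]
            trunc, cut = _point_upstream_of_end(e1.geometry, stub)
            vnew = net.add_node(float(cut[0]), float(cut[1]), "pseudo")
            e1.geometry = trunc
            e1.recompute_length()
            e1.to_node = vnew
            g2 = e2.geometry.copy()
            g2[-1] = cut
            e2.geometry = g2
            e2.recompute_length()
            e2.to_node = vnew
            art = Edge(
                rid=net.new_rid(),
                netID=e1.netID,
                from_node=vnew,
                to_node=nid,
                geometry=np.array([cut, [old.x, old.y]]),
                cells=np.empty((0, 2), dtype=np.int32),
                rca_cells=np.empty((0, 2), dtype=np.int32),
                rca_km2=0.0,
                artificial=True,
            )
            art.recompute_length()
            net.add_edge(art)
    net.recompute_derived()
    return net


def delete_lakes(net: StreamNetwork, lakes) -> StreamNetwork:
    """Remove edges intersecting lake polygons and renumber the severed
    upstream subtrees as new networks.

    Surviving networks that still contain their original outlet edge keep
    their netID; each severed component gets a fresh netID (assigned in
    outlet-coordinate order) and its own outlet node. Removed rids are
    retired, never reused.
    """
    lakes = [shapely.geometry.shape(g) if isinstance(g, dict) else g for g in (lakes or [])]
    lakes = [g for g in lakes if g is not None and not g.is_empty]
    if not lakes:
        return net.copy()
    union = shapely.union_all(lakes)
    net = net.copy()
    doomed = [rid for rid, e in net.edges.items() if e.line().intersects(union)]
    if not doomed:
        return net
    for rid in doomed:
        del net.edges[rid]
    if not net.edges:
        raise NetworkError("delete_lakes removed every edge in the network")

    out = net.outflow_map()
    old_netids = set()

    def root_of(rid: int) -> int:
        cur = rid
        while True:
            nxt = out.get(net.edges[cur].to_node, [])
            if not nxt:
                return cur
            cur = nxt[0]

    groups: dict[int, list[int]] = defaultdict(list)
    for rid in net.edges:
        old_netids.add(net.edges[rid].netID)
        groups[root_of(rid)].append(rid)

    # an original outlet edge is one whose downstream node is an 'outlet' node
    original_outlets = {
        root for root in groups if net.nodes[net.edges[root].to_node].kind == "outlet"
    }

    next_netid = max(old_netids) + 1 if old_netids else 1
    new_roots = sorted(
        (r for r in groups if r not in original_outlets),
        key=lambda r: (net.nodes[net.edges[r].to_node].y, net.nodes[net.edges[r].to_node].x),
    )
    for root in sorted(groups, key=lambda r: (r not in original_outlets, net.edges[r].netID)):
        if root in original_outlets:
            netid = net.edges[root].netID
        else:
            netid = next_netid + new_roots.index(root)
            old = net.nodes[net.edges[root].to_node]
            nid = net.add_node(old.x, old.y, "outlet")
            net.edges[root].to_node = nid
        for rid in groups[root]:
            net.edges[rid].netID = netid

    used_nodes = {e.from_node for e in net.edges.values()} | {
        e.to_node for e in net.edges.values()
    }
    net.nodes = {nid: n for nid, n in net.nodes.items() if nid in used_nodes}
    net.recompute_derived()
    return net
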