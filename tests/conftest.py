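import numpy as np
import pytest

from streamprep.flow import accumulate, d8_directions, mfd_directions
from streamprep.grid import RasterGrid, fill_depressions
from streamprep.network import Edge, StreamNetwork, extract_streams, vectorize

CRS = 'LOCAL_CS["test meters",UNIT["metre",1.0]]'


def make_grid(values, cell_size=10.0, origin_x=0.0, origin_y=None, crs=CRS):
    values = np.asarray(values, dtype=float)
    if origin_y is None:
        origin_y = values.shape[0] * cell_size
    return RasterGrid(values, cell_size, origin_x, origin_y, crs_tag=crs)


def run_pipeline(dem, accum_threshold, min_stream_length=0, routing="d8"):
    """fill -> directions -> accumulation -> extraction -> vectorize."""
    filled = fill_depressions(dem)
    fd = d8_directions(filled) if routing == "d8" else mfd_directions(filled)
    acc = accumulate(fd, mode=routing)
    labels = extract_streams(acc, fd, accum_threshold, min_stream_length)
    net = vectorize(labels, fd, filled)
    return net, fd, filled


# ---------------------------------------------------------------------------
# hand-built synthetic networks (geometry in meters, cell_size 10)
# ---------------------------------------------------------------------------

def _edge(net, rid, frm, to, geom, rca_km2):
    e = Edge(
        rid=rid, netID=1, from_node=frm, to_node=to,
        geometry=np.asarray(geom, dtype=float),
        cells=np.empty((0, 2), dtype=np.int32),
        rca_cells=np.empty((0, 2), dtype=np.int32),
        rca_km2=rca_km2,
    )
    e.recompute_length()
    net.add_edge(e)
    return e


def build_chain_net(n_edges=3, edge_len=100.0):
    """A straight chain of edges flowing south to an outlet at y=0."""
    net = StreamNetwork(cell_size=10.0, crs_tag=CRS)
    nodes = [net.add_node(0.0, i * edge_len, "pseudo") for i in range(n_edges + 1)]
    net.nodes[nodes[0]].kind = "outlet"
    net.nodes[nodes[-1]].kind = "source"
    for i in range(n_edges):
        _edge(
            net, i, nodes[i + 1], nodes[i],
            [[0.0, (i + 1) * edge_len], [0.0, i * edge_len]],
            rca_km2=0.1 * (i + 1),
        )
    net.recompute_derived()
    return net


def build_y_net():
    """Two headwaters joining at a confluence, one outlet edge."""
    net = StreamNetwork(cell_size=10.0, crs_tag=CRS)
    out = net.add_node(0.0, 0.0, "outlet")
    conf = net.add_node(0.0, 100.0, "confluence")
    s1 = net.add_node(-80.0, 200.0, "source")
    s2 = net.add_node(80.0, 200.0, "source")
    _edge(net, 0, conf, out, [[0.0, 100.0], [0.0, 0.0]], rca_km2=0.3)
    _edge(net, 1, s1, conf, [[-80.0, 200.0], [0.0, 100.0]], rca_km2=0.5)
    _edge(net, 2, s2, conf, [[80.0, 200.0], [0.0, 100.0]], rca_km2=0.2)
    net.recompute_derived()
    return net


def build_star_net(k):
    """k inflow edges converging on one node with a single outflow edge
    (complex confluence for k >= 3)."""
    net = StreamNetwork(cell_size=10.0, crs_tag=CRS)
    out = net.add_node(0.0, 0.0, "outlet")
    hub = net.add_node(0.0, 100.0, "confluence")
    _edge(net, 0, hub, out, [[0.0, 100.0], [0.0, 0.0]], rca_km2=0.1)
    for i in range(k):
        x = -100.0 + 200.0 * i / max(k - 1, 1)
        src = net.add_node(x, 220.0, "source")
        _edge(net, i + 1, src, hub, [[x, 220.0], [0.0, 100.0]], rca_km2=0.1 * (i + 2))
    net.recompute_derived()
    return net


@pytest.fixture
def y_net():
    return build_y_net()


@pytest.fixture
def chain_net():
    return build_chain_net(3)
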