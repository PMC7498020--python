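import numpy as np
import pytest

from streamprep.flow import upstream_cells
from streamprep.predictors import (
    PredictorError,
    PredictorLayer,
    attach_edge_attributes,
    rasterize_polygons,
    sites_attributes_approx,
    sites_attributes_exact,
)
from streamprep.sites import snap_sites

from test_network import y_dem
from conftest import make_grid, run_pipeline


@pytest.fixture(scope="module")
def y_case():
    dem = y_dem()
    net, fd, filled = run_pipeline(dem, accum_threshold=20)
    return net, fd, filled


def uniform_layer(filled, value=7.0, name="u"):
    return PredictorLayer(
        name=name, kind="continuous", stats=["mean", "sum"],
        grid=filled.like(np.full(filled.shape, value)),
    )


class TestAttachEdgeAttributes:
    def test_uniform_layer_mean(self, y_case):
        net, fd, filled = y_case
        attach_edge_attributes(net, [uniform_layer(filled)], filled)
        for e in net.edges.values():
            if len(e.rca_cells):
                assert e.attributes["u_mean_rca"] == pytest.approx(7.0)
            assert e.attributes["u_mean_cum"] == pytest.approx(7.0)

    def test_categorical_percent_definitional(self, y_case):
        net, fd, filled = y_case
        rng = np.random.default_rng(4)
        codes = rng.integers(1, 4, size=filled.shape).astype(float)
        layer = PredictorLayer(
            name="lu", kind="categorical", stats=["percent", "area_km2"],
            grid=filled.like(codes),
        )
        attach_edge_attributes(net, [layer], filled)
        outlet = net.edges[net.outlet_rids()[1]]
        basin = upstream_cells(fd, tuple(outlet.cells[-1]))
        n_basin = len(basin)
        for cls in (1, 2, 3):
            n_cls = sum(1 for rc in basin if codes[rc] == cls)
            assert outlet.attributes[f"lu_p{cls}_cum"] == pytest.approx(
                100.0 * n_cls / n_basin
            )
            assert outlet.attributes[f"lu_a{cls}_cum"] == pytest.approx(
                n_cls * filled.cell_area_km2
            )

    def test_cum_sum_matches_upstream_cells_oracle(self, y_case):
        net, fd, filled = y_case
        rng = np.random.default_rng(8)
        vals = filled.like(rng.uniform(0, 10, filled.shape))
        layer = PredictorLayer(name="v", kind="continuous", stats=["sum"], grid=vals)
        attach_edge_attributes(net, [layer], filled)
        outlet = net.edges[net.outlet_rids()[1]]
        basin = upstream_cells(fd, tuple(outlet.cells[-1]))
        direct = sum(vals.values[rc] for rc in basin)
        assert outlet.attributes["v_sum_cum"] == pytest.approx(direct, rel=1e-12)

    def test_aggregation_order_independent(self, y_case):
        net, fd, filled = y_case
        rng = np.random.default_rng(9)
        vals = filled.like(rng.uniform(0, 5, filled.shape))
        layer = PredictorLayer(name="w", kind="continuous", stats=["sum"], grid=vals)
        attach_edge_attributes(net, [layer], filled)

        # independent recursive-descent reference
        def cum(rid):
            e = net.edges[rid]
            own = sum(vals.values[r, c] for r, c in e.rca_cells)
            return own + sum(cum(u) for u in net.upstream_rids(rid))

        for e in net.edges.values():
            assert e.attributes["w_sum_cum"] == pytest.approx(cum(e.rid), rel=1e-12)

    def test_grid_mismatch_rejected(self, y_case):
        net, fd, filled = y_case
        bad = make_grid(np.zeros((3, 3)))
        layer = PredictorLayer(name="b", kind="continuous", stats=["mean"], grid=bad)
        with pytest.raises(Exception):
            attach_edge_attributes(net, [layer], filled)

    def test_layer_validation(self):
        with pytest.raises(PredictorError):
            PredictorLayer(name="x", kind="continuous", stats=["percent"], grid=None,
                           polygons=[])
        with pytest.raises(PredictorError):
            PredictorLayer(name="x", kind="nope", stats=["mean"])


class TestSiteAttribution:
    def _sites(self, net):
        pts = []
        rng = np.random.default_rng(6)
        for e in net.edges.values():
            for t in rng.uniform(0.1, 0.9, 3):
                p = e.line().interpolate(t * e.length_m)
                pts.append((p.x, p.y))
        sites, _ = snap_sites(pts, net, max_dist=20.0)
        return sites

    def test_ratio_zero_endpoint_equals_downstream_catchment(self, y_case):
        net, fd, filled = y_case
        attach_edge_attributes(net, [uniform_layer(filled)], filled)
        sites = self._sites(net)
        s = sites[0].copy()
        s.ratio = 0.0
        (out,) = sites_attributes_approx([s], net, [uniform_layer(filled)], filled)
        e = net.edges[s.rid]
        assert out.attributes["areaKm2"] == pytest.approx(e.h2o_km2, abs=1e-15)
        assert out.attributes["u_sum"] == pytest.approx(
            e.attributes["u_sum_cum"], abs=1e-12
        )

    def test_ratio_one_endpoint_equals_upstream_sum(self, y_case):
        net, fd, filled = y_case
        layer = uniform_layer(filled)
        attach_edge_attributes(net, [layer], filled)
        outlet = net.edges[net.outlet_rids()[1]]
        s = self._sites(net)[0].copy()
        s.rid = outlet.rid
        s.ratio = 1.0
        (out,) = sites_attributes_approx([s], net, [layer], filled)
        up_sum = sum(net.edges[u].attributes["u_sum_cum"] for u in outlet.prev_rids)
        assert out.attributes["u_sum"] == pytest.approx(up_sum, abs=1e-12)
        assert out.attributes["areaKm2"] == pytest.approx(
            sum(net.edges[u].h2o_km2 for u in outlet.prev_rids), abs=1e-15
        )

    def test_midpoint_arithmetic(self, y_case):
        """cum 10 km2, rca 2 km2, ratio 0.5 -> 9 km2."""
        net, fd, filled = y_case
        s = self._sites(net)[0].copy()
        e = net.edges[s.rid]
        e0_h2o, e0_rca = e.h2o_km2, e.rca_km2
        try:
            e.h2o_km2, e.rca_km2 = 10.0, 2.0
            s.ratio = 0.5
            (out,) = sites_attributes_approx([s], net, [], filled)
            assert out.attributes["areaKm2"] == pytest.approx(9.0)
        finally:
            e.h2o_km2, e.rca_km2 = e0_h2o, e0_rca

    def test_exact_outlet_area_is_basin(self, y_case):
        net, fd, filled = y_case
        outlet = net.edges[net.outlet_rids()[1]]
        end = outlet.geometry[-1]
        sites, _ = snap_sites([tuple(end)], net, max_dist=50.0)
        out = sites_attributes_exact(sites, fd, [], filled, net=net)
        basin = upstream_cells(fd, tuple(outlet.cells[-1]))
        assert out[0].attributes["areaKm2_ex"] == pytest.approx(
            len(basin) * filled.cell_area_km2
        )

    def test_exact_equals_approx_at_ratio_zero(self, y_case):
        net, fd, filled = y_case
        attach_edge_attributes(net, [uniform_layer(filled)], filled)
        for e in net.edges.values():
            s = self._sites(net)[0].copy()
            s.rid = e.rid
            s.ratio = 0.0
            end = e.geometry[-1]
            s.x, s.y = float(end[0]), float(end[1])
            (a,) = sites_attributes_approx([s], net, [], filled)
            (x,) = sites_attributes_exact([s], fd, [], filled, net=net)
            assert a.attributes["areaKm2"] == pytest.approx(
                x.attributes["areaKm2_ex"], abs=1e-12
            )

    def test_uniform_layer_exact_mean(self, y_case):
        net, fd, filled = y_case
        sites = self._sites(net)
        out = sites_attributes_exact(sites, fd, [uniform_layer(filled)], filled, net=net)
        for s in out:
            assert s.attributes["u_mean_ex"] == pytest.approx(7.0)

    def test_interpolation_error_bounded_by_rca(self, y_case):
        net, fd, filled = y_case
        sites = self._sites(net)
        approx = sites_attributes_approx(sites, net, [], filled)
        exact = sites_attributes_exact(approx, fd, [], filled, net=net)
        for s in exact:
            e = net.edges[s.rid]
            err = abs(s.attributes["areaKm2"] - s.attributes["areaKm2_ex"])
            assert err <= e.rca_km2 + 1e-12

    def test_class_percents_sum_to_100(self, y_case):
        net, fd, filled = y_case
        rng = np.random.default_rng(10)
        codes = filled.like(rng.integers(1, 4, filled.shape).astype(float))
        layer = PredictorLayer(name="c", kind="categorical", stats=["percent"], grid=codes)
        attach_edge_attributes(net, [layer], filled)
        sites = self._sites(net)
        out = sites_attributes_approx(sites, net, [layer], filled)
        for s in out:
            tot = sum(s.attributes[f"c_p{k}"] for k in (1, 2, 3))
            assert tot == pytest.approx(100.0)
            for k in (1, 2, 3):
                assert -1e-9 <= s.attributes[f"c_p{k}"] <= 100.0 + 1e-9

    def test_missing_edge_attributes_rejected(self, y_case):
        net, fd, filled = y_case
        fresh_net, _, _ = run_pipeline(y_dem(), accum_threshold=20)
        sites = self._sites(fresh_net)
        with pytest.raises(PredictorError, match="attach_edge_attributes"):
            sites_attributes_approx(sites, fresh_net, [uniform_layer(filled)], filled)

    def test_approx_exact_correlation(self, y_case):
        net, fd, filled = y_case
        sites = self._sites(net)
        assert len(sites) >= 9
        approx = sites_attributes_approx(sites, net, [], filled)
        exact = sites_attributes_exact(approx, fd, [], filled, net=net)
        a = np.array([s.attributes["areaKm2"] for s in exact])
        x = np.array([s.attributes["areaKm2_ex"] for s in exact])
        assert np.corrcoef(a, x)[0, 1] > 0.95


class TestPolygonRasterization:
    def test_nodata_excluded_from_means(self, y_case):
        net, fd, filled = y_case
        vals = np.full(filled.shape, 4.0)
        vals[:5, :] = np.nan
        layer = PredictorLayer(
            name="m", kind="continuous", stats=["mean"], grid=filled.like(vals)
        )
        attach_edge_attributes(net, [layer], filled)
        for e in net.edges.values():
            m = e.attributes["m_mean_cum"]
            if not np.isnan(m):
                assert m == pytest.approx(4.0)

    def test_raster_and_polygon_paths_agree(self):
        from streamprep.fixtures import FixtureSpec, make_dem, make_landuse

        spec = FixtureSpec(nrows=30, ncols=30, n_classes=3, seed=12)
        dem = make_dem(spec)
        grid, feats = make_landuse(spec, dem)
        back = rasterize_polygons(
            [(g, p["class"]) for g, p in feats], dem
        )
        np.testing.assert_array_equal(back.values, grid.values)
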