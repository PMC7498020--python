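# streamprep

Turn a digital elevation model (DEM), sampling-site coordinates and optional
predictor layers into a topologically valid spatial-stream-network dataset
(a `.ssn` directory) ready for SSN-style spatial modelling — with no
external GIS dependency.

The pipeline:

1. **Condition the DEM** — optional stream burning, priority-flood
   depression filling with an epsilon gradient (`streamprep.grid`).
2. **Route flow** — D8 and Freeman-style MFD flow directions and
   accumulation, plus D8 upstream tracing for catchments
   (`streamprep.flow`).
3. **Extract and clean the network** — threshold the accumulation grid,
   enforce D8 continuity, prune short headwaters, vectorize into directed
   edges with reach contributing areas (RCAs), Shreve orders, binaryIDs and
   along-network distances; detect and correct complex (3+-inflow)
   confluences; optionally sever the network at lake polygons
   (`streamprep.network`).
4. **Handle sites** — snap observation points to edges (with a maximum
   snap distance), generate evenly spaced prediction sites, expand repeated
   measurements (`streamprep.sites`).
5. **Attribute predictors** — summarize raster or polygon layers over RCAs
   and catchments, then attribute sites by the fast edge-interpolated
   (approximate) method or by exact per-site catchment delineation
   (`streamprep.predictors`).
6. **Export** — write `edges`/`sites`/`preds` layers (shapefile by default,
   GeoJSON as a dialect) plus per-network `netID<k>.dat` topology tables
   into a `.ssn` directory; re-read and validate it (`streamprep.ssn`).

`streamprep.fixtures` generates deterministic synthetic inputs (DEM relief
models, jittered sites, Voronoi land use, repeated measurements) so every
stage is testable offline.

Raster I/O covers ESRI ASCII grids and GeoTIFF (via `tifffile`); vector I/O
covers GeoJSON and an internal shapefile reader/writer. All inputs must
share one projected CRS in meters with square cells.

## CLI

Generate a synthetic input bundle:

```sh
streamprep fixtures --out demo/ --relief twin_valley --seed 42
```

Run the full pipeline from a config file (JSON or YAML; paths are resolved
relative to the config file):

```sh
streamprep run --config demo/config.json
streamprep check --root demo/out.ssn     # validate an exported directory
```

Example config:

```json
{
  "dem": "dem.asc",
  "sites": "sites.geojson",
  "streams": null,
  "burn_depth": 0,
  "routing": "mfd",
  "accum_threshold": 20,
  "min_stream_length": 16,
  "max_snap_dist": 150,
  "predictors": [
    {"name": "lu", "path": "landuse.asc", "kind": "categorical",
     "stats": ["percent", "area_km2"]}
  ],
  "prediction_sites": {"n_sites": 10},
  "measurements": {"path": "measurements.csv", "key": "site_id"},
  "out_root": "out.ssn",
  "overwrite": true
}
```

Key conventions:

* `ratio` of a site is measured from its edge's **downstream** junction
  (0 = downstream node, 1 = upstream node).
* `upDist` of an edge is the along-network distance from the network outlet
  to the edge's **upstream** node; the outlet edge's `upDist` equals its own
  length.
* binaryIDs: the outlet edge is `"1"`; at each confluence the inflow with
  the larger cumulative catchment appends `"1"`, the other `"0"`.
* Artificial edges created by complex-confluence correction carry an empty
  RCA, so catchment areas stay exactly additive.

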