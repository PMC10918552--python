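# fcaccess

Spatial accessibility of health services with floating catchment area
methods — classic **2SFCA** and enhanced **E2SFCA** — using either
Euclidean distance buffers or road-network travel-time catchments.
`fcaccess` is a plain Python library + CLI: no desktop GIS, no online
routing service, no network-analysis license.

## Who this is for

Health-services and health-equity researchers who need a per-area
accessibility index — "how many providers (physicians, dialysis
machines, hospital beds) are effectively available per 100,000 people
here?" — from three inputs:

- a **provider point layer** (ID + capacity $S_j$),
- a **demand polygon layer** (ID + population $P_i$, e.g. census tracts,
  optionally with per-age-group counts),
- optionally a **road network** (node/edge tables with travel times in
  minutes).

Vector layers are GeoJSON in a projected CRS (linear units; geographic
lat/lon is refused), tables are CSV.

## The model

**Classic 2SFCA.** Step 1: each provider $j$ gets a provider-to-demand
ratio over the demand within its catchment $d_0$,

$$R_j = \frac{S_j}{\sum_{k:\, d_{kj} \le d_0} P_k}.$$

Step 2: each demand location $i$ sums the ratios of the providers it can
reach,

$$A_i = \sum_{j:\, d_{ij} \le d_0} R_j.$$

**Enhanced E2SFCA.** The catchment splits into three nested zones $D_r$
(defaults 5/10/15 miles, or 10/20/30 minutes) with step distance-decay
weights $W_r$ (default $1,\ 0.68,\ 0.22$) applied in both steps:

$$R_j = \frac{S_j}{\sum_r W_r \sum_{k:\, d_{kj} \in D_r} P_k},
\qquad
A_i = \sum_r W_r \sum_{j:\, d_{ij} \in D_r} R_j.$$

Catchments are either exact Euclidean distance bands or travel-time
isochrones (convex hulls of the network nodes reachable within each
cutoff, computed by cutoff-bounded Dijkstra). Demand can be
**age-adjusted** first: per-age-group counts are reweighted by
incidence-rate ratios (e.g. end-stage kidney disease rates yield integer
weights 1/7/51/106/189 across five age groups), giving a need-based
population. Scores are reported per capita (default ×100,000) and can be
classed for mapping with exact natural-breaks (Jenks) classification.

## Worked example

Generate a synthetic study area (20×20 grid of 2-km "tracts" with
age-structured populations, 16 capacity-weighted providers, grid road
network) and run the enhanced buffer tool with its defaults:

```sh
fcaccess make-fixtures --outdir fx --rows 8 --cols 8 --providers 4 --seed 7
fcaccess e2sfca-buffer --providers fx/providers.geojson \
    --demand fx/demand.geojson --out access.geojson
```

which prints the score summary:

```
n                           64.000000
min                         25.345289
q25                         32.056280
median                      36.006661
mean                        34.631140
q75                         37.885150
max                         39.957041
population_weighted_mean    34.979984
zero_access_count            0.000000
zero_access_share            0.000000
```

Read: every one of the 64 cells has access; a typical resident
effectively has ~35 provider capacity units per 100,000 people within
the weighted 5/10/15-mile zones. `access.geojson` mirrors the demand
layer plus `final_index`, `zone1_index`–`zone3_index` (the three zones'
contributions), and the per-capita `scaled_index`; a manifest JSON
records parameters and warning counts.

The travel-time tools are two-stage — build catchments once, reuse them
across runs:

```sh
fcaccess create-catchments --providers fx/providers.geojson \
    --network-nodes fx/network_nodes.csv --network-edges fx/network_edges.csv \
    --thresholds 10,20,30 --out pcat.geojson
fcaccess create-catchments --demand fx/demand.geojson \
    --network-nodes fx/network_nodes.csv --network-edges fx/network_edges.csv \
    --direction from_origin --out dcat.geojson
fcaccess e2sfca-travel --providers fx/providers.geojson --demand fx/demand.geojson \
    --catchments pcat.geojson dcat.geojson --out access_tt.geojson
```

The same pipeline is available from Python (`fcaccess.run_model`,
`fcaccess.apply_age_adjustment`, `fcaccess.jenks_breaks`, ...).

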