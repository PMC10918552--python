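# Methods

## Model

Spatial accessibility is measured with floating catchment area methods.
Both steps operate on point representatives: providers are points with
capacity S_j; each demand polygon is collapsed to a representative point
(centroid when interior, otherwise a guaranteed-interior point) carrying
population P_i. The classic two-step method (2SFCA) computes, within a
catchment of radius d0,

    R_j = S_j / sum_{k: d_kj <= d0} P_k        (step 1, per provider)
    A_i = sum_{j: d_ij <= d0} R_j              (step 2, per demand unit)

The enhanced method (E2SFCA) replaces the all-or-nothing catchment with
three nested zones D_1..D_3 and a step distance-decay weight W_r applied
in both steps. A_i then decomposes into per-zone components that sum to
the final index; both are written to the output layer.

Assumptions inherited from the model family: demand interacts with
supply only within the outermost zone; all residents of a polygon sit at
its representative point (no areal interpolation — a membership decision
is all-or-nothing per polygon); distances are planar Euclidean between
points, so layers must use a projected CRS (readers refuse known
geographic descriptors rather than computing degree distances).

## Catchments

**Buffers.** Zone membership in buffer mode is decided by exact
point-to-point distance against the thresholds, not by point-in-polygon
tests on discretized circles; polygonal buffers (128-segment circles,
disk-area error ~0.04%) exist only for persistence and display. This
removes discretization artifacts from the scores entirely.

**Travel-time isochrones.** An origin snaps to its nearest network node
(ties broken to the smallest node id). One cutoff-bounded Dijkstra at
the largest cutoff yields arrival times; each zone's outer region is the
convex hull of the nodes within its cutoff. Reachable sets nest, so
hulls nest, and zones are their successive set-differences. A cutoff
that reaches no area (isolated node, cutoff below every incident edge)
degenerates to a tiny buffered point with a logged warning. Convex hulls
are a deliberate choice over concave/alpha shapes: they are
deterministic, parameter-free and checkable against enumeration; on the
uniform grid fixtures they are exact (a Manhattan ball hulls to its
diamond, and every grid point inside the diamond is genuinely within the
cutoff). On strongly concave real networks they overestimate fringe
membership; the structure admits a buffered-edge polygonizer as a future
option without changing the membership interface.

**Zone boundaries.** Intervals are half-open: zone 1 is [0, t1], zone r
is (t_{r-1}, t_r]. A point exactly on a shared edge belongs to the inner
(higher-weight) zone. Polygon membership realizes the same rule by
taking the first nested region that covers the point.

**Step-2 membership.** Buffer variants use the one symmetric distance
test in both steps. Travel variants follow the two-file design: step 1
tests demand points against provider isochrones (built toward the
provider — patients travel to facilities), step 2 tests provider points
against demand isochrones (built outward from homes). On directed
networks the two matrices can disagree; the disagreement count is
logged, not an error.

## Parameters and units

| parameter | default | meaning |
|---|---|---|
| classic buffer d0 | 15 miles | catchment radius |
| enhanced zones | 5 / 10 / 15 miles | nested zone edges |
| classic travel cutoff | 30 min | drive-time catchment |
| enhanced travel cutoffs | 10 / 20 / 30 min | nested zone edges |
| zone weights W_r | 1, 0.68, 0.22 | step distance decay |
| per-capita multiplier | 100,000 | reporting scale |

Thresholds always carry explicit units; internal computation is in
meters with 1 mile = 1609.344 m exactly (the common "1 mile = 1.6 km"
is display rounding, not a conversion). The zone weights are
configuration constants of the step-decay family, not fitted values;
users should choose weights appropriate to their service context.

## Age-adjusted demand

Demand can be reweighted by per-age-group incidence-rate ratios:
weight(g) = rate(g) / rate(baseline), rounded to the nearest integer
half-away-from-zero — the only rounding rule consistent with the
published integer weight set (77/11 = 7, 561/11 = 51, 1171/11 = 106.45
-> 106, 2080/11 = 189.09 -> 189); a flag keeps the unrounded ratios for
sensitivity analyses. Group labels are opaque strings matched exactly —
the module does not parse age bins or harmonize mismatched labelings
(reference rate tables are not always internally consistent about bin
edges), leaving that to the user.

## Numerical choices

- All score reductions (catchment demand totals, ratio sums, zone
  components) use `math.fsum`, the correctly rounded float sum. Results
  are therefore independent of summation order and bit-reproducible,
  and a naive double-loop reference reproduces them exactly rather than
  to a tolerance.
- R_j := 0 (with a logged warning) for providers whose catchment holds
  zero (weighted) demand, keeping every provider in the outputs without
  dividing by zero. The supply-conservation identity is stated
  conditionally on no such providers.
- Jenks natural breaks use the exact O(k·n²) dynamic program over
  distinct values with multiplicities — optimal, deterministic (ties
  resolve toward the smallest split index), and adequate for
  choropleth-scale inputs (thousands of units); k defaults to 5 classes.
- Snapping ties and zone-boundary ties are broken deterministically
  (smallest node id; inner zone), so repeated runs are identical.

## Supply conservation

When membership is shared between the two steps (step-2 zone(i,j) equals
step-1 zone(j,i)) and no provider has an empty catchment, the weighted
numerators and denominators cancel and

    sum_i P_i · A_i = sum_j S_j

exactly, for classic and enhanced variants alike. Buffer variants
satisfy the premise by construction. For travel variants the premise
requires demand points to sit on the network: the covering-scenario
generator therefore places road nodes at cell centers (so demand
representative points and providers are network nodes), making hull
membership symmetric on the uniform grid. The test suite verifies the
identity to 1e-9 relative across all four variants on seeded covering
scenarios.

## Synthetic data

`make_scenario` emulates a census-tract-like study area: an r×c grid of
square cells (default 2 km) whose populations are negative-binomial
draws (mean 3,981, dispersion 5.86, hence SD ≈ 1,646 — typical tract
heterogeneity), split into five age groups by a multinomial draw
(shares 0.22/0.36/0.25/0.10/0.07 over 0-17, 18-44, 45-64, 65-74, 75+,
a plausible US age structure); providers are uniform points with
capacities 1 + Poisson(17) (dialysis-center-like, mean ≈ 18 machines);
the road network is the cell-corner grid with a uniform 48 km/h speed
(2.5 min per 2-km edge). Everything derives from one numpy Generator
seed; provider coordinates are rounded to millimeters for cross-platform
byte-identity.

`make_covering_scenario` additionally guarantees the conservation
preconditions (providers on an evenly spaced cell-center subgrid; every
population at least 1) and verifies them by direct distance and
network-time checks, raising a configuration error for infeasible
threshold/spacing combinations.

What the generator does **not** emulate: real road topology (no dead
ends, one-ways, or speed heterogeneity), irregular tract shapes and
sizes, spatially correlated population and provider clustering
(urban/rural structure). Passing tests therefore demonstrate
correctness of the computation and its invariants, not realism of any
particular accessibility surface; empirical conclusions still require
real provider, census and network data.

## Problem sizes

Default test and acceptance runs use grids up to 20×20 cells,
up to ~200 demand units × 50 providers for reference comparisons, and
road graphs up to a few hundred nodes — sizes at which the exhaustive
oracles (double loops, Bellman-Ford, exhaustive partitions) remain
exact and the full suite completes in seconds. The implementation
itself is vectorized (distance matrices, vectorized point-in-polygon)
and handles choropleth-scale inputs (~2,000 tracts × ~200 providers)
comfortably.

## Known limitations

- GeoJSON + CSV only; no GeoPackage/Shapefile dialects and no
  reprojection — supply projected coordinates.
- Representative-point membership only; polygons partially overlapping
  a catchment are in or out as a whole (areal interpolation is a noted
  future option).
- Static edge travel times; no traffic profiles, turn restrictions or
  mode inference — travel mode is whatever the user's edge weights
  encode.
- Convex isochrones can over-cover around concave network boundaries.
- Zone weights are constants; no continuous decay functions (gravity,
  Gaussian kernel) in this release.
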