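"""Self-contained synthetic study areas for testing and examples.

A scenario is a rectangular grid of census-tract-like square cells with
age-structured populations, capacity-weighted provider points scattered
over the extent, and a grid road network with a uniform travel speed.
Defaults mimic a mid-sized US study region: cell populations drawn from
a negative-binomial (gamma-Poisson) distribution with mean 3,981 and
SD ~1,646 people (typical census-tract heterogeneity), five age groups,
dialysis-center-like provider capacities around 18 machines, 2-km cells
and 48 km/h uniform road speed.

Everything is deterministic given the seed (numpy Generator; coordinates
rounded to millimeters), and the generated layers pass geodata_io
validation unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .catchment import DEFAULT_BUFFER_MILES, DEFAULT_TRAVEL_MIN
from .errors import ConfigurationError
from .geodata_io import DemandLayer, ProviderLayer
from .road_network import RoadNetwork, build_network
from .units import to_meters

#: default age split over the five groups of the demand-weighting table
DEFAULT_AGE_SHARES = {
    "0-17": 0.22,
    "18-44": 0.36,
    "45-64": 0.25,
    "65-74": 0.10,
    "75+": 0.07,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic study area.

    ``pop_dispersion`` is the negative-binomial shape r (variance =
    mean + mean^2 / r); the default reproduces SD ~1,646 at mean 3,981.
    ``road_nodes`` places network nodes at cell ``corners`` (default) or
    cell ``centers`` (used by covering scenarios, where demand points
    must sit on the network).
    """

    rows: int = 20
    cols: int = 20
    cell_km: float = 2.0
    pop_mean: float = 3981.0
    pop_dispersion: float = 5.86
    age_shares: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SHARES))
    n_providers: int = 16
    capacity_mean: float = 18.0
    road_speed_kmh: float = 48.0
    road_nodes: str = "corners"
    seed: int = 42

    def __post_init__(self):
        if min(self.rows, self.cols, self.n_providers) <= 0:
            raise ConfigurationError("rows, cols and n_providers must be positive")
        if self.cell_km <= 0 or self.pop_mean <= 0 or self.pop_dispersion <= 0:
            raise ConfigurationError("cell size and population parameters must be positive")
        if self.road_speed_kmh <= 0:
            raise ConfigurationError("road speed must be positive")
        if self.road_nodes not in ("corners", "centers"):
            raise ConfigurationError("road_nodes must be 'corners' or 'centers'")
        total = math.fsum(self.age_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"age shares must sum to 1, got {total}")

    @property
    def cell_m(self) -> float:
        return self.cell_km * 1000.0

    @property
    def edge_minutes(self) -> float:
        """Travel time along one cell edge at the uniform speed."""
        return self.cell_km / self.road_speed_kmh * 60.0


def _cell_polygons(spec: ScenarioSpec):
    ids, polys, centers = [], [], []
    c = spec.cell_m
    for r in range(spec.rows):
        for q in range(spec.cols):
            x0, y0 = q * c, r * c
            ids.append(f"c{r:03d}_{q:03d}")
            polys.append(Polygon([(x0, y0), (x0 + c, y0), (x0 + c, y0 + c), (x0, y0 + c)]))
            centers.append((x0 + c / 2, y0 + c / 2))
    return ids, polys, centers


def _draw_populations(spec: ScenarioSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    r = spec.pop_dispersion
    p = r / (r + spec.pop_mean)
    return rng.negative_binomial(r, p, size=n).astype(float)


def _draw_age_counts(spec: ScenarioSpec, rng: np.random.Generator,
                     populations: np.ndarray) -> dict:
    groups = list(spec.age_shares)
    shares = np.array([spec.age_shares[g] for g in groups], dtype=float)
    counts = {g: np.zeros(len(populations)) for g in groups}
    for i, pop in enumerate(populations):
        draw = rng.multinomial(int(pop), shares)
        for g, c in zip(groups, draw):
            counts[g][i] = float(c)
    return counts


def _draw_capacities(spec: ScenarioSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    # at least one machine/provider per facility
    return 1.0 + rng.poisson(max(spec.capacity_mean - 1.0, 0.0), size=n).astype(float)


def _grid_network(spec: ScenarioSpec) -> RoadNetwork:
    c = spec.cell_m
    t = spec.edge_minutes
    if spec.road_nodes == "corners":
        nr, nc = spec.rows + 1, spec.cols + 1
        origin = 0.0
    else:  # nodes at cell centers
        nr, nc = spec.rows, spec.cols
        origin = c / 2
    nodes = [
        {"node_id": r * nc + q, "x": origin + q * c, "y": origin + r * c}
        for r in range(nr)
        for q in range(nc)
    ]
    edges = []
    for r in range(nr):
        for q in range(nc):
            nid = r * nc + q
            if q + 1 < nc:
                edges.append({"from_node": nid, "to_node": nid + 1, "travel_time_min": t})
            if r + 1 < nr:
                edges.append({"from_node": nid, "to_node": nid + nc, "travel_time_min": t})
    return build_network(pd.DataFrame(nodes), pd.DataFrame(edges), directed=False)


def make_scenario(spec: ScenarioSpec | None = None):
    """Generate (ProviderLayer, DemandLayer, RoadNetwork) from a spec.

    Demand polygons tile the grid exactly; providers fall uniformly inside
    the extent (coordinates rounded to 1 mm for cross-platform
    determinism); the road network covers the grid with uniform edge
    travel times derived from cell size and speed.
    """
    spec = spec or ScenarioSpec()
    rng = np.random.default_rng(spec.seed)
    ids, polys, _centers = _cell_polygons(spec)
    populations = _draw_populations(spec, rng, len(ids))
    age_counts = _draw_age_counts(spec, rng, populations)
    demand = DemandLayer(
        tuple(ids), populations, tuple(polys), age_counts=age_counts,
    )
    extent_x, extent_y = spec.cols * spec.cell_m, spec.rows * spec.cell_m
    px = np.round(rng.uniform(0, extent_x, spec.n_providers), 3)
    py = np.round(rng.uniform(0, extent_y, spec.n_providers), 3)
    providers = ProviderLayer(
        tuple(f"p{i:03d}" for i in range(spec.n_providers)),
        _draw_capacities(spec, rng, spec.n_providers),
        tuple(Point(x, y) for x, y in zip(px, py)),
    )
    return providers, demand, _grid_network(spec)


def make_covering_scenario(
    spec: ScenarioSpec | None = None,
    buffer_threshold_miles: float = DEFAULT_BUFFER_MILES[0],
    travel_cutoff_min: float = DEFAULT_TRAVEL_MIN[0],
):
    """Scenario guaranteeing the supply-conservation preconditions.

    Providers are placed at cell-center road nodes on a regular subgrid
    chosen so that (verified by direct membership checks) every provider
    catchment contains at least one demand point and every demand unit
    reaches at least one provider — both within the buffer threshold and
    within the travel-time cutoff. Road nodes sit at cell centers so that
    demand representative points lie exactly on the network, which makes
    travel-time membership symmetric between the two steps on the uniform
    grid.

    Raises :class:`ConfigurationError` when the thresholds are too small
    for the requested grid spacing.
    """
    spec = spec or ScenarioSpec()
    if spec.road_nodes != "centers":
        spec = ScenarioSpec(**{**asdict(spec), "road_nodes": "centers"})
    rng = np.random.default_rng(spec.seed)
    ids, polys, centers = _cell_polygons(spec)
    populations = np.maximum(_draw_populations(spec, rng, len(ids)), 1.0)
    age_counts = _draw_age_counts(spec, rng, populations)
    demand = DemandLayer(tuple(ids), populations, tuple(polys), age_counts=age_counts)

    # provider subgrid: about sqrt(n) positions per axis, evenly spread
    k = max(1, round(math.sqrt(spec.n_providers)))
    row_picks = [int((i + 0.5) * spec.rows / k) for i in range(min(k, spec.rows))]
    col_picks = [int((i + 0.5) * spec.cols / k) for i in range(min(k, spec.cols))]
    cells = [(r, q) for r in sorted(set(row_picks)) for q in sorted(set(col_picks))]
    pts = [Point(*centers[r * spec.cols + q]) for r, q in cells]
    providers = ProviderLayer(
        tuple(f"p{i:03d}" for i in range(len(pts))),
        _draw_capacities(spec, rng, len(pts)),
        tuple(pts),
    )
    net = _grid_network(spec)

    # verify the conservation preconditions by direct membership checks
    d0 = to_meters(buffer_threshold_miles, "miles")
    ccoords = np.array(centers)
    pcoords = providers.coords
    dist = np.hypot(
        ccoords[:, None, 0] - pcoords[None, :, 0],
        ccoords[:, None, 1] - pcoords[None, :, 1],
    )
    max_edges = math.floor(travel_cutoff_min / spec.edge_minutes + 1e-12)
    manhattan = (
        np.abs(ccoords[:, None, 0] - pcoords[None, :, 0])
        + np.abs(ccoords[:, None, 1] - pcoords[None, :, 1])
    ) / spec.cell_m
    buffer_ok = (dist <= d0).any(axis=1).all() and (dist <= d0).any(axis=0).all()
    travel_ok = (
        (manhattan <= max_edges + 1e-12).any(axis=1).all()
        and (manhattan <= max_edges + 1e-12).any(axis=0).all()
    )
    if not (buffer_ok and travel_ok):
        raise ConfigurationError(
            f"covering scenario infeasible: thresholds ({buffer_threshold_miles} mi, "
            f"{travel_cutoff_min} min) too small for a {spec.rows}x{spec.cols} grid "
            f"of {spec.cell_km} km cells with {len(pts)} providers"
        )
    return providers, demand, net


def write_fixtures(spec: ScenarioSpec, outdir, covering: bool = False) -> dict:
    """Write the three layers plus a manifest JSON; returns written paths."""
    import os

    from .geodata_io import write_demand_layer, write_provider_layer

    os.makedirs(outdir, exist_ok=True)
    providers, demand, net = (
        make_covering_scenario(spec) if covering else make_scenario(spec)
    )
    paths = {
        "providers": os.path.join(outdir, "providers.geojson"),
        "demand": os.path.join(outdir, "demand.geojson"),
        "network_nodes": os.path.join(outdir, "network_nodes.csv"),
        "network_edges": os.path.join(outdir, "network_edges.csv"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }
    write_provider_layer(providers, paths["providers"])
    write_demand_layer(demand, paths["demand"])
    nodes = pd.DataFrame(
        [{"node_id": n, "x": xy[0], "y": xy[1]} for n, xy in sorted(net.coords.items())]
    )
    edges = pd.DataFrame(
        [
            {"from_node": u, "to_node": v, "travel_time_min": d["travel_time"]}
            for u, v, d in net.graph.edges(data=True)
            if u < v  # undirected grid: write each edge once
        ]
    )
    nodes.to_csv(paths["network_nodes"], index=False)
    edges.to_csv(paths["network_edges"], index=False)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump({"spec": asdict(spec), "covering": covering}, fh, indent=2)
    return paths
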