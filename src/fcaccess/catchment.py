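"""Catchment construction: Euclidean buffers and travel-time isochrones.

A catchment is the region within which supply and demand interact. The
classic model uses one catchment per origin; the enhanced model nests
three zones (rings) weighted by a step distance-decay function. Zones are
half-open: zone 1 covers distances/times in [0, t1], zone r>1 covers
(t_{r-1}, t_r]; a point exactly on a shared boundary belongs to the inner
(higher-weight) zone.

Buffer catchments are polygonal circle approximations (128 segments);
membership tests for buffer mode elsewhere use exact distances, so the
approximation only affects persisted/plotted shapes. Travel-time
catchments are convex hulls of the network nodes reachable within each
cutoff; inner hulls are subsets of outer hulls by construction because
the reachable sets nest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point

from .errors import ConfigurationError, DomainError
from .road_network import TO_ORIGIN, RoadNetwork, bounded_shortest_times, snap_point
from .units import to_meters

logger = logging.getLogger(__name__)

#: quarter-circle segment count for buffer polygons (128-gon circles,
#: disk-area error ~0.04%)
BUFFER_QUAD_SEGS = 32

#: radius (coordinate units) of the degenerate zone drawn around an origin
#: whose reachable set has no area (isolated node / cutoff below all edges)
DEGENERATE_RADIUS = 1e-6

BUFFER_MODE = "buffer"
TRAVEL_MODE = "travel_time"

#: printed tool defaults: classic 15-mile buffer / 30-minute drive;
#: enhanced 5/10/15 miles / 10/20/30 minutes with step-decay weights
DEFAULT_BUFFER_MILES = (15.0,)
DEFAULT_BUFFER_ZONES_MILES = (5.0, 10.0, 15.0)
DEFAULT_TRAVEL_MIN = (30.0,)
DEFAULT_TRAVEL_ZONES_MIN = (10.0, 20.0, 30.0)
DEFAULT_ZONE_WEIGHTS = (1.0, 0.68, 0.22)


@dataclass(frozen=True)
class CatchmentConfig:
    """Catchment parameters: mode, zone edges, units, decay weights.

    ``thresholds`` has length 1 (classic) or 3 (enhanced, strictly
    increasing zone edges). ``weights`` applies to enhanced variants only;
    the first (inner-zone) weight must be the maximum.
    """

    mode: str
    thresholds: tuple
    units: str
    weights: tuple | None = None
    direction: str = TO_ORIGIN

    def __post_init__(self):
        if self.mode not in (BUFFER_MODE, TRAVEL_MODE):
            raise ConfigurationError(f"unknown catchment mode {self.mode!r}")
        thr = tuple(float(t) for t in self.thresholds)
        if len(thr) not in (1, 3):
            raise ConfigurationError("thresholds must list 1 (classic) or 3 (enhanced) values")
        if any(t <= 0 for t in thr) or any(b <= a for a, b in zip(thr, thr[1:])):
            raise ConfigurationError(f"thresholds must be positive and strictly increasing: {thr}")
        if self.mode == TRAVEL_MODE and self.units != "minutes":
            raise ConfigurationError("travel_time mode requires units='minutes'")
        if self.mode == BUFFER_MODE and self.units not in ("miles", "km", "meters"):
            raise ConfigurationError(f"buffer mode requires distance units, got {self.units!r}")
        if self.weights is not None:
            w = tuple(float(x) for x in self.weights)
            if len(w) != 3:
                raise ConfigurationError("zone weights must list exactly 3 values")
            if any(not 0 < x <= 1 for x in w):
                raise ConfigurationError("zone weights must lie in (0, 1]")
            if w[0] != max(w):
                raise ConfigurationError("the inner-zone weight must be the maximum")
            object.__setattr__(self, "weights", w)
        object.__setattr__(self, "thresholds", thr)

    @property
    def enhanced(self) -> bool:
        return len(self.thresholds) == 3

    @property
    def thresholds_internal(self) -> tuple:
        """Thresholds in internal units: meters (buffer) or minutes (travel)."""
        if self.mode == TRAVEL_MODE:
            return self.thresholds
        return tuple(to_meters(t, self.units) for t in self.thresholds)


def default_config(variant: str) -> CatchmentConfig:
    """The published tool defaults for each of the four variants."""
    table = {
        "2sfca_buffer": CatchmentConfig(BUFFER_MODE, DEFAULT_BUFFER_MILES, "miles"),
        "e2sfca_buffer": CatchmentConfig(
            BUFFER_MODE, DEFAULT_BUFFER_ZONES_MILES, "miles", weights=DEFAULT_ZONE_WEIGHTS
        ),
        "2sfca_travel": CatchmentConfig(TRAVEL_MODE, DEFAULT_TRAVEL_MIN, "minutes"),
        "e2sfca_travel": CatchmentConfig(
            TRAVEL_MODE, DEFAULT_TRAVEL_ZONES_MIN, "minutes", weights=DEFAULT_ZONE_WEIGHTS
        ),
    }
    if variant not in table:
        raise ConfigurationError(f"unknown variant {variant!r}; expected one of {sorted(table)}")
    return table[variant]


@dataclass(frozen=True)
class Catchment:
    """Zones for one origin: disjoint rings plus the nested outer regions.

    ``rings[r]`` is zone r+1 (set difference of consecutive outer regions);
    ``outer[r]`` is everything within threshold r+1 and is what membership
    tests use (first covering region wins, honoring the half-open rule).
    """

    origin_id: object
    rings: tuple
    outer: tuple
    cutoffs: tuple
    degenerate: bool = False


@dataclass(frozen=True)
class CatchmentSet:
    """Per-origin ordered zone polygons for a whole layer."""

    mode: str
    cutoffs: tuple
    items: dict = field(default_factory=dict)  # origin_id -> Catchment

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, origin_id) -> Catchment:
        return self.items[origin_id]


def _validate_increasing(values, what: str) -> tuple:
    vals = tuple(float(v) for v in values)
    if not vals or any(v <= 0 for v in vals) or any(b <= a for a, b in zip(vals, vals[1:])):
        raise ConfigurationError(f"{what} must be positive and strictly increasing: {vals}")
    return vals


def _rings_from_outer(outer: list) -> list:
    rings = [outer[0]]
    for inner, out in zip(outer, outer[1:]):
        rings.append(out.difference(inner))
    return rings


def buffer_zones(origin: Point, thresholds) -> list:
    """Disk + annuli around a point: zone 1 = disk(t1), zone r = annulus(t_{r-1}, t_r]."""
    thr = _validate_increasing(thresholds, "buffer thresholds")
    outer = [origin.buffer(t, quad_segs=BUFFER_QUAD_SEGS) for t in thr]
    return _rings_from_outer(outer)


def _hull(coords: np.ndarray):
    geom = shapely.multipoints(coords)
    return geom.convex_hull


def isochrone_zones(
    net: RoadNetwork,
    origin: Point,
    cutoffs,
    direction: str = TO_ORIGIN,
) -> list:
    """Travel-time rings around a point: convex hulls of reachable nodes.

    The origin is snapped to its nearest node; a single bounded Dijkstra
    at the largest cutoff yields every zone (smaller cutoffs filter the
    arrival times). A cutoff reaching no area (isolated node, or cutoff
    below all incident edge times) produces a degenerate buffered-point
    zone with a warning.
    """
    zones, _ = isochrone_catchment(net, origin, cutoffs, direction)
    return list(zones.rings)


def isochrone_catchment(net, origin: Point, cutoffs, direction: str = TO_ORIGIN,
                        origin_id=None):
    """Full Catchment (rings + nested outer hulls) for one origin point."""
    cuts = _validate_increasing(cutoffs, "travel-time cutoffs")
    node = snap_point(net, origin)
    reach = bounded_shortest_times(net, node, cuts[-1], direction=direction)
    coords_all = np.array([net.node_coords(n) for n in reach.reached], dtype=float)
    times_all = np.array(list(reach.reached.values()), dtype=float)
    outer = []
    degenerate = False
    for c in cuts:
        pts = coords_all[times_all <= c]
        hull = _hull(pts)
        if hull.area == 0:  # point or line: no 2-D reach at this cutoff
            degenerate = True
            hull = hull.buffer(DEGENERATE_RADIUS, quad_segs=BUFFER_QUAD_SEGS)
        outer.append(hull)
    # enforce nesting under degenerate fallbacks
    for r in range(1, len(outer)):
        if not outer[r].covers(outer[r - 1]):
            outer[r] = outer[r].union(outer[r - 1])
    if degenerate:
        logger.warning(
            "origin %r: degenerate travel-time zone (reachable set has no area)",
            origin_id if origin_id is not None else node,
        )
    cat = Catchment(
        origin_id if origin_id is not None else node,
        tuple(_rings_from_outer(outer)),
        tuple(outer),
        cuts,
        degenerate=degenerate,
    )
    return cat, reach


def buffer_catchment(origin: Point, thresholds, origin_id=None) -> Catchment:
    """Catchment (rings + nested disks) for one origin point."""
    thr = _validate_increasing(thresholds, "buffer thresholds")
    outer = [origin.buffer(t, quad_segs=BUFFER_QUAD_SEGS) for t in thr]
    return Catchment(origin_id, tuple(_rings_from_outer(outer)), tuple(outer), thr)


def build_catchment_set(
    ids,
    points,
    config: CatchmentConfig,
    net: RoadNetwork | None = None,
    path=None,
) -> CatchmentSet:
    """One zone list per input point, optionally persisted to GeoJSON.

    ``ids`` and ``points`` are parallel sequences (origin identifier,
    shapely Point). Travel-time mode requires a network.
    """
    if config.mode == TRAVEL_MODE and net is None:
        raise ConfigurationError("travel_time catchments require a road network")
    cuts = config.thresholds_internal
    items = {}
    for oid, pt in zip(ids, points):
        if config.mode == BUFFER_MODE:
            items[oid] = buffer_catchment(pt, cuts, origin_id=oid)
        else:
            items[oid], _ = isochrone_catchment(
                net, pt, cuts, direction=config.direction, origin_id=oid
            )
    cs = CatchmentSet(config.mode, cuts, items)
    if path is not None:
        write_catchment_set(cs, path)
    return cs


def write_catchment_set(cs: CatchmentSet, path) -> None:
    """Persist zone rings to GeoJSON with origin_id / zone_rank / cutoff fields."""
    import json

    from shapely.geometry import mapping

    features = []
    for oid, cat in cs.items.items():
        for rank, (ring, cut) in enumerate(zip(cat.rings, cat.cutoffs), start=1):
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(ring),
                    "properties": {"origin_id": oid, "zone_rank": rank, "cutoff": cut},
                }
            )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_catchment_set(path, mode: str = TRAVEL_MODE) -> CatchmentSet:
    """Read zone rings written by :func:`write_catchment_set`.

    Outer regions are rebuilt as cumulative unions of the rings, so
    membership semantics round-trip (up to polygon-coordinate precision).
    """
    import json

    from shapely.geometry import shape
    from shapely.ops import unary_union

    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    per_origin: dict = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        for fld in ("origin_id", "zone_rank", "cutoff"):
            if fld not in props:
                raise ConfigurationError(f"{path}: catchment feature missing {fld!r}")
        per_origin.setdefault(props["origin_id"], []).append(
            (int(props["zone_rank"]), float(props["cutoff"]), shape(feat["geometry"]))
        )
    items = {}
    cuts_ref = None
    for oid, entries in per_origin.items():
        entries.sort()
        rings = [g for _, _, g in entries]
        cuts = tuple(c for _, c, _ in entries)
        outer = []
        acc = None
        for ring in rings:
            acc = ring if acc is None else unary_union([acc, ring])
            outer.append(acc)
        items[oid] = Catchment(oid, tuple(rings), tuple(outer), cuts)
        cuts_ref = cuts
    if cuts_ref is None:
        raise DomainError(f"{path}: empty catchment file")
    return CatchmentSet(mode, cuts_ref, items)
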