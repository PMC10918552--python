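"""Road networks as weighted graphs with bounded shortest-path times.

Replaces a proprietary network dataset / online routing service with a
plain node/edge representation: nodes carry planar coordinates, edges a
positive travel time in minutes. Travel times are static per edge; mode
(driving, walking) is expressed only through the user's edge weights.

Shortest-path work is delegated to networkx Dijkstra with a cutoff;
``to_origin`` queries run on the transposed graph, which matters on
directed (one-way) networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point

from .errors import DomainError, ValidationError

FROM_ORIGIN = "from_origin"
TO_ORIGIN = "to_origin"
DIRECTIONS = (FROM_ORIGIN, TO_ORIGIN)


@dataclass
class RoadNetwork:
    """Weighted road graph; internally always a DiGraph (undirected input
    edges become arc pairs)."""

    graph: nx.DiGraph
    coords: dict  # node_id -> (x, y)
    directed: bool = False
    _kdtree: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        for u, v, data in self.graph.edges(data=True):
            t = data.get("travel_time")
            if t is None or not np.isfinite(t) or t <= 0:
                raise ValidationError(f"edge ({u!r}, {v!r}) has non-positive travel time")
        missing = [n for n in self.graph.nodes if n not in self.coords]
        if missing:
            raise ValidationError(f"nodes without coordinates: {missing[:5]}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Undirected edge count when the network is undirected."""
        m = self.graph.number_of_edges()
        return m // 2 if not self.directed else m

    def node_coords(self, node_id) -> tuple:
        return self.coords[node_id]

    def _tree(self):
        if self._kdtree is None:
            ids = sorted(self.coords, key=lambda n: (str(type(n)), n))
            pts = np.array([self.coords[n] for n in ids], dtype=float)
            self._kdtree = (ids, pts, cKDTree(pts))
        return self._kdtree


@dataclass(frozen=True)
class ReachableSet:
    """Nodes reachable from (or into) an origin within a time cutoff."""

    origin: object
    cutoff: float
    reached: dict  # node_id -> arrival time <= cutoff

    def __post_init__(self):
        if self.reached.get(self.origin, None) != 0:
            raise ValidationError("origin must be reached at time 0")
        if any(t > self.cutoff for t in self.reached.values()):
            raise ValidationError("reached time exceeds cutoff")

    def __len__(self) -> int:
        return len(self.reached)


def build_network(nodes: pd.DataFrame, edges: pd.DataFrame, directed: bool = False) -> RoadNetwork:
    """Assemble a validated RoadNetwork from node and edge tables.

    ``nodes`` needs columns ``node_id, x, y``; ``edges`` needs
    ``from_node, to_node, travel_time_min``.
    """
    for col in ("node_id", "x", "y"):
        if col not in nodes.columns:
            raise ValidationError(f"nodes table missing column {col!r}")
    for col in ("from_node", "to_node", "travel_time_min"):
        if col not in edges.columns:
            raise ValidationError(f"edges table missing column {col!r}")
    if nodes["node_id"].duplicated().any():
        dupes = nodes.loc[nodes["node_id"].duplicated(), "node_id"].tolist()
        raise ValidationError(f"duplicate node ids: {dupes}")
    coords = {
        row.node_id: (float(row.x), float(row.y)) for row in nodes.itertuples(index=False)
    }
    g = nx.DiGraph()
    g.add_nodes_from(coords)
    for row in edges.itertuples(index=False):
        u, v, t = row.from_node, row.to_node, float(row.travel_time_min)
        if u not in coords or v not in coords:
            raise ValidationError(f"edge ({u!r}, {v!r}) references an unknown node")
        if not np.isfinite(t) or t <= 0:
            raise ValidationError(f"edge ({u!r}, {v!r}) has non-positive travel time {t}")
        g.add_edge(u, v, travel_time=t)
        if not directed:
            g.add_edge(v, u, travel_time=t)
    return RoadNetwork(g, coords, directed=directed)


def load_network(nodes_path, edges_path, directed: bool = False) -> RoadNetwork:
    """Load a network from ``node_id,x,y`` and ``from_node,to_node,travel_time_min`` CSVs."""
    return build_network(pd.read_csv(nodes_path), pd.read_csv(edges_path), directed=directed)


def load_network_geojson(path, snap_tolerance: float = 1e-6, directed: bool = False) -> RoadNetwork:
    """Load a network from GeoJSON LineStrings with a ``travel_time_min`` property.

    Endpoints within ``snap_tolerance`` of each other are merged into one
    node (coordinates quantized to the tolerance grid); multi-vertex lines
    contribute a single edge between their endpoints.
    """
    import json

    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    node_ids: dict[tuple, int] = {}
    coords: dict[int, tuple] = {}
    nodes_rows, edges_rows = [], []

    def node_for(xy):
        key = (round(xy[0] / snap_tolerance), round(xy[1] / snap_tolerance))
        if key not in node_ids:
            nid = len(node_ids)
            node_ids[key] = nid
            coords[nid] = (float(xy[0]), float(xy[1]))
            nodes_rows.append({"node_id": nid, "x": xy[0], "y": xy[1]})
        return node_ids[key]

    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise ValidationError(f"{path}: expected LineString features")
        props = feat.get("properties") or {}
        if "travel_time_min" not in props:
            raise ValidationError(f"{path}: feature missing 'travel_time_min'")
        pts = geom["coordinates"]
        u, v = node_for(pts[0]), node_for(pts[-1])
        edges_rows.append(
            {"from_node": u, "to_node": v, "travel_time_min": float(props["travel_time_min"])}
        )
    return build_network(pd.DataFrame(nodes_rows), pd.DataFrame(edges_rows), directed=directed)


def snap_point(net: RoadNetwork, p: Point) -> object:
    """Nearest network node to ``p`` by planar distance.

    Exact ties are broken by the smallest node id, so snapping is
    deterministic regardless of node insertion order.
    """
    if net.n_nodes == 0:
        raise DomainError("cannot snap to an empty network")
    ids, pts, tree = net._tree()
    xy = np.array([p.x, p.y], dtype=float)
    d, _ = tree.query(xy)
    # gather every node achieving the minimum distance (within fp slack),
    # then re-check exactly and take the smallest id
    cand = tree.query_ball_point(xy, d + 1e-9 * max(1.0, d))
    dists = np.hypot(pts[cand, 0] - xy[0], pts[cand, 1] - xy[1])
    dmin = dists.min()
    best = [ids[cand[i]] for i in range(len(cand)) if dists[i] == dmin]
    return min(best)


def bounded_shortest_times(
    net: RoadNetwork, origin, cutoff: float, direction: str = FROM_ORIGIN
) -> ReachableSet:
    """Exact single-source shortest-path times truncated at ``cutoff``.

    ``from_origin`` expands outward along arcs; ``to_origin`` answers
    "from which nodes can the origin be reached within the cutoff" by
    running on the transposed graph. On undirected networks the two
    coincide.
    """
    if origin not in net.graph:
        raise DomainError(f"origin node {origin!r} not in network")
    if direction not in DIRECTIONS:
        raise DomainError(f"direction must be one of {DIRECTIONS}")
    if cutoff <= 0:
        raise DomainError("cutoff must be positive")
    g = net.graph if direction == FROM_ORIGIN else net.graph.reverse(copy=False)
    times = nx.single_source_dijkstra_path_length(
        g, origin, cutoff=cutoff, weight="travel_time"
    )
    return ReachableSet(origin, float(cutoff), dict(times))
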