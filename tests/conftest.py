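import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from fcaccess.geodata_io import DemandLayer, ProviderLayer
from fcaccess.road_network import build_network


def grid_network(rows=5, cols=5, spacing=1.0, minutes=1.0, directed=False):
    """rows x cols lattice with uniform edge travel times; node ids row-major."""
    nodes = [
        {"node_id": r * cols + c, "x": c * spacing, "y": r * spacing}
        for r in range(rows)
        for c in range(cols)
    ]
    edges = []
    for r in range(rows):
        for c in range(cols):
            n = r * cols + c
            if c + 1 < cols:
                edges.append({"from_node": n, "to_node": n + 1, "travel_time_min": minutes})
            if r + 1 < rows:
                edges.append({"from_node": n, "to_node": n + cols, "travel_time_min": minutes})
    return build_network(pd.DataFrame(nodes), pd.DataFrame(edges), directed=directed)


def point_layers(prov_xy, caps, dem_xy, pops, half=0.1):
    """Provider/demand layers from coordinate arrays; each demand polygon is
    a small square centered on its representative point."""
    prov_xy = np.asarray(prov_xy, dtype=float)
    dem_xy = np.asarray(dem_xy, dtype=float)
    providers = ProviderLayer(
        tuple(f"p{j}" for j in range(len(caps))),
        np.asarray(caps, dtype=float),
        tuple(Point(x, y) for x, y in prov_xy),
    )
    polys, reps = [], []
    for x, y in dem_xy:
        polys.append(Polygon([(x - half, y - half), (x + half, y - half),
                              (x + half, y + half), (x - half, y + half)]))
        reps.append(Point(x, y))
    demand = DemandLayer(
        tuple(f"d{i}" for i in range(len(pops))),
        np.asarray(pops, dtype=float),
        tuple(polys),
        rep_point=tuple(reps),
    )
    return providers, demand


@pytest.fixture
def unit_grid():
    """5x5 unit-spacing grid, 1 minute per edge."""
    return grid_network(5, 5, 1.0, 1.0)
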