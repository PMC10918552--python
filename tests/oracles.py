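"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (pure-Python double loops,
Bellman-Ford relaxation, exhaustive partition search) and shares no code
with the implementation under test.
"""

import math
from itertools import combinations


def _dist(a, b):
    return math.sqrt((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2)


def _zone(d, thresholds):
    for r, t in enumerate(thresholds):
        if d <= t:
            return r + 1
    return 0


def brute_force_fca(prov_xy, caps, dem_xy, pops, thresholds, weights=None):
    """Double-loop 2SFCA / E2SFCA: returns (R per provider, A per demand,
    per-zone components per demand or None)."""
    n_p, n_d = len(caps), len(pops)
    ratios = []
    for j in range(n_p):
        terms = []
        for k in range(n_d):
            z = _zone(_dist(prov_xy[j], dem_xy[k]), thresholds)
            if z:
                terms.append((weights[z - 1] if weights else 1.0) * pops[k])
        tot = math.fsum(terms)
        ratios.append(caps[j] / tot if tot > 0 else 0.0)
    access, comps = [], []
    for i in range(n_d):
        zones = [_zone(_dist(prov_xy[j], dem_xy[i]), thresholds) for j in range(n_p)]
        if weights:
            per = [
                weights[r] * math.fsum(ratios[j] for j in range(n_p) if zones[j] == r + 1)
                for r in range(3)
            ]
            comps.append(per)
            access.append(math.fsum(per))
        else:
            access.append(math.fsum(ratios[j] for j in range(n_p) if zones[j] >= 1))
    return ratios, access, (comps if weights else None)


def bellman_ford_times(nodes, arcs, origin, cutoff):
    """All-pairs-free single-source shortest times by repeated relaxation,
    truncated at the cutoff. ``arcs`` are (u, v, weight) triples."""
    dist = {origin: 0.0}
    for _ in range(len(nodes) - 1):
        changed = False
        for u, v, w in arcs:
            if u in dist:
                cand = dist[u] + w
                if cand < dist.get(v, math.inf):
                    dist[v] = cand
                    changed = True
        if not changed:
            break
    return {n: d for n, d in dist.items() if d <= cutoff}


def exhaustive_jenks_objective(values, k):
    """Minimal within-class SSE over every ordered partition of the sorted
    values into k non-empty contiguous classes."""
    sv = sorted(values)
    n = len(sv)

    def sse(chunk):
        m = math.fsum(chunk) / len(chunk)
        return math.fsum((x - m) ** 2 for x in chunk)

    best = math.inf
    for cuts in combinations(range(1, n), k - 1):
        edges = (0, *cuts, n)
        total = math.fsum(sse(sv[a:b]) for a, b in zip(edges, edges[1:]))
        best = min(best, total)
    return best
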