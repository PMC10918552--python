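"""Natural-breaks (Jenks) classification and score summaries.

The classifier is the exact O(k n^2) dynamic program minimizing total
within-class sum of squared deviations over ordered partitions of the
sorted values — deterministic, and provably optimal (unlike the common
Fisher/Jenks heuristics), which keeps it checkable against an exhaustive
partition search at small n. Intended scale is choropleth-sized inputs
(thousands of demand units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .geodata_io import AccessibilityResult, DemandLayer


@dataclass(frozen=True)
class Classification:
    """k classes over 1-D values: ascending break (upper-edge) values,
    per-value class labels, and the achieved within-class SSE."""

    k: int
    breaks: np.ndarray  # k upper class edges, last = max(values)
    labels: np.ndarray  # class index (0-based) per input value
    objective: float

    def __post_init__(self):
        b = np.asarray(self.breaks, dtype=float)
        if (np.diff(b) <= 0).any():
            raise DomainError("class breaks must be strictly ascending")


def jenks_breaks(values, k: int) -> Classification:
    """Optimal natural-breaks classification of ``values`` into ``k`` classes.

    Breaks are the upper edge of each class; a value belongs to the first
    class whose break is >= the value (half-open intervals). Requires at
    least ``k`` distinct values. The dynamic program runs over distinct
    values with multiplicities (tied values are never split across
    classes — an optimum of this form always exists for squared-error
    loss), so breaks are strictly ascending and the result deterministic:
    exact ties in the objective resolve toward the smallest split indices.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise DomainError("values must be a non-empty 1-D array")
    if not np.isfinite(v).all():
        raise DomainError("values must be finite")
    if k < 2:
        raise DomainError("number of classes must be at least 2")
    u, counts = np.unique(v, return_counts=True)
    m_distinct = u.size
    if m_distinct < k:
        raise DomainError(f"cannot form {k} classes from {m_distinct} distinct value(s)")
    # weighted prefix sums over distinct values
    cw = np.concatenate([[0.0], np.cumsum(counts)])
    s = np.concatenate([[0.0], np.cumsum(counts * u)])
    s2 = np.concatenate([[0.0], np.cumsum(counts * u**2)])

    def sse(i: int, j: int) -> float:  # distinct values u[i..j] inclusive
        n = cw[j + 1] - cw[i]
        tot = s[j + 1] - s[i]
        return max((s2[j + 1] - s2[i]) - tot * tot / n, 0.0)

    # dp[m][i]: minimal SSE for u[0..i] in m+1 classes
    dp = np.full((k, m_distinct), np.inf)
    cut = np.zeros((k, m_distinct), dtype=int)  # first distinct index of the last class
    for i in range(m_distinct):
        dp[0, i] = sse(0, i)
    for m in range(1, k):
        for i in range(m, m_distinct):
            best, best_j = np.inf, m
            for j in range(m, i + 1):
                cand = dp[m - 1, j - 1] + sse(j, i)
                if cand < best:
                    best, best_j = cand, j
            dp[m, i] = best
            cut[m, i] = best_j
    edges = []
    i = m_distinct - 1
    for m in range(k - 1, 0, -1):
        j = cut[m, i]
        edges.append(u[j - 1])  # upper edge of the class ending before the cut
        i = j - 1
    edges.reverse()
    breaks = np.array(edges + [u[-1]], dtype=float)
    labels = np.searchsorted(breaks, v, side="left")
    return Classification(k, breaks, labels, float(dp[k - 1, m_distinct - 1]))


def summarize(result: AccessibilityResult, demand: DemandLayer) -> pd.Series:
    """Distribution summary of the accessibility scores.

    Uses the per-capita ``scaled_index`` when present (the reporting
    scale), else the raw ``final_index``; adds the count and share of
    zero-access demand units and the population-weighted mean.
    """
    if len(result) == 0:
        raise DomainError("cannot summarize an empty result")
    scores = result.scaled_index if result.scaled_index is not None else result.final_index
    order = {did: i for i, did in enumerate(result.demand_id)}
    pop = np.array([demand.population[i] for i, did in enumerate(demand.demand_id)])
    aligned = np.array([scores[order[did]] for did in demand.demand_id])
    zero = aligned == 0
    wmean = float(np.average(aligned, weights=pop)) if pop.sum() > 0 else float("nan")
    return pd.Series(
        {
            "n": len(aligned),
            "min": float(aligned.min()),
            "q25": float(np.quantile(aligned, 0.25)),
            "median": float(np.median(aligned)),
            "mean": float(aligned.mean()),
            "q75": float(np.quantile(aligned, 0.75)),
            "max": float(aligned.max()),
            "population_weighted_mean": wmean,
            "zero_access_count": int(zero.sum()),
            "zero_access_share": float(zero.mean()),
        }
    )


def plot_choropleth(demand: DemandLayer, result: AccessibilityResult, path,
                    k: int = 5, cmap: str = "YlOrRd") -> None:
    """Convenience choropleth of the scores with natural-breaks classes.

    Zero-access units are drawn white; not part of the tested contract.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    scores = result.scaled_index if result.scaled_index is not None else result.final_index
    order = {did: i for i, did in enumerate(result.demand_id)}
    aligned = np.array([scores[order[did]] for did in demand.demand_id])
    positive = aligned[aligned > 0]
    classes = None
    if np.unique(positive).size >= k:
        classes = jenks_breaks(positive, k)
    colors = plt.get_cmap(cmap)
    fig, ax = plt.subplots(figsize=(8, 6))
    for i, geom in enumerate(demand.geometry):
        val = aligned[i]
        if val == 0:
            fc = "white"
        elif classes is not None:
            cls = int(np.searchsorted(classes.breaks, val, side="left"))
            fc = colors((cls + 0.5) / k)
        else:
            fc = colors(0.5)
        polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
        for poly in polys:
            ax.add_patch(MplPolygon(np.asarray(poly.exterior.coords), facecolor=fc,
                                    edgecolor="0.6", linewidth=0.3))
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
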