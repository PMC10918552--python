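"""Two-step floating catchment area scores, classic and enhanced.

Classic 2SFCA:
  step 1   R_j = S_j / sum_{k: d_kj <= d0} P_k
  step 2   A_i = sum_{j: d_ij <= d0} R_j

Enhanced (E2SFCA) splits the catchment into three nested zones D_r with
step-decay weights W_r (default 1 / 0.68 / 0.22):
  step 1   R_j = S_j / sum_r W_r * sum_{k: d_kj in D_r} P_k
  step 2   A_i = sum_r W_r * sum_{j: d_ij in D_r} R_j

Membership is pluggable: a distance-band oracle (exact point-to-point
Euclidean distances against the thresholds) serves the buffer variants,
a polygon oracle (point-in-isochrone tests against a CatchmentSet)
serves the travel-time variants. Zone intervals are half-open with the
boundary belonging to the inner zone.

All reductions go through math.fsum, so scores are correctly rounded
sums independent of summation order — results are bit-reproducible and
directly comparable with a naive double-loop reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial.distance import cdist

from .catchment import (
    BUFFER_MODE,
    TRAVEL_MODE,
    CatchmentConfig,
    CatchmentSet,
    build_catchment_set,
    default_config,
)
from .errors import ConfigurationError
from .geodata_io import AccessibilityResult, DemandLayer, ProviderLayer
from .road_network import FROM_ORIGIN, TO_ORIGIN, RoadNetwork

logger = logging.getLogger(__name__)

VARIANTS = ("2sfca_buffer", "e2sfca_buffer", "2sfca_travel", "e2sfca_travel")

DEFAULT_PER_CAPITA = 100_000.0


@dataclass(frozen=True)
class ProviderRatio:
    """Step-1 output: provider-to-demand ratio R_j per provider, with the
    (weighted) demand total inside each provider's catchment."""

    provider_id: tuple
    ratio: np.ndarray
    catchment_demand: np.ndarray

    def __post_init__(self):
        if (np.asarray(self.ratio) < 0).any():
            raise ConfigurationError("provider ratios must be non-negative")


class DistanceBandMembership:
    """Zone membership from exact pairwise Euclidean distances.

    ``zone(j, k)`` is 0 outside the outermost threshold, else 1-based index
    of the zone whose half-open interval contains d_jk. The same distance
    matrix serves both steps (symmetric membership).
    """

    def __init__(self, providers: ProviderLayer, demand: DemandLayer, thresholds):
        self.thresholds = np.asarray(sorted(thresholds), dtype=float)
        d = cdist(providers.coords, demand.coords)
        pos = np.searchsorted(self.thresholds, d, side="left")
        self._zones = np.where(pos < len(self.thresholds), pos + 1, 0).astype(np.int8)

    def step1_zones(self) -> np.ndarray:
        """(n_providers, n_demand) zone indices: demand inside provider catchments."""
        return self._zones

    def step2_zones(self) -> np.ndarray:
        """(n_demand, n_providers) zone indices: providers inside demand catchments."""
        return self._zones.T


class PolygonMembership:
    """Zone membership by point-in-polygon tests against catchment sets.

    Step 1 asks whether each demand representative point lies in each
    provider's travel-time polygons; step 2 whether each provider point
    lies in each demand unit's polygons. The zone index is the rank of the
    first (innermost) nested region covering the point, which realizes the
    half-open boundary rule. On directed networks the two matrices need
    not be transposes of each other; the asymmetry is logged.
    """

    def __init__(
        self,
        providers: ProviderLayer,
        demand: DemandLayer,
        provider_catchments: CatchmentSet,
        demand_catchments: CatchmentSet,
    ):
        self._z1 = self._zone_matrix(
            provider_catchments, providers.provider_id, shapely.points(demand.coords)
        )
        self._z2 = self._zone_matrix(
            demand_catchments, demand.demand_id, shapely.points(providers.coords)
        )
        if not np.array_equal(self._z1, self._z2.T):
            logger.info(
                "asymmetric travel-time membership (%d of %d pairs differ between steps)",
                int((self._z1 != self._z2.T).sum()), self._z1.size,
            )

    @staticmethod
    def _zone_matrix(catchments: CatchmentSet, origin_ids, points) -> np.ndarray:
        zones = np.zeros((len(origin_ids), len(points)), dtype=np.int8)
        for row, oid in enumerate(origin_ids):
            cat = catchments[oid]
            assigned = np.zeros(len(points), dtype=bool)
            for rank, region in enumerate(cat.outer, start=1):
                inside = shapely.covers(region, points) & ~assigned
                zones[row, inside] = rank
                assigned |= inside
        return zones

    def step1_zones(self) -> np.ndarray:
        return self._z1

    def step2_zones(self) -> np.ndarray:
        return self._z2


def _check_layers(providers: ProviderLayer, demand: DemandLayer) -> None:
    if providers.crs != demand.crs:
        raise ConfigurationError(
            f"provider CRS {providers.crs!r} differs from demand CRS {demand.crs!r}"
        )


def _weighted_demand(zones_row: np.ndarray, pop: np.ndarray, weights) -> float:
    """Correctly rounded sum of W_zone * P_k over in-catchment demand."""
    terms = [
        weights[z - 1] * pop[k] if weights is not None else pop[k]
        for k, z in enumerate(zones_row)
        if z > 0
    ]
    return math.fsum(terms)


def classic_step1(
    providers: ProviderLayer, demand: DemandLayer, member
) -> ProviderRatio:
    """R_j = S_j / total population within provider j's catchment.

    Providers whose catchment holds no demand get R_j = 0 and are logged.
    """
    _check_layers(providers, demand)
    zones = member.step1_zones()
    totals = np.array(
        [_weighted_demand(zones[j], demand.population, None) for j in range(len(providers))]
    )
    return _ratios_from_totals(providers, totals)


def enhanced_step1(
    providers: ProviderLayer, demand: DemandLayer, member, weights
) -> ProviderRatio:
    """R_j = S_j / sum_r W_r * (population in zone r of provider j)."""
    _check_layers(providers, demand)
    w = tuple(float(x) for x in weights)
    if len(w) != 3:
        raise ConfigurationError("enhanced step 1 needs exactly 3 zone weights")
    zones = member.step1_zones()
    totals = np.array(
        [_weighted_demand(zones[j], demand.population, w) for j in range(len(providers))]
    )
    return _ratios_from_totals(providers, totals)


def _ratios_from_totals(providers: ProviderLayer, totals: np.ndarray) -> ProviderRatio:
    ratio = np.zeros(len(providers))
    nonzero = totals > 0
    ratio[nonzero] = providers.capacity[nonzero] / totals[nonzero]
    empty = [pid for pid, nz in zip(providers.provider_id, nonzero) if not nz]
    if empty:
        logger.warning(
            "%d provider(s) with zero catchment demand get R_j = 0: %s",
            len(empty), empty,
        )
    return ProviderRatio(tuple(providers.provider_id), ratio, totals)


def classic_step2(
    ratios: ProviderRatio,
    demand: DemandLayer,
    providers: ProviderLayer,
    member,
) -> AccessibilityResult:
    """A_i = sum of R_j over providers within demand i's catchment."""
    zones = member.step2_zones()
    final = np.array(
        [
            math.fsum(ratios.ratio[j] for j in range(len(providers)) if zones[i, j] > 0)
            for i in range(len(demand))
        ]
    )
    diags = {"unreachable_demand": int((final == 0).sum()),
             "zero_demand_providers": int((ratios.catchment_demand == 0).sum())}
    return AccessibilityResult(tuple(demand.demand_id), final, diagnostics=diags)


def enhanced_step2(
    ratios: ProviderRatio,
    demand: DemandLayer,
    providers: ProviderLayer,
    member,
    weights,
) -> AccessibilityResult:
    """A_i = sum_r W_r * (sum of R_j over providers in zone r of demand i),
    with each zone's contribution recorded separately."""
    w = tuple(float(x) for x in weights)
    if len(w) != 3:
        raise ConfigurationError("enhanced step 2 needs exactly 3 zone weights")
    zones = member.step2_zones()
    n = len(demand)
    comps = np.zeros((n, 3))
    for i in range(n):
        for r in range(3):
            comps[i, r] = w[r] * math.fsum(
                ratios.ratio[j] for j in range(len(providers)) if zones[i, j] == r + 1
            )
    final = np.array([math.fsum(comps[i]) for i in range(n)])
    diags = {"unreachable_demand": int((final == 0).sum()),
             "zero_demand_providers": int((ratios.catchment_demand == 0).sum())}
    return AccessibilityResult(
        tuple(demand.demand_id), final, zone_components=comps, diagnostics=diags
    )


def per_capita_scale(result: AccessibilityResult, multiplier: float) -> AccessibilityResult:
    """Scaled index = final index x multiplier (e.g. 100,000 for
    providers-per-100,000-people reporting); the final index is unchanged."""
    if not multiplier > 0:
        raise ConfigurationError(f"per-capita multiplier must be positive, got {multiplier}")
    return AccessibilityResult(
        result.demand_id,
        result.final_index,
        zone_components=result.zone_components,
        scaled_index=result.final_index * float(multiplier),
        per_capita=float(multiplier),
        diagnostics=dict(result.diagnostics),
    )


def build_membership(
    variant: str,
    providers: ProviderLayer,
    demand: DemandLayer,
    config: CatchmentConfig,
    net: RoadNetwork | None = None,
    provider_catchments: CatchmentSet | None = None,
    demand_catchments: CatchmentSet | None = None,
):
    """Membership oracle appropriate to the variant.

    Buffer variants use exact distance bands. Travel variants test points
    against isochrone polygons, building them from the network when
    prebuilt catchment sets are not supplied (providers with the
    configured direction, demand with the opposite one — patients travel
    toward facilities).
    """
    if config.mode == BUFFER_MODE:
        return DistanceBandMembership(providers, demand, config.thresholds_internal)
    if provider_catchments is None or demand_catchments is None:
        if net is None:
            raise ConfigurationError(
                "travel-time variants need a road network or prebuilt catchment sets"
            )
        opposite = FROM_ORIGIN if config.direction == TO_ORIGIN else TO_ORIGIN
        if provider_catchments is None:
            provider_catchments = build_catchment_set(
                providers.provider_id, providers.geometry, config, net=net
            )
        if demand_catchments is None:
            demand_config = CatchmentConfig(
                config.mode, config.thresholds, config.units,
                weights=config.weights, direction=opposite,
            )
            demand_catchments = build_catchment_set(
                demand.demand_id, demand.rep_point, demand_config, net=net
            )
    return PolygonMembership(providers, demand, provider_catchments, demand_catchments)


def run_model(
    variant: str,
    providers: ProviderLayer,
    demand: DemandLayer,
    config: CatchmentConfig | None = None,
    net: RoadNetwork | None = None,
    provider_catchments: CatchmentSet | None = None,
    demand_catchments: CatchmentSet | None = None,
    per_capita: float = DEFAULT_PER_CAPITA,
) -> AccessibilityResult:
    """Run one of the four accessibility tools end to end.

    Variants: ``2sfca_buffer``, ``e2sfca_buffer``, ``2sfca_travel``,
    ``e2sfca_travel``. ``config`` defaults to the published tool defaults
    for the variant. The result carries diagnostics (counts of providers
    with empty catchments and of demand units reaching no provider) and a
    per-capita ``scaled_index``.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if config is None:
        config = default_config(variant)
    enhanced = variant.startswith("e2sfca")
    if enhanced and not config.enhanced:
        raise ConfigurationError("enhanced variants need 3 thresholds")
    if not enhanced and config.enhanced:
        raise ConfigurationError("classic variants need a single threshold")
    wants_travel = variant.endswith("travel")
    if wants_travel != (config.mode == TRAVEL_MODE):
        raise ConfigurationError(
            f"variant {variant!r} is inconsistent with catchment mode {config.mode!r}"
        )
    member = build_membership(
        variant, providers, demand, config,
        net=net,
        provider_catchments=provider_catchments,
        demand_catchments=demand_catchments,
    )
    if enhanced:
        weights = config.weights or (1.0, 0.68, 0.22)
        ratios = enhanced_step1(providers, demand, member, weights)
        result = enhanced_step2(ratios, demand, providers, member, weights)
    else:
        ratios = classic_step1(providers, demand, member)
        result = classic_step2(ratios, demand, providers, member)
    logger.info(
        "%s: %d providers, %d demand units, %d zero-demand providers, %d unreachable demand units",
        variant, len(providers), len(demand),
        result.diagnostics.get("zero_demand_providers", 0),
        result.diagnostics.get("unreachable_demand", 0),
    )
    return per_capita_scale(result, per_capita)
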