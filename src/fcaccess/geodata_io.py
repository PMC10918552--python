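"""Read, validate and write the vector layers the accessibility tools consume.

Vector dialect is GeoJSON (FeatureCollection); tabular inputs are CSV.
Layers are immutable in-memory containers built on shapely geometries and
numpy arrays. Coordinates must come from a projected CRS with linear
units: known geographic descriptors (WGS84 lat/lon and friends) are
refused rather than silently producing degree "distances".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import ConfigurationError, CRSError, IntegrityError, ValidationError

logger = logging.getLogger(__name__)

#: descriptor substrings that identify a geographic (angular-unit) CRS
_GEOGRAPHIC_TOKENS = ("epsg:4326", "epsg:4269", "crs84", "wgs84", "wgs 84")

#: descriptor used when a file declares no CRS; treated as an unnamed
#: planar (projected) system in meters
LOCAL_PLANAR = "local-planar"


def _is_geographic(crs: str) -> bool:
    low = crs.lower()
    return any(tok in low for tok in _GEOGRAPHIC_TOKENS)


def _check_projected(crs: str) -> None:
    if _is_geographic(crs):
        raise CRSError(
            f"layer CRS {crs!r} is geographic (lat/lon); reproject to a "
            "projected CRS with linear units before computing distances"
        )


def _read_feature_collection(path) -> tuple[list[dict], str]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    crs = LOCAL_PLANAR
    if isinstance(doc.get("crs"), dict):  # legacy named-CRS member
        crs = str(doc["crs"].get("properties", {}).get("name", LOCAL_PLANAR))
    return doc.get("features", []), crs


def _write_feature_collection(path, features: list[dict], crs: str) -> None:
    doc = {"type": "FeatureCollection", "features": features}
    if crs != LOCAL_PLANAR:
        doc["crs"] = {"type": "name", "properties": {"name": crs}}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def _require_field(props: dict, name: str, path) -> None:
    if name not in props:
        raise ConfigurationError(f"{path}: required field {name!r} not present")


def representative_point(polygon: BaseGeometry) -> shapely.Point:
    """Single demand point for a polygon: its centroid when the centroid
    falls inside, otherwise a guaranteed-interior point."""
    c = polygon.centroid
    if polygon.covers(c):
        return c
    return polygon.representative_point()


# ---------------------------------------------------------------------------
# layers


@dataclass(frozen=True)
class ProviderLayer:
    """Point layer of service providers with a capacity S_j per record."""

    provider_id: tuple
    capacity: np.ndarray
    geometry: tuple  # shapely Points
    crs: str = LOCAL_PLANAR

    def __post_init__(self):
        ids = list(self.provider_id)
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1}, key=str)
            raise ValidationError(f"duplicate provider ids: {dupes}")
        cap = np.asarray(self.capacity, dtype=float)
        if cap.shape != (len(ids),) or len(self.geometry) != len(ids):
            raise ValidationError("provider fields have inconsistent lengths")
        bad = [i for i, c in zip(ids, cap) if not np.isfinite(c) or c < 0]
        if bad:
            raise ValidationError(f"missing/negative capacity for providers: {bad}")
        for g in self.geometry:
            if not isinstance(g, shapely.Point):
                raise ValidationError("provider geometries must be points")
        _check_projected(self.crs)
        object.__setattr__(self, "capacity", cap)

    def __len__(self) -> int:
        return len(self.provider_id)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of provider coordinates."""
        return np.array([(p.x, p.y) for p in self.geometry], dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class DemandLayer:
    """Polygon layer of demand units with a population P_i per record.

    ``rep_point`` is the single point standing in for the whole polygon in
    all distance and membership computations. ``age_counts`` optionally
    holds per-age-group counts N_g (one array per group label);
    ``attributes`` keeps every original property for lossless output.
    """

    demand_id: tuple
    population: np.ndarray
    geometry: tuple  # shapely Polygons / MultiPolygons
    rep_point: tuple = None
    age_counts: dict | None = None
    attributes: pd.DataFrame | None = None
    crs: str = LOCAL_PLANAR

    def __post_init__(self):
        ids = list(self.demand_id)
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1}, key=str)
            raise ValidationError(f"duplicate demand ids: {dupes}")
        pop = np.asarray(self.population, dtype=float)
        bad = [i for i, p in zip(ids, pop) if not np.isfinite(p) or p < 0]
        if bad:
            raise ValidationError(f"missing/negative population for demand units: {bad}")
        for g in self.geometry:
            if not isinstance(g, (shapely.Polygon, shapely.MultiPolygon)):
                raise ValidationError(
                    f"demand geometries must be polygons, got {g.geom_type}"
                )
        if self.rep_point is None:
            object.__setattr__(
                self, "rep_point", tuple(representative_point(g) for g in self.geometry)
            )
        if self.age_counts is not None:
            for grp, counts in self.age_counts.items():
                arr = np.asarray(counts, dtype=float)
                if arr.shape != (len(ids),) or (arr < 0).any():
                    raise ValidationError(f"invalid age counts for group {grp!r}")
                self.age_counts[grp] = arr
        _check_projected(self.crs)
        object.__setattr__(self, "population", pop)

    def __len__(self) -> int:
        return len(self.demand_id)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of representative-point coordinates."""
        return np.array([(p.x, p.y) for p in self.rep_point], dtype=float).reshape(-1, 2)

    def with_population(self, population: np.ndarray) -> "DemandLayer":
        """Copy of the layer with the population field replaced."""
        return replace(self, population=np.asarray(population, dtype=float))


@dataclass(frozen=True)
class AccessibilityResult:
    """Per-demand accessibility index A_i plus optional per-zone parts.

    ``final_index`` is the raw two-step score; ``zone_components`` (enhanced
    variants) holds each decay zone's contribution, summing to the final
    index; ``scaled_index`` is final_index times the per-capita multiplier.
    """

    demand_id: tuple
    final_index: np.ndarray
    zone_components: np.ndarray | None = None  # (n, 3)
    scaled_index: np.ndarray | None = None
    per_capita: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        idx = np.asarray(self.final_index, dtype=float)
        if (idx < 0).any():
            raise ValidationError("accessibility index must be non-negative")
        if self.zone_components is not None:
            zc = np.asarray(self.zone_components, dtype=float)
            if not np.allclose(zc.sum(axis=1), idx, rtol=1e-9, atol=1e-12):
                raise ValidationError("zone components must sum to the final index")
            object.__setattr__(self, "zone_components", zc)
        object.__setattr__(self, "final_index", idx)

    def __len__(self) -> int:
        return len(self.demand_id)


# ---------------------------------------------------------------------------
# readers / writers


def read_provider_layer(
    path,
    id_field: str = "id",
    capacity_field: str = "capacity",
    crs: str | None = None,
    strict: bool = True,
) -> ProviderLayer:
    """Read a provider point layer from GeoJSON.

    With ``strict=True`` (default) records with missing or negative capacity
    raise a :class:`ValidationError` listing the offending ids; with
    ``strict=False`` they are dropped and reported through the logger, so
    accepted + rejected always equals the input count.
    """
    features, file_crs = _read_feature_collection(path)
    layer_crs = crs or file_crs
    ids, caps, geoms, rejected = [], [], [], []
    for feat in features:
        props = feat.get("properties") or {}
        _require_field(props, id_field, path)
        _require_field(props, capacity_field, path)
        geom = shape(feat["geometry"])
        cap = props[capacity_field]
        ok = isinstance(cap, (int, float)) and np.isfinite(cap) and cap >= 0
        if not ok:
            rejected.append(props[id_field])
            if strict:
                continue  # collect all offenders before raising
            continue
        ids.append(props[id_field])
        caps.append(float(cap))
        geoms.append(geom)
    if rejected:
        if strict:
            raise ValidationError(
                f"{path}: missing/negative capacity for providers: {rejected}"
            )
        logger.warning(
            "%s: rejected %d provider(s) with invalid capacity: %s",
            path, len(rejected), rejected,
        )
    return ProviderLayer(tuple(ids), np.array(caps, dtype=float), tuple(geoms), layer_crs)


def read_demand_layer(
    path,
    id_field: str = "id",
    population_field: str = "population",
    age_fields: dict | None = None,
    crs: str | None = None,
) -> DemandLayer:
    """Read a demand polygon layer from GeoJSON.

    ``age_fields`` maps age-group label -> property name; when given, the
    layer's ``age_counts`` is populated from those properties.
    """
    features, file_crs = _read_feature_collection(path)
    layer_crs = crs or file_crs
    ids, pops, geoms, rows = [], [], [], []
    age_counts = {grp: [] for grp in age_fields} if age_fields else None
    for feat in features:
        props = feat.get("properties") or {}
        _require_field(props, id_field, path)
        _require_field(props, population_field, path)
        geom = shape(feat["geometry"])
        ids.append(props[id_field])
        pops.append(props[population_field])
        geoms.append(geom)
        rows.append(dict(props))
        if age_fields:
            for grp, fld in age_fields.items():
                _require_field(props, fld, path)
                age_counts[grp].append(props[fld])
    attributes = pd.DataFrame(rows) if rows else pd.DataFrame()
    if age_counts is not None:
        age_counts = {g: np.array(v, dtype=float) for g, v in age_counts.items()}
    return DemandLayer(
        tuple(ids),
        np.array(pops, dtype=float),
        tuple(geoms),
        age_counts=age_counts,
        attributes=attributes,
        crs=layer_crs,
    )


def write_provider_layer(layer: ProviderLayer, path,
                         id_field: str = "id", capacity_field: str = "capacity") -> None:
    """Write a provider layer to GeoJSON."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(g),
            "properties": {id_field: pid, capacity_field: float(cap)},
        }
        for pid, cap, g in zip(layer.provider_id, layer.capacity, layer.geometry)
    ]
    _write_feature_collection(path, features, layer.crs)


def write_demand_layer(layer: DemandLayer, path,
                       id_field: str = "id", population_field: str = "population") -> None:
    """Write a demand layer to GeoJSON, preserving any original attributes."""
    features = []
    for i, (did, pop, g) in enumerate(
        zip(layer.demand_id, layer.population, layer.geometry)
    ):
        props = {}
        if layer.attributes is not None and len(layer.attributes):
            props.update(layer.attributes.iloc[i].to_dict())
        if layer.age_counts:
            for grp, counts in layer.age_counts.items():
                props.setdefault(grp, float(counts[i]))
        props[id_field] = did
        props[population_field] = float(pop)
        features.append(
            {"type": "Feature", "geometry": mapping(g), "properties": props}
        )
    _write_feature_collection(path, features, layer.crs)


RESULT_FIELDS = ("final_index", "zone1_index", "zone2_index", "zone3_index", "scaled_index")


def write_result_layer(demand: DemandLayer, result: AccessibilityResult, path) -> None:
    """Write the demand polygons with accessibility fields appended.

    The output mirrors the demand layer (all original attributes, geometry
    unchanged) plus ``final_index`` and, when present, per-zone indices and
    the per-capita ``scaled_index``.
    """
    if set(result.demand_id) != set(demand.demand_id):
        missing = sorted(set(demand.demand_id) - set(result.demand_id), key=str)
        extra = sorted(set(result.demand_id) - set(demand.demand_id), key=str)
        raise IntegrityError(
            f"result does not match demand layer (missing ids: {missing}, "
            f"unknown ids: {extra})"
        )
    order = {did: i for i, did in enumerate(result.demand_id)}
    features = []
    for i, (did, g) in enumerate(zip(demand.demand_id, demand.geometry)):
        props = {}
        if demand.attributes is not None and len(demand.attributes):
            props.update(demand.attributes.iloc[i].to_dict())
        props.setdefault("id", did)
        props.setdefault("population", float(demand.population[i]))
        r = order[did]
        props["final_index"] = float(result.final_index[r])
        if result.zone_components is not None:
            for z in range(result.zone_components.shape[1]):
                props[f"zone{z + 1}_index"] = float(result.zone_components[r, z])
        if result.scaled_index is not None:
            props["scaled_index"] = float(result.scaled_index[r])
        features.append(
            {"type": "Feature", "geometry": mapping(g), "properties": props}
        )
    _write_feature_collection(path, features, demand.crs)


def read_result_layer(path, id_field: str = "id") -> AccessibilityResult:
    """Read back a result layer written by :func:`write_result_layer`."""
    features, _crs = _read_feature_collection(path)
    ids, final, zones, scaled = [], [], [], []
    have_zones = have_scaled = False
    for feat in features:
        props = feat.get("properties") or {}
        _require_field(props, id_field, path)
        _require_field(props, "final_index", path)
        ids.append(props[id_field])
        final.append(float(props["final_index"]))
        if "zone1_index" in props:
            have_zones = True
            zones.append([float(props[f"zone{z}_index"]) for z in (1, 2, 3)])
        if "scaled_index" in props:
            have_scaled = True
            scaled.append(float(props["scaled_index"]))
    return AccessibilityResult(
        tuple(ids),
        np.array(final, dtype=float),
        zone_components=np.array(zones, dtype=float) if have_zones else None,
        scaled_index=np.array(scaled, dtype=float) if have_scaled else None,
    )
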