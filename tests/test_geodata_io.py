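import json

import numpy as np
import pytest
from shapely.geometry import Point

import fcaccess as f
from fcaccess.errors import ConfigurationError, CRSError, IntegrityError, ValidationError


def write_geojson(path, features, crs=None):
    doc = {"type": "FeatureCollection", "features": features}
    if crs:
        doc["crs"] = {"type": "name", "properties": {"name": crs}}
    path.write_text(json.dumps(doc))


def point_feature(pid, cap, x, y, extra=None):
    props = {"id": pid, "capacity": cap, **(extra or {})}
    return {"type": "Feature", "geometry": {"type": "Point", "coordinates": [x, y]},
            "properties": props}


def cell_feature(did, pop, x0, y0, size=1.0, extra=None):
    ring = [[x0, y0], [x0 + size, y0], [x0 + size, y0 + size], [x0, y0 + size], [x0, y0]]
    return {"type": "Feature", "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"id": did, "population": pop, **(extra or {})}}


class TestProviderLayer:
    def test_round_trip_preserves_capacities(self, tmp_path):
        p = tmp_path / "prov.geojson"
        write_geojson(p, [point_feature(f"p{i}", c, i, 0) for i, c in enumerate([10, 5, 0])])
        layer = f.read_provider_layer(p)
        assert len(layer) == 3
        assert layer.capacity.tolist() == [10.0, 5.0, 0.0]
        out = tmp_path / "out.geojson"
        f.write_provider_layer(layer, out)
        again = f.read_provider_layer(out)
        assert again.provider_id == layer.provider_id
        assert np.allclose(again.capacity, layer.capacity, atol=1e-9)

    def test_missing_capacity_field_is_configuration_error(self, tmp_path):
        p = tmp_path / "prov.geojson"
        feats = [point_feature("p0", 1, 0, 0)]
        for feat in feats:
            del feat["properties"]["capacity"]
        write_geojson(p, feats)
        with pytest.raises(ConfigurationError, match="capacity"):
            f.read_provider_layer(p)

    def test_negative_capacity_names_offenders(self, tmp_path):
        p = tmp_path / "prov.geojson"
        write_geojson(p, [point_feature("good", 3, 0, 0), point_feature("bad", -1, 1, 0)])
        with pytest.raises(ValidationError, match="bad"):
            f.read_provider_layer(p)
        lenient = f.read_provider_layer(p, strict=False)
        assert lenient.provider_id == ("good",)  # accepted + rejected = input count

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "prov.geojson"
        write_geojson(p, [point_feature("p", 1, 0, 0), point_feature("p", 2, 1, 0)])
        with pytest.raises(ValidationError, match="duplicate"):
            f.read_provider_layer(p)

    def test_geographic_crs_refused(self, tmp_path):
        p = tmp_path / "prov.geojson"
        write_geojson(p, [point_feature("p0", 1, 0, 0)], crs="EPSG:4326")
        with pytest.raises(CRSError, match="reproject"):
            f.read_provider_layer(p)

    def test_synthetic_192_provider_fixture_round_trips(self, tmp_path):
        providers, _, _ = f.make_scenario(f.ScenarioSpec(n_providers=192, seed=3))
        p = tmp_path / "prov.geojson"
        f.write_provider_layer(providers, p)
        assert len(f.read_provider_layer(p)) == 192


class TestDemandLayer:
    def test_grid_read_with_rep_points_inside(self, tmp_path):
        p = tmp_path / "dem.geojson"
        write_geojson(p, [cell_feature(f"d{i}", pop, i % 2, i // 2)
                          for i, pop in enumerate([100, 200, 300, 400])])
        layer = f.read_demand_layer(p)
        assert len(layer) == 4
        assert layer.population.tolist() == [100.0, 200.0, 300.0, 400.0]
        for poly, rep in zip(layer.geometry, layer.rep_point):
            assert poly.covers(rep)

    def test_negative_population_rejected(self, tmp_path):
        p = tmp_path / "dem.geojson"
        write_geojson(p, [cell_feature("d0", -5, 0, 0)])
        with pytest.raises(ValidationError, match="d0"):
            f.read_demand_layer(p)

    def test_non_polygon_geometry_rejected(self, tmp_path):
        p = tmp_path / "dem.geojson"
        write_geojson(p, [point_feature("d0", 1, 0, 0)])
        with pytest.raises(ValidationError, match="polygon"):
            f.read_demand_layer(p, population_field="capacity")

    def test_age_fields_round_trip(self, tmp_path):
        groups = ["0-17", "18-44", "45-64", "65-74", "75+"]
        p = tmp_path / "dem.geojson"
        write_geojson(
            p,
            [cell_feature(f"d{i}", 100, i, 0, extra={g: 10 + j for j, g in enumerate(groups)})
             for i in range(3)],
        )
        layer = f.read_demand_layer(p, age_fields={g: g for g in groups})
        assert set(layer.age_counts) == set(groups)
        assert all(v.shape == (3,) for v in layer.age_counts.values())


class TestResultLayer:
    def make_demand(self, tmp_path, n=3):
        p = tmp_path / "dem.geojson"
        write_geojson(p, [cell_feature(f"d{i}", 100 * (i + 1), i, 0) for i in range(n)])
        return f.read_demand_layer(p)

    def test_write_read_round_trip_to_1e9(self, tmp_path):
        demand = self.make_demand(tmp_path)
        result = f.AccessibilityResult(
            demand.demand_id, np.array([0.1, 0.25, 0.0]),
            scaled_index=np.array([1e4, 2.5e4, 0.0]),
        )
        out = tmp_path / "res.geojson"
        f.write_result_layer(demand, result, out)
        again = f.read_result_layer(out)
        assert again.demand_id == result.demand_id
        assert np.allclose(again.final_index, result.final_index, atol=1e-9)
        assert np.allclose(again.scaled_index, result.scaled_index, atol=1e-9)
        # original attributes and geometry survive
        reread = f.read_demand_layer(out)
        assert reread.population.tolist() == demand.population.tolist()
        assert all(a.equals(b) for a, b in zip(reread.geometry, demand.geometry))

    def test_missing_demand_id_is_integrity_error(self, tmp_path):
        demand = self.make_demand(tmp_path)
        result = f.AccessibilityResult(demand.demand_id[:-1], np.array([0.1, 0.2]))
        with pytest.raises(IntegrityError, match="d2"):
            f.write_result_layer(demand, result, tmp_path / "res.geojson")

    def test_enhanced_result_carries_three_zone_fields(self, tmp_path):
        demand = self.make_demand(tmp_path)
        comps = np.array([[0.1, 0.05, 0.01]] * 3)
        result = f.AccessibilityResult(demand.demand_id, comps.sum(axis=1),
                                       zone_components=comps)
        out = tmp_path / "res.geojson"
        f.write_result_layer(demand, result, out)
        props = json.loads(out.read_text())["features"][0]["properties"]
        assert {"zone1_index", "zone2_index", "zone3_index", "final_index"} <= set(props)

    def test_zone_components_must_sum_to_final(self):
        with pytest.raises(ValidationError, match="sum"):
            f.AccessibilityResult(("d0",), np.array([1.0]),
                                  zone_components=np.array([[0.2, 0.2, 0.2]]))


def test_rep_point_falls_back_to_interior_for_concave_polygon():
    from shapely.geometry import Polygon

    from fcaccess.geodata_io import representative_point

    horseshoe = Polygon([(0, 0), (5, 0), (5, 5), (0, 5), (0, 4), (4, 4), (4, 1), (0, 1)])
    assert not horseshoe.covers(horseshoe.centroid)
    assert horseshoe.covers(representative_point(horseshoe))
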