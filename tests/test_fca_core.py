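import numpy as np
import pytest

import fcaccess as f
from conftest import point_layers
from fcaccess.catchment import BUFFER_MODE, CatchmentConfig
from fcaccess.errors import ConfigurationError
from fcaccess.fca_core import (
    DistanceBandMembership,
    classic_step1,
    classic_step2,
    enhanced_step1,
    enhanced_step2,
    per_capita_scale,
    run_model,
)
from oracles import brute_force_fca

W = (1.0, 0.68, 0.22)


def membership(prov, dem, thresholds):
    return DistanceBandMembership(prov, dem, thresholds)


class TestClassicSteps:
    def test_single_pair_ratio(self):
        prov, dem = point_layers([(0, 0)], [10.0], [(1, 0)], [1000.0])
        r = classic_step1(prov, dem, membership(prov, dem, [5]))
        assert r.ratio[0] == 0.01

    def test_zero_catchment_demand_gives_zero_ratio_and_warning(self, caplog):
        prov, dem = point_layers([(0, 0)], [10.0], [(100, 0)], [1000.0])
        with caplog.at_level("WARNING", logger="fcaccess.fca_core"):
            r = classic_step1(prov, dem, membership(prov, dem, [5]))
        assert r.ratio[0] == 0.0
        assert any("zero catchment demand" in rec.message for rec in caplog.records)

    def test_two_symmetric_providers_sum_in_step2(self):
        # both providers see only the middle demand of 200 people
        prov, dem = point_layers([(0, 0), (2, 0)], [1.0, 1.0], [(1, 0)], [200.0])
        member = membership(prov, dem, [1.5])
        ratios = classic_step1(prov, dem, member)
        assert np.allclose(ratios.ratio, [1 / 200, 1 / 200])
        result = classic_step2(ratios, dem, prov, member)
        assert result.final_index[0] == pytest.approx(0.01, rel=1e-12)

    def test_demand_outside_all_catchments_scores_zero(self):
        prov, dem = point_layers([(0, 0)], [5.0], [(1, 0), (50, 0)], [100.0, 100.0])
        member = membership(prov, dem, [5])
        result = classic_step2(classic_step1(prov, dem, member), dem, prov, member)
        assert result.final_index[1] == 0.0
        assert result.diagnostics["unreachable_demand"] == 1

    def test_crs_mismatch_rejected(self):
        from dataclasses import replace

        prov, dem = point_layers([(0, 0)], [1.0], [(1, 0)], [10.0])
        prov = replace(prov, crs="EPSG:32616")
        with pytest.raises(ConfigurationError, match="CRS"):
            classic_step1(prov, dem, membership(prov, dem, [5]))


class TestEnhancedSteps:
    def layout(self):
        # one provider; one demand of 100 in each of the three zones
        return point_layers(
            [(0, 0)], [10.0], [(3, 0), (7, 0), (12, 0)], [100.0, 100.0, 100.0]
        )

    def test_weighted_ratio_with_default_decay(self):
        prov, dem = self.layout()
        r = enhanced_step1(prov, dem, membership(prov, dem, [5, 10, 15]), W)
        assert r.ratio[0] == pytest.approx(10 / 190, rel=1e-12)

    def test_all_demand_in_outer_zone(self):
        prov, dem = point_layers([(0, 0)], [22.0], [(12, 0)], [1000.0])
        r = enhanced_step1(prov, dem, membership(prov, dem, [5, 10, 15]), W)
        assert r.ratio[0] == pytest.approx(0.1, rel=1e-12)  # 22 / (0.22 * 1000)

    def test_step2_applies_zone_weight_of_the_demand(self):
        prov, dem = self.layout()
        member = membership(prov, dem, [5, 10, 15])
        ratios = enhanced_step1(prov, dem, member, W)
        result = enhanced_step2(ratios, dem, prov, member, W)
        R = 10 / 190
        assert result.final_index[0] == pytest.approx(R, rel=1e-12)  # zone 1
        assert result.final_index[2] == pytest.approx(R * 0.22, rel=1e-12)  # zone 3

    def test_zone_components_sum_to_final_index(self):
        rng = np.random.default_rng(11)
        prov, dem = point_layers(
            rng.uniform(0, 30, (8, 2)), rng.uniform(1, 20, 8),
            rng.uniform(0, 30, (40, 2)), rng.uniform(10, 500, 40),
        )
        member = membership(prov, dem, [5, 10, 15])
        result = enhanced_step2(enhanced_step1(prov, dem, member, W), dem, prov, member, W)
        assert np.allclose(result.zone_components.sum(axis=1), result.final_index,
                           rtol=1e-12)

    def test_wrong_weight_count_rejected(self):
        prov, dem = self.layout()
        with pytest.raises(ConfigurationError):
            enhanced_step1(prov, dem, membership(prov, dem, [5, 10, 15]), (1.0, 0.5))


class TestPerCapitaScale:
    def test_scales_without_touching_final_index(self):
        res = f.AccessibilityResult(("a",), np.array([1e-4]))
        scaled = per_capita_scale(res, 100_000)
        assert scaled.scaled_index[0] == pytest.approx(10.0)
        assert scaled.final_index[0] == 1e-4

    def test_identity_multiplier(self):
        res = f.AccessibilityResult(("a", "b"), np.array([0.5, 0.25]))
        scaled = per_capita_scale(res, 1.0)
        assert np.array_equal(scaled.scaled_index, scaled.final_index)

    def test_non_positive_multiplier_rejected(self):
        res = f.AccessibilityResult(("a",), np.array([1.0]))
        with pytest.raises(ConfigurationError):
            per_capita_scale(res, 0)


class TestRunModel:
    def test_all_variants_share_the_record_set(self):
        prov, dem, net = f.make_covering_scenario(
            f.ScenarioSpec(rows=6, cols=6, n_providers=4, seed=5)
        )
        ids = None
        for variant in ("2sfca_buffer", "e2sfca_buffer", "2sfca_travel", "e2sfca_travel"):
            res = run_model(variant, prov, dem, net=net)
            assert res.scaled_index is not None
            ids = ids or res.demand_id
            assert res.demand_id == ids

    def test_variant_config_mismatch_rejected(self):
        prov, dem = point_layers([(0, 0)], [1.0], [(1, 0)], [10.0])
        with pytest.raises(ConfigurationError):
            run_model("e2sfca_buffer", prov, dem,
                      CatchmentConfig(BUFFER_MODE, (15,), "miles"))
        with pytest.raises(ConfigurationError):
            run_model("2sfca_buffer", prov, dem,
                      CatchmentConfig(BUFFER_MODE, (5, 10, 15), "miles"))
        with pytest.raises(ConfigurationError, match="network"):
            run_model("2sfca_travel", prov, dem)

    def test_unknown_variant_rejected(self):
        prov, dem = point_layers([(0, 0)], [1.0], [(1, 0)], [10.0])
        with pytest.raises(ConfigurationError):
            run_model("3sfca", prov, dem)


class TestInvariants:
    def random_instance(self, rng, n_p=10, n_d=40):
        return point_layers(
            rng.uniform(0, 40, (n_p, 2)), rng.uniform(0, 30, n_p),
            rng.uniform(0, 40, (n_d, 2)), rng.uniform(0, 800, n_d),
        )

    def test_adding_a_provider_never_decreases_access(self):
        rng = np.random.default_rng(23)
        prov, dem = self.random_instance(rng)
        base = run_model("2sfca_buffer", prov, dem,
                         CatchmentConfig(BUFFER_MODE, (15,), "meters"))
        from dataclasses import replace
        from shapely.geometry import Point

        bigger = f.ProviderLayer(
            prov.provider_id + ("extra",),
            np.append(prov.capacity, 12.0),
            prov.geometry + (Point(20, 20),),
        )
        more = run_model("2sfca_buffer", bigger, dem,
                         CatchmentConfig(BUFFER_MODE, (15,), "meters"))
        assert (more.final_index >= base.final_index - 1e-15).all()

    def test_adding_demand_never_increases_access(self):
        rng = np.random.default_rng(29)
        prov, dem = self.random_instance(rng)
        config = CatchmentConfig(BUFFER_MODE, (15,), "meters")
        base = run_model("2sfca_buffer", prov, dem, config)
        boosted = dem.with_population(dem.population + 50.0)
        more = run_model("2sfca_buffer", prov, boosted, config)
        assert (more.final_index <= base.final_index + 1e-15).all()

    @pytest.mark.parametrize("c", [2.0, 0.5])
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(31)
        prov, dem = self.random_instance(rng)
        config = CatchmentConfig(BUFFER_MODE, (5, 10, 15), "meters", weights=W)
        base = run_model("e2sfca_buffer", prov, dem, config)
        scaled_caps = f.ProviderLayer(prov.provider_id, prov.capacity * c, prov.geometry)
        capr = run_model("e2sfca_buffer", scaled_caps, dem, config)
        assert np.allclose(capr.final_index, c * base.final_index, rtol=1e-12)
        popr = run_model("e2sfca_buffer", prov, dem.with_population(dem.population * c),
                         config)
        # zero-population demands stay zero; others divide by c
        nz = dem.population > 0
        assert np.allclose(popr.final_index[nz], base.final_index[nz] / c, rtol=1e-12)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            n_p, n_d = int(rng.integers(2, 10)), int(rng.integers(5, 30))
            prov, dem = self.random_instance(rng, n_p, n_d)
            thresholds = (6.0, 13.0, 22.0)
            member = membership(prov, dem, thresholds)
            ratios = enhanced_step1(prov, dem, member, W)
            result = enhanced_step2(ratios, dem, prov, member, W)
            bR, bA, bC = brute_force_fca(
                prov.coords.tolist(), prov.capacity.tolist(),
                dem.coords.tolist(), dem.population.tolist(), thresholds, W,
            )
            assert ratios.ratio.tolist() == bR
            assert result.final_index.tolist() == bA
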