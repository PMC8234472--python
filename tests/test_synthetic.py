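"""Generator tests: study region, cluster sampling, field simulation,
outcome mechanism, geo-masking and covariate rasters."""

import numpy as np
import pytest

from geostunt import spde
from geostunt import synthetic as syn


class TestMakeStudyRegion:
    def test_single_zone_equals_boundary(self):
        region = syn.make_study_region(1, 100.0, seed=7)
        assert len(region.zones) == 1
        assert region.zones[0].polygon.area == pytest.approx(10_000.0)
        assert region.zones[0].polygon.equals(region.boundary)

    def test_partition_conserves_area(self):
        region = syn.make_study_region(12, 500.0, seed=1)
        assert len(region.zones) == 12
        total = sum(z.polygon.area for z in region.zones)
        assert total == pytest.approx(250_000.0, rel=1e-6)
        # pairwise-disjoint interiors
        for i in range(12):
            for j in range(i + 1, 12):
                inter = region.zones[i].polygon.intersection(
                    region.zones[j].polygon
                )
                assert inter.area < 1e-6

    def test_seed_determinism(self):
        a = syn.make_study_region(5, 200.0, seed=3)
        b = syn.make_study_region(5, 200.0, seed=3)
        for za, zb in zip(a.zones, b.zones):
            assert za.polygon.equals(zb.polygon)
        np.testing.assert_array_equal(a.urban_centres, b.urban_centres)

    def test_urban_centres_inside_boundary(self):
        region = syn.make_study_region(8, 300.0, seed=2)
        import shapely

        assert np.all(
            shapely.contains_xy(
                region.boundary,
                region.urban_centres[:, 0],
                region.urban_centres[:, 1],
            )
        )

    def test_invalid_extent(self):
        with pytest.raises(ValueError):
            syn.make_study_region(3, -5.0, seed=0)


class TestSampleClusters:
    def test_all_rural_when_urban_fraction_zero(self, region):
        cfg = syn.SimulationConfig(n_clusters=40, urban_fraction=0.0, seed=1)
        records, _ = syn.sample_clusters(region, cfg)
        assert all(not r.urban for r in records)

    def test_national_scale_cluster_count(self, region):
        cfg = syn.SimulationConfig(seed=2)  # defaults: the national-scale 622-cluster scenario
        records, locs = syn.sample_clusters(region, cfg)
        assert len(records) == 622
        assert locs.shape == (622, 2)

    def test_mean_children_matches_design_rate(self, region):
        # expected children/cluster = 28 households x rate ~= 9089/622
        target = 9089 / 622
        cfg = syn.SimulationConfig(n_clusters=200, seed=3)
        records, _ = syn.sample_clusters(region, cfg)
        mean_children = np.mean([r.n_children for r in records])
        assert abs(mean_children - target) / target < 0.05

    def test_urban_fraction_validation(self):
        with pytest.raises(ValueError):
            syn.SimulationConfig(urban_fraction=1.5)

    def test_stratum_combines_zone_and_urbanicity(self, region):
        cfg = syn.SimulationConfig(n_clusters=50, urban_fraction=0.5, seed=4)
        records, _ = syn.sample_clusters(region, cfg)
        for r in records:
            zone, ur = r.stratum.split("/")
            assert zone.startswith("zone_")
            assert ur == ("U" if r.urban else "R")


class TestSimulateSpatialField:
    def test_single_location_standard_normal(self):
        params = spde.MaternParams(kappa=0.1, sigma2=1.0)
        draws = np.array(
            [syn.simulate_spatial_field([[0.0, 0.0]], params, seed=s)[0]
             for s in range(10_000)]
        )
        assert np.var(draws) == pytest.approx(1.0, abs=0.06)
        assert abs(np.mean(draws)) < 0.05

    def test_zero_variance_gives_zeros(self):
        params = spde.MaternParams(kappa=0.1, sigma2=0.0)
        out = syn.simulate_spatial_field(
            [[0.0, 0.0], [5.0, 5.0]], params, seed=1
        )
        np.testing.assert_array_equal(out, 0.0)

    def test_distant_points_uncorrelated(self):
        # two locations 1000 km apart at kappa=0.1: correlation ~ 0
        params = spde.MaternParams(kappa=0.1, sigma2=1.0)
        locs = [[0.0, 0.0], [1000.0, 0.0]]
        draws = np.array(
            [syn.simulate_spatial_field(locs, params, seed=s)
             for s in range(5000)]
        )
        emp = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        target = spde.matern_correlation(1000.0, 0.1)
        assert abs(emp - target) < 0.05

    def test_moderate_distance_correlation(self):
        params = spde.MaternParams(kappa=0.04, sigma2=1.0)
        locs = [[0.0, 0.0], [30.0, 0.0]]
        draws = np.array(
            [syn.simulate_spatial_field(locs, params, seed=s)
             for s in range(5000)]
        )
        emp = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert abs(emp - spde.matern_correlation(30.0, 0.04)) < 0.05

    def test_duplicate_locations_raise_with_hint(self):
        params = spde.MaternParams(kappa=0.1, sigma2=1.0)
        with pytest.raises(ValueError, match="jitter|duplicate"):
            syn.simulate_spatial_field(
                [[1.0, 1.0], [1.0, 1.0]], params, seed=0
            )


class TestSimulateOutcomes:
    def _skeletons(self, region, n_clusters, n_children, seed=5):
        cfg = syn.SimulationConfig(
            n_clusters=n_clusters, seed=seed, covariates=(), intercept=0.0,
            matern=spde.MaternParams(0.05, 0.0),
        )
        records, locs = syn.sample_clusters(region, cfg)
        for r in records:
            r.n_children = n_children
        return records, locs, cfg

    def test_half_prevalence_recovered(self, region):
        # intercept 0, no effects, no field -> true prevalence 0.5 everywhere
        records, locs, cfg = self._skeletons(region, 100, 100)
        records, truth = syn.simulate_outcomes(records, np.zeros(100), cfg)
        np.testing.assert_allclose(truth.cluster_prevalence, 0.5)
        frac = sum(r.n_stunted for r in records) / sum(r.n_children for r in records)
        assert 0.49 <= frac <= 0.51

    def test_degenerate_haz_sd_zero(self, region):
        records, locs, _ = self._skeletons(region, 10, 20)
        cfg = syn.SimulationConfig(
            n_clusters=10, seed=5, covariates=(), intercept=3.0,
            matern=spde.MaternParams(0.05, 0.0), haz_sd=0.0,
        )
        records, truth = syn.simulate_outcomes(records, np.zeros(10), cfg)
        assert all(r.n_stunted == r.n_children for r in records)

    def test_haz_threshold_is_strict(self):
        from geostunt.survey import classify_stunting

        assert classify_stunting(-2.01) == 1
        assert classify_stunting(-2.0) == 0

    def test_ground_truth_prevalence_invariant(self, region):
        cfg = syn.SimulationConfig(
            n_clusters=30, seed=6,
            matern=spde.MaternParams(0.04, 0.4),
        )
        records, locs = syn.sample_clusters(region, cfg)
        fld = syn.simulate_spatial_field(locs, cfg.matern, seed=1)
        records, truth = syn.simulate_outcomes(records, fld, cfg)
        assert np.all((truth.cluster_prevalence > 0) & (truth.cluster_prevalence < 1))


@pytest.fixture(scope="module")
def masked(region):
    cfg = syn.SimulationConfig(n_clusters=300, urban_fraction=0.4, seed=9)
    records, locs = syn.sample_clusters(region, cfg)
    fld = np.zeros(len(records))
    records, truth = syn.simulate_outcomes(records, fld, cfg)
    displaced = syn.apply_geomasking(records, cfg, region, seed=21)
    return records, displaced, truth


class TestGeomasking:

    def test_distance_bounds(self, masked):
        records, displaced, truth = masked
        for orig, disp in zip(records, displaced):
            d = np.hypot(disp.x - orig.x, disp.y - orig.y)
            cap = 2.0 if orig.urban else 10.0
            assert d <= cap + 1e-9

    def test_displaced_point_stays_in_zone(self, masked, region):
        records, displaced, _ = masked
        for orig, disp in zip(records, displaced):
            zone = region.zone_of(orig.x, orig.y)
            from shapely.geometry import Point

            assert zone.polygon.covers(Point(disp.x, disp.y))

    def test_seed_reproducibility(self, masked, region):
        records, displaced, _ = masked
        cfg = syn.SimulationConfig(n_clusters=300, urban_fraction=0.4, seed=9)
        again = syn.apply_geomasking(records, cfg, region, seed=21)
        for a, b in zip(displaced, again):
            assert (a.x, a.y) == (b.x, b.y)

    def test_truth_keeps_original_coordinates(self, region):
        cfg = syn.SimulationConfig(n_clusters=50, seed=10)
        records, truth = syn.simulate_survey(region, cfg, geomask=True)
        moved = np.hypot(
            truth.true_locations[:, 0] - np.array([r.x for r in records]),
            truth.true_locations[:, 1] - np.array([r.y for r in records]),
        )
        assert np.any(moved > 0)


class TestCovariateRaster:
    def test_zero_variance_constant(self, region):
        r = syn.simulate_covariate_raster(
            region, spde.MaternParams(0.05, 0.0), resolution_km=25.0, seed=0
        )
        vals = r.values[~np.isnan(r.values)]
        assert np.all(vals == vals[0])

    def test_grid_shape_arithmetic(self):
        region = syn.make_study_region(1, 100.0, seed=0)
        r = syn.simulate_covariate_raster(
            region, spde.MaternParams(0.05, 1.0), resolution_km=5.0, seed=0
        )
        assert r.values.shape == (20, 20)

    def test_variance_near_target(self):
        region = syn.make_study_region(1, 500.0, seed=0)
        # 50 km conventional range -> kappa = sqrt(8)/50
        params = spde.MaternParams(kappa=np.sqrt(8.0) / 50.0, sigma2=1.0)
        r = syn.simulate_covariate_raster(region, params, resolution_km=10.0, seed=3)
        vals = r.values[~np.isnan(r.values)]
        assert abs(np.var(vals) - 1.0) < 0.25


def test_survey_pipeline_deterministic(region):
    cfg = syn.SimulationConfig(n_clusters=40, seed=17)
    a_recs, a_truth = syn.simulate_survey(region, cfg)
    b_recs, b_truth = syn.simulate_survey(region, cfg)
    for a, b in zip(a_recs, b_recs):
        assert (a.x, a.y, a.n_children, a.n_stunted) == (b.x, b.y, b.n_children, b.n_stunted)
        assert a.covariates == b.covariates
    np.testing.assert_array_equal(a_truth.field_values, b_truth.field_values)


def test_geomasking_attenuates_spatial_covariate_effect(region):
    """Re-extracting a spatially smooth covariate at displaced coordinates
    misclassifies exposure non-differentially, so the fitted effect is
    systematically attenuated toward zero relative to fits at the true
    coordinates."""
    from geostunt import model
    from geostunt.geodata import ClusterRecord
    from geostunt.model import ModelSpec, NumericTerm

    beta_true = 0.8
    diffs = []
    for rep in range(30):
        cfg = syn.SimulationConfig(
            n_clusters=100, urban_fraction=0.0, seed=300 + rep, covariates=()
        )
        skeletons, locs = syn.sample_clusters(region, cfg)
        raster = syn.simulate_covariate_raster(
            region, spde.MaternParams(kappa=np.sqrt(8.0) / 40.0, sigma2=1.0),
            resolution_km=5.0, seed=900 + rep,
        )
        rng = np.random.default_rng(1700 + rep)
        z_true = np.array([raster.value_at(x, y) for x, y in locs])
        records = []
        for rec, z in zip(skeletons, z_true):
            p = 1.0 / (1.0 + np.exp(-(-0.5 + beta_true * z)))
            n = max(rec.n_children, 1)
            records.append(
                ClusterRecord(
                    rec.cluster_id, rec.x, rec.y, rec.urban, rec.stratum,
                    rec.weight, n, int(rng.binomial(n, p)),
                    covariates={"z": float(z)},
                )
            )
        displaced = syn.apply_geomasking(records, cfg, region, seed=2500 + rep)
        for d in displaced:
            d.covariates["z"] = float(raster.value_at(d.x, d.y))
        spec = ModelSpec(covariates=[NumericTerm("z")])
        b_true = np.median(
            model.fit_nonspatial(spec, records, method="laplace", seed=rep)
            .beta_draws[:, 1]
        )
        b_disp = np.median(
            model.fit_nonspatial(spec, displaced, method="laplace", seed=rep)
            .beta_draws[:, 1]
        )
        diffs.append(b_true - b_disp)
    # mean attenuation is toward zero (non-negative for a positive effect)
    assert np.mean(diffs) >= 0.0
    assert np.mean(diffs) > 0.02  # and clearly nonzero at 10 km displacement
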