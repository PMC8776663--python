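import numpy as np
import pytest

from mrdsurvey.abundance import (
    combined_pa,
    cv_components,
    effort_for_cv,
    encounter_var_s2,
    extrapolate,
    ht_abundance,
    lognormal_ci,
    mean_group,
    s2_rate_variance,
)
from mrdsurvey.survey_data import (
    ClusterObservation,
    StratumSpec,
    SurveyDataset,
    TransectRecord,
)


def _dataset(strata, transects, obs_spec):
    """obs_spec: list of (transect_id, stratum_id, distance, size)."""
    obs = tuple(
        ClusterObservation(id=f"o{i}", transect_id=t, stratum_id=s, distance_m=d,
                           seen_front=1, seen_rear=0, cluster_size=g)
        for i, (t, s, d, g) in enumerate(obs_spec)
    )
    return SurveyDataset(obs, tuple(transects), tuple(strata))


class TestCombinedPa:
    def test_perfect_line_detection_passthrough(self):
        pa, var = combined_pa(1.0, 0.0, 0.6, 0.01)
        assert (pa, var) == (0.6, 0.01)

    def test_published_model_averaged_combination(self):
        pa, var = combined_pa(0.953, 0.056**2, 0.571, 0.151**2)
        assert pa == pytest.approx(0.544, abs=0.001)
        assert np.sqrt(var) == pytest.approx(0.147, abs=0.002)

    def test_symmetric_inputs(self):
        pa, var = combined_pa(0.8, 0.01, 0.8, 0.01)
        assert var == pytest.approx(2 * 0.8**2 * 0.01)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            combined_pa(0.0, 0.0, 0.5, 0.0)


class TestMeanGroup:
    def test_published_composition(self):
        sizes = [1] * 13 + [2] * 9 + [3] * 6
        st_ = StratumSpec(id="s", area_km2=10.0)
        tr = TransectRecord(id="T1", stratum_id="s", length_km=5.0, design_order=0)
        ds = _dataset([st_], [tr], [("T1", "s", 100.0, g) for g in sizes])
        g, se = mean_group(ds)
        assert g == pytest.approx(1.75)
        assert se == pytest.approx(0.15, abs=0.005)

    def test_three_point_formula(self):
        st_ = StratumSpec(id="s", area_km2=10.0)
        tr = TransectRecord(id="T1", stratum_id="s", length_km=5.0, design_order=0)
        ds = _dataset([st_], [tr], [("T1", "s", 100.0, g) for g in (1, 2, 3)])
        g, se = mean_group(ds)
        assert g == pytest.approx(2.0)
        assert se == pytest.approx(1.0 / np.sqrt(3))

    def test_constant_sizes_have_zero_se(self):
        st_ = StratumSpec(id="s", area_km2=10.0)
        tr = TransectRecord(id="T1", stratum_id="s", length_km=5.0, design_order=0)
        ds = _dataset([st_], [tr], [("T1", "s", 100.0, 1) for _ in range(5)])
        assert mean_group(ds) == (1.0, 0.0)


class TestEncounterVarianceS2:
    def test_hand_computed_pairing(self):
        # pairs {1,2}, {3,4}: each var_h(n/L) = 0.01, combined 0.005
        assert s2_rate_variance([10, 10, 10, 10], [2, 0, 2, 0]) == pytest.approx(0.005)

    def test_homogeneous_counts_give_zero(self):
        assert s2_rate_variance([10, 10, 10, 10], [1, 1, 1, 1]) == 0.0

    def test_odd_transect_folds_into_last_group(self):
        assert s2_rate_variance([10, 10, 10], [1, 1, 1]) == 0.0

    def test_single_transect_names_stratum(self):
        tr = [TransectRecord(id="T1", stratum_id="lonely", length_km=5.0, design_order=0)]
        with pytest.raises(ValueError, match="lonely"):
            encounter_var_s2(tr, {})

    def test_mean_matches_poisson_variance(self):
        """On equal transects with Poisson counts, S2 is nearly unbiased."""
        rng = np.random.default_rng(0)
        k, lam, reps = 20, 3.0, 500
        lengths = [10.0] * k
        total_l = float(sum(lengths))
        est = [
            total_l**2 * s2_rate_variance(lengths, rng.poisson(lam, k))
            for _ in range(reps)
        ]
        true_var = lam * k  # variance of the total count
        assert np.mean(est) == pytest.approx(true_var, rel=0.10)


class TestHTAbundance:
    def _toy(self):
        st_ = StratumSpec(id="s", area_km2=1000.0, truncation_m=1000.0)
        trs = [
            TransectRecord(id=f"T{i}", stratum_id="s", length_km=25.0, design_order=i)
            for i in range(2)
        ]
        # a = 2 * 1 km * 50 km = 100 km^2; c = 5
        obs = [("T0", "s", 100.0, 2)] * 3 + [("T1", "s", 200.0, 2)] * 2
        return _dataset([st_], trs, obs)

    def test_hand_computed_horvitz_thompson(self):
        ds = self._toy()
        est = ht_abundance(ds, pa=0.5, var_pa=0.01, g_mean=2.0, var_g=0.0)
        assert est.clusters_surveyed == pytest.approx(10.0)
        assert est.clusters_total == pytest.approx(100.0)
        assert est.n_total == pytest.approx(200.0)
        # detection variance: (10)^2 * (5 * 0.5^-2)^2 * 0.01 = 400
        assert est.var_detection == pytest.approx(100 * 400 * 0.01)

    def test_census_limit(self):
        st_ = StratumSpec(id="s", area_km2=100.0, truncation_m=1000.0)
        trs = [
            TransectRecord(id=f"T{i}", stratum_id="s", length_km=25.0, design_order=i)
            for i in range(2)
        ]
        obs = [(f"T{i % 2}", "s", 100.0, 2) for i in range(14)]
        ds = _dataset([st_], trs, obs)  # a = 100 km^2 = A: full coverage
        est = ht_abundance(ds, pa=1.0, var_pa=0.0, g_mean=2.0, var_g=0.0)
        assert est.n_total == pytest.approx(28.0)
        assert est.var_detection == 0.0

    def test_variance_additivity_and_area_scaling(self):
        ds = self._toy()
        est = ht_abundance(ds, pa=0.5, var_pa=0.01, g_mean=2.0, var_g=0.04)
        assert est.var_total == pytest.approx(est.var_detection + est.var_encounter)
        doubled = SurveyDataset(
            ds.observations,
            ds.transects,
            tuple(
                StratumSpec(id=s.id, area_km2=2 * s.area_km2, truncation_m=s.truncation_m)
                for s in ds.strata
            ),
        )
        est2 = ht_abundance(doubled, pa=0.5, var_pa=0.01, g_mean=2.0, var_g=0.04)
        assert est2.clusters_total == pytest.approx(2 * est.clusters_total)
        assert est2.n_total == pytest.approx(2 * est.n_total)

    def test_no_detections_rejected(self):
        st_ = StratumSpec(id="s", area_km2=100.0, truncation_m=1000.0)
        trs = [
            TransectRecord(id=f"T{i}", stratum_id="s", length_km=25.0, design_order=i)
            for i in range(2)
        ]
        ds = _dataset([st_], trs, [])
        with pytest.raises(ValueError, match="no detections"):
            ht_abundance(ds, pa=0.5, var_pa=0.0, g_mean=2.0, var_g=0.0)


class TestIntervalsAndPlanning:
    def test_zero_cv_collapses_interval(self):
        assert lognormal_ci(100.0, 0.0) == (100.0, 100.0)

    def test_published_scale_interval(self):
        lo, hi = lognormal_ci(190.0, 0.39)
        assert lo == pytest.approx(91, abs=1.0)
        assert hi == pytest.approx(397, abs=1.0)

    def test_interval_width_factor(self):
        lo, hi = lognormal_ci(100.0, 0.2474)
        assert hi / 100.0 == pytest.approx(1.62, abs=0.01)

    def test_extrapolation_to_polynya_area(self):
        n, se, (lo, hi) = extrapolate(1.7, 1.9, 27_214.0)
        assert n == pytest.approx(46.3, abs=0.1)
        assert lo < n < hi

    def test_zero_density(self):
        n, se, ci = extrapolate(0.0, 0.0, 500.0)
        assert n == 0.0

    def test_direct_product(self):
        assert extrapolate(2.0, 0.0, 500.0)[0] == pytest.approx(1.0)

    def test_effort_multiplier_examples(self):
        assert effort_for_cv(0.39, 0.25) == pytest.approx(2.4, abs=0.05)
        assert effort_for_cv(0.3, 0.3) == 1.0
        assert effort_for_cv(0.5, 0.25) == pytest.approx(4.0)


class TestCVDecomposition:
    def test_published_component_row_composes(self):
        """CVs like the uniform-cosine row combine to a total CV near 0.24."""
        p0, se_p0 = 0.953, 0.06 * 0.953
        pd_, se_pd = 0.614, 0.13 * 0.614
        pa, var_pa = combined_pa(p0, se_p0**2, pd_, se_pd**2)
        cv_pa = np.sqrt(var_pa) / pa
        cv_n = np.sqrt(cv_pa**2 + 0.16**2 + 0.09**2)
        assert cv_n == pytest.approx(0.24, abs=0.02)

    def test_all_zero_components_give_zero_total(self):
        st_ = StratumSpec(id="s", area_km2=100.0, truncation_m=1000.0)
        trs = [
            TransectRecord(id=f"T{i}", stratum_id="s", length_km=25.0, design_order=i)
            for i in range(2)
        ]
        obs = [(f"T{i % 2}", "s", 100.0, 2) for i in range(4)]
        ds = _dataset([st_], trs, obs)
        est = ht_abundance(ds, pa=1.0, var_pa=0.0, g_mean=2.0, var_g=0.0)
        comps = cv_components(est, 1.0, 0.0, 1.0, 0.0)
        assert comps["n_total"] == pytest.approx(0.0)
        assert comps["p0_star"] == 0.0

    def test_largest_component_flagged(self):
        st_ = StratumSpec(id="s", area_km2=1000.0, truncation_m=1000.0)
        trs = [
            TransectRecord(id=f"T{i}", stratum_id="s", length_km=25.0, design_order=i)
            for i in range(2)
        ]
        obs = [("T0", "s", 100.0, 2)] * 3 + [("T1", "s", 200.0, 2)] * 2
        ds = _dataset([st_], trs, obs)
        est = ht_abundance(ds, pa=0.5, var_pa=0.02, g_mean=2.0, var_g=0.01)
        comps = cv_components(est, 0.95, 0.01, 0.55, 0.15)
        assert comps["largest"] == "pd"
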