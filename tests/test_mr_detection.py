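import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from mrdsurvey.model_averaging import aicc
from mrdsurvey.mr_detection import (
    BLIND_SPOT_M,
    CovariateMissingError,
    MRModelSpec,
    fit_mr,
    mr_gof,
    mr_loglik,
    mr_model_set,
    p0_star,
)
from mrdsurvey.survey_data import (
    ClusterObservation,
    StratumSpec,
    SurveyDataset,
    TransectRecord,
)

from conftest import simulate_capture_histories


def brute_force_loglik(coef, dataset, spec):
    """Independent direct-sum oracle: per-cluster three-term multinomial."""
    total = 0.0
    for o in dataset.observations:
        d = o.distance_m / 1000.0
        x_f = x_r = 0.0
        if spec.extra_covariate == "distance2":
            x_f = x_r = d**2
        elif spec.extra_covariate == "blind_spot":
            x_r = 1.0 if o.distance_m <= BLIND_SPOT_M else 0.0
        elif spec.extra_covariate == "distance_position":
            x_r = d
        b2 = coef[3] if len(coef) > 3 else 0.0
        pf = expit(coef[0] + coef[2] * d + b2 * x_f)
        pr = expit(coef[1] + coef[2] * d + b2 * x_r)
        p_star = 1 - (1 - pf) * (1 - pr)
        if o.seen_front and o.seen_rear:
            num = pf * pr
        elif o.seen_front:
            num = pf * (1 - pr)
        else:
            num = (1 - pf) * pr
        total += np.log(num / p_star)
    return total


class TestConditionalLikelihood:
    def test_zero_coefficients_give_uniform_histories(self, kb_fixture):
        # pF = pR = 1/2 makes each of the three histories equally likely
        ll = mr_loglik([0.0, 0.0, 0.0], kb_fixture, MRModelSpec("none"))
        assert ll == pytest.approx(28 * np.log(1.0 / 3.0), abs=1e-12)

    def test_certain_front_detection_kills_rear_only(self, kb_fixture):
        # huge front intercept -> P(rear only) ~ 0 and the fixture has rear-only rows
        ll = mr_loglik([30.0, 0.0, 0.0], kb_fixture, MRModelSpec("none"))
        assert ll < 28 * np.log(1.0 / 3.0) - 100

    @pytest.mark.parametrize("extra", ["none", "distance2", "blind_spot", "distance_position"])
    def test_matches_direct_sum_oracle(self, kb_fixture, extra):
        spec = MRModelSpec(extra)
        rng = np.random.default_rng(42)
        for _ in range(5):
            coef = rng.normal(scale=1.0, size=spec.k)
            assert mr_loglik(coef, kb_fixture, spec) == pytest.approx(
                brute_force_loglik(coef, kb_fixture, spec), abs=1e-10
            )

    @given(
        b0f=st.floats(-3, 3), b0r=st.floats(-3, 3), b1=st.floats(-3, 1),
        d=st.floats(0, 1400),
    )
    @settings(max_examples=50, deadline=None)
    def test_history_probabilities_normalize(self, b0f, b0r, b1, d):
        pf = expit(b0f + b1 * d / 1000)
        pr = expit(b0r + b1 * d / 1000)
        p_star = 1 - (1 - pf) * (1 - pr)
        total = (pf * (1 - pr) + (1 - pf) * pr + pf * pr) / p_star
        assert total == pytest.approx(1.0, abs=1e-12)


class TestP0Star:
    def test_published_worked_examples(self):
        assert p0_star(0.842, 0.727)[0] == pytest.approx(0.957, abs=5e-4)
        assert p0_star(0.891, 0.774)[0] == pytest.approx(0.975, abs=5e-4)

    def test_certain_front_detection(self):
        assert p0_star(1.0, 0.3)[0] == 1.0

    def test_delta_method_se_with_independent_components(self):
        value, se = p0_star(0.8, 0.6, var_f=0.01, var_r=0.04)
        # gradient (1-pR, 1-pF) = (0.4, 0.2)
        assert value == pytest.approx(0.92)
        assert se == pytest.approx(np.sqrt(0.16 * 0.01 + 0.04 * 0.04))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            p0_star(0.0, 0.5)

    @given(
        pf=st.floats(0.05, 1.0), pr=st.floats(0.05, 1.0), bump=st.floats(0.0, 0.2)
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_dominates_each_argument(self, pf, pr, bump):
        base = p0_star(pf, pr)[0]
        assert base >= max(pf, pr) - 1e-12
        assert p0_star(min(pf + bump, 1.0), pr)[0] >= base - 1e-12


class TestFitMR:
    def test_parameter_recovery_within_3_se(self):
        truth = np.array([1.0, 0.5, -1.0])
        ds = simulate_capture_histories(np.random.default_rng(7), 2000, *truth)
        fit = fit_mr(ds, MRModelSpec("none"), seed=0)
        se = np.sqrt(np.diag(fit.vcov))
        assert np.all(np.abs(fit.coefficients - truth) < 3 * se)
        assert fit.p0_star >= max(fit.p0_front, fit.p0_rear)

    def test_aicc_uses_detected_cluster_count(self, kb_fixture):
        fit = fit_mr(kb_fixture, MRModelSpec("none"), seed=0)
        assert fit.aicc == pytest.approx(aicc(fit.loglik, 3, 28))
        # small-sample penalty for k=3, n=28 is exactly 2*3*4/(28-4)
        assert fit.aicc - (-2 * fit.loglik + 6) == pytest.approx(1.0)

    def test_nesting_never_decreases_loglik(self, kb_fixture):
        base = fit_mr(kb_fixture, MRModelSpec("none"), seed=0)
        for extra in ("distance2", "distance_position"):
            nested = fit_mr(kb_fixture, MRModelSpec(extra), seed=0)
            assert nested.loglik >= base.loglik - 1e-6

    def test_degenerate_rear_subset_flagged(self):
        # rear observer saw exactly the clusters the front saw: no asymmetry
        tr = TransectRecord(id="T1", stratum_id="s", length_km=5.0, design_order=0)
        st_ = StratumSpec(id="s", area_km2=10.0)
        obs = tuple(
            ClusterObservation(id=f"o{i}", transect_id="T1", stratum_id="s",
                               distance_m=50.0 * i, seen_front=1, seen_rear=1)
            for i in range(12)
        )
        fit = fit_mr(SurveyDataset(obs, (tr,), (st_,)), MRModelSpec("none"), seed=0)
        assert not fit.identifiable

    def test_wald_coverage_of_distance_slope(self):
        """95% Wald intervals for the shared slope cover truth at nominal rate."""
        truth = np.array([1.0, 0.5, -1.0])
        hits = 0
        n_reps = 200
        for rep in range(n_reps):
            ds = simulate_capture_histories(np.random.default_rng(1000 + rep), 400, *truth)
            fit = fit_mr(ds, MRModelSpec("none"), n_starts=2, seed=rep)
            se = np.sqrt(fit.vcov[2, 2])
            hits += abs(fit.coefficients[2] - truth[2]) < 1.96 * se
        assert 0.90 <= hits / n_reps <= 0.99


class TestModelSet:
    def test_weights_sum_to_one_on_full_covariate_data(self):
        ds = simulate_capture_histories(np.random.default_rng(3), 400, 1.0, 0.5, -1.0)
        result = mr_model_set(ds, seed=0)
        assert len(result.fits) == 9
        assert sum(f.weight for f in result.fits) == pytest.approx(1.0)
        assert result.fits[0].delta_aicc == 0.0

    def test_fixture_without_covariates_raises_documented_error(self, kb_fixture):
        with pytest.raises(CovariateMissingError):
            fit_mr(kb_fixture, MRModelSpec("ice_rough"), seed=0)
        result = mr_model_set(kb_fixture, seed=0)
        assert "ice_rough" in result.failures
        assert all(f.label not in ("ice_rough", "activity") for f in result.fits)

    def test_true_ice_effect_ranks_first(self):
        """A real rough-ice effect should win the AICc ranking in most replicates."""
        wins = 0
        n_reps = 50
        for rep in range(n_reps):
            ds = simulate_capture_histories(
                np.random.default_rng(500 + rep), 1000, 1.0, 0.5, -1.0, ice_beta=-1.0
            )
            result = mr_model_set(ds, seed=rep)
            wins += result.fits[0].label == "ice_rough"
        assert wins / n_reps >= 0.80


class TestGoodnessOfFit:
    def test_perfect_agreement_gives_zero(self):
        # capture histories exactly matching the all-zero-coefficient model:
        # equal counts of the three histories in one bin
        tr = TransectRecord(id="T1", stratum_id="s", length_km=5.0, design_order=0)
        st_ = StratumSpec(id="s", area_km2=10.0)
        obs = []
        i = 0
        for mid in (100.0, 300.0, 500.0, 700.0, 900.0):
            for sf, sr in [(1, 0), (0, 1), (1, 1)]:
                obs.append(
                    ClusterObservation(id=f"o{i}", transect_id="T1", stratum_id="s",
                                       distance_m=mid, seen_front=sf, seen_rear=sr)
                )
                i += 1
        ds = SurveyDataset(tuple(obs), (tr,), (st_,))
        fit = fit_mr(ds, MRModelSpec("none"), seed=0)
        chi2, df, p = mr_gof(fit, ds, bin_width_m=200.0)
        assert chi2 == pytest.approx(0.0, abs=1e-4)

    def test_statistic_near_df_under_null(self):
        """Mean Pearson statistic over null replicates tracks the mean df."""
        stats_, dfs = [], []
        for rep in range(100):
            ds = simulate_capture_histories(
                np.random.default_rng(2000 + rep), 150, 1.0, 0.5, -1.0
            )
            fit = fit_mr(ds, MRModelSpec("none"), n_starts=2, seed=rep)
            chi2, df, _ = mr_gof(fit, ds, bin_width_m=200.0)
            stats_.append(chi2)
            dfs.append(df)
        ratio = np.mean(stats_) / np.mean(dfs)
        assert 0.7 <= ratio <= 1.3

    def test_pooling_reduces_df_on_sparse_fixture(self, kb_fixture):
        # without pooling the 7-bin double-observer table would carry
        # 2*7 - 3 = 11 df; sparse far bins must pool, shrinking df
        fit = fit_mr(kb_fixture, MRModelSpec("none"), seed=0)
        chi2, df, p = mr_gof(fit, kb_fixture, bin_width_m=200.0)
        assert 1 <= df < 11
        assert 0 <= p <= 1
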