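"""Virtual-cohort generation: population sampling, observation noise,
aggregation, missingness, and the mAb cohort."""

import numpy as np
import pandas as pd
import pytest

from dpinns import cohort as ch
from dpinns.moments import ResidualModel


class TestPopulationSpec:
    def test_log_scale_matches_specified_moments(self, rng):
        spec = ch.PopulationSpec(names=["Vd", "ke"],
                                 means=[15.0, ch.KE_MEAN],
                                 cvs=[0.10, 0.40], rho=0.0)
        mu, omega = spec.log_scale()
        draws = np.exp(rng.multivariate_normal(mu, omega, size=500_000))
        np.testing.assert_allclose(draws.mean(axis=0),
                                   [15.0, ch.KE_MEAN], rtol=5e-3)
        cv = draws.std(axis=0, ddof=1) / draws.mean(axis=0)
        np.testing.assert_allclose(cv, [0.10, 0.40], rtol=2e-2)

    def test_non_psd_rho_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        spec = ch.PopulationSpec(names=["a", "b"], means=[1.0, 1.0],
                                 cvs=[0.1, 0.1], rho=bad)
        with pytest.raises(ValueError):
            spec.correlation_matrix()

    def test_zero_correlation_in_draws(self):
        spec = ch.PopulationSpec(names=["Vd", "ke"],
                                 means=[15.0, 0.115], cvs=[0.1, 0.4],
                                 rho=0.0, n_subjects=2)
        draws = ch.sample_parameters(
            ch.PopulationSpec(names=spec.names, means=spec.means,
                              cvs=spec.cvs, rho=0.0, n_subjects=100_000), 0)
        r = np.corrcoef(np.log(draws["Vd"]), np.log(draws["ke"]))[0, 1]
        assert abs(r) < 0.01


class TestSimulateObservations:
    def _draws(self):
        return pd.DataFrame({"Vd": [15.0, 12.0], "ke": [ch.KE_MEAN, 0.1]})

    def test_noise_free_matches_closed_form(self):
        sched = ch.SamplingSchedule(np.array([0.5, 6.0, 24.0]))
        cohort = ch.simulate_observations(self._draws(), sched, 300.0,
                                          ResidualModel(0.0), seed=0)
        np.testing.assert_array_equal(cohort.profiles_observed,
                                      cohort.profiles_true)
        # subject 1: Vd=15, ke=ln2/6 -> one half-life at 6 h
        assert cohort.profiles_true[0, 1] == pytest.approx(10.0)

    def test_log_residual_sd_matches_sigma(self):
        n = 400
        draws = pd.DataFrame({"Vd": np.full(n, 15.0),
                              "ke": np.full(n, ch.KE_MEAN)})
        sched = ch.SamplingSchedule(ch.CASE1_SCHEDULE)
        cohort = ch.simulate_observations(draws, sched, 300.0,
                                          ResidualModel(0.1), seed=1)
        resid = np.log(cohort.profiles_observed / cohort.profiles_true)
        assert resid.std(ddof=1) == pytest.approx(0.1, rel=0.05)

    def test_frozen_noise_reused_across_scenarios(self):
        sched = ch.SamplingSchedule(np.array([1.0, 2.0]))
        eps = np.full((2, 2), 0.05)
        a = ch.simulate_observations(self._draws(), sched, 300.0,
                                     ResidualModel(0.1), seed=0, eps=eps)
        b = ch.simulate_observations(self._draws(), sched, 300.0,
                                     ResidualModel(0.1), seed=99, eps=eps)
        np.testing.assert_array_equal(a.profiles_observed,
                                      b.profiles_observed)


class TestAggregate:
    def test_hand_computed_mean_and_unbiased_variance(self):
        cohort = ch.CohortData(
            times=np.array([1.0]), parameters=pd.DataFrame(),
            profiles_true=np.array([[1.0], [3.0]]),
            profiles_observed=np.array([[1.0], [3.0]]))
        agg = ch.aggregate(cohort)
        assert agg.mean[0] == pytest.approx(2.0)
        assert agg.variance[0] == pytest.approx(2.0)
        assert agg.n[0] == 2

    def test_identical_values_zero_variance(self):
        cohort = ch.CohortData(
            times=np.array([1.0]), parameters=pd.DataFrame(),
            profiles_true=np.full((5, 1), 4.2),
            profiles_observed=np.full((5, 1), 4.2))
        assert ch.aggregate(cohort).variance[0] == 0.0

    def test_masked_subject_excluded_matches_two_subject_summary(self):
        obs = np.array([[1.0, 5.0], [3.0, 6.0], [10.0, 7.0]])
        mask = np.array([[True, True], [True, True], [False, True]])
        cohort = ch.CohortData(times=np.array([1.0, 2.0]),
                               parameters=pd.DataFrame(),
                               profiles_true=obs, profiles_observed=obs,
                               mask=mask)
        agg = ch.aggregate(cohort)
        assert agg.mean[0] == pytest.approx(2.0)
        assert agg.variance[0] == pytest.approx(2.0)
        assert agg.n[0] == 2
        assert agg.mean[1] == pytest.approx(6.0)
        assert agg.n[1] == 3

    def test_underpopulated_time_dropped_with_warning(self):
        obs = np.ones((2, 2))
        mask = np.array([[True, False], [True, False]])
        cohort = ch.CohortData(times=np.array([1.0, 2.0]),
                               parameters=pd.DataFrame(),
                               profiles_true=obs, profiles_observed=obs,
                               mask=mask)
        with pytest.warns(UserWarning):
            agg = ch.aggregate(cohort)
        assert len(agg.times) == 1


class TestMaskMissing:
    def test_zero_fraction_keeps_everything(self, rng):
        cohort, _ = ch.simulate_onecomp_cohort(seed=0)
        masked = ch.mask_missing(cohort, 0.0, seed=1)
        assert masked.mask.all()

    def test_half_fraction_exact_count_and_determinism(self):
        cohort, _ = ch.simulate_onecomp_cohort(seed=0)
        m1 = ch.mask_missing(cohort, 0.5, seed=1)
        m2 = ch.mask_missing(cohort, 0.5, seed=1)
        assert (~m1.mask).sum() == 90  # half of the 30 x 6 grid
        np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_invalid_fraction(self):
        cohort, _ = ch.simulate_onecomp_cohort(seed=0)
        with pytest.raises(ValueError):
            ch.mask_missing(cohort, 1.0, seed=0)


class TestOneCompCohortPipeline:
    def test_default_study_conditions(self, case1_data):
        cohort, agg = case1_data
        assert cohort.profiles_observed.shape == (30, 6)
        np.testing.assert_array_equal(agg.times, ch.CASE1_SCHEDULE)
        assert np.all(agg.n == 30)

    def test_reproducible_under_seed(self):
        _, a = ch.simulate_onecomp_cohort(seed=11)
        _, b = ch.simulate_onecomp_cohort(seed=11)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.variance, b.variance)

    def test_se_tightens_with_cohort_size(self):
        # aggregated-mean dispersion across replicates shrinks ~ 1/sqrt(n)
        cfg = ch.CASE1_POPULATION
        disp = {}
        for n in (30, 480):
            means = []
            for rep in range(24):
                spec = ch.PopulationSpec(names=cfg["names"],
                                         means=cfg["means"], cvs=cfg["cvs"],
                                         rho=0.0, sigma=0.1, n_subjects=n)
                _, agg = ch.simulate_onecomp_cohort(seed=1000 + rep, spec=spec)
                means.append(agg.mean[0])
            disp[n] = np.std(means, ddof=1)
        ratio = disp[30] / disp[480]
        assert ratio == pytest.approx(4.0, rel=0.5)  # sqrt(480/30) = 4


class TestMabCohort:
    def test_dose_scales_linearly_with_body_weight(self):
        cohort, _ = ch.simulate_mab_cohort(seed=4, n_subjects=12)
        np.testing.assert_allclose(cohort.parameters["dose"],
                                   cohort.parameters["body_weight"], rtol=1e-12)

    def test_degenerate_clearance_single_weight_no_biological_variance(self):
        cohort, _ = ch.simulate_mab_cohort(seed=0, n_subjects=5,
                                           weight_range=(70.0, 70.0 + 1e-12),
                                           cl_sd=1e-12, sigma=0.0)
        assert np.allclose(cohort.profiles_true.std(axis=0), 0.0, atol=1e-8)

    def test_cmax_at_end_of_infusion(self):
        sched = ch.SamplingSchedule(
            np.array([0.5, 1.0, 1.5, 2.0, 4.0, 24.0, 168.0]))
        cohort, _ = ch.simulate_mab_cohort(seed=3, n_subjects=8, sigma=0.0,
                                           schedule=sched)
        assert np.all(np.argmax(cohort.profiles_true, axis=1) == 2)
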