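"""Progression model: curves, calibration recovery, personalization,
forecasting and serialization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from coursemap.model import (CalibrationError, CourseMap, IndividualEffects,
                             average_instances, individual_curve, time_reparam,
                             _objective, _pack)
from coursemap.simulate import (CohortSpec, SimConfig, default_population_params,
                                simulate_cohorts, simulation_normalizer)
from conftest import NO_MISSING, SIM_ENDPOINTS


class TestTimeReparam:
    def test_identity_warp(self):
        t = np.linspace(50, 90, 7)
        assert np.allclose(time_reparam(t, 0.0, 0.0, 75.0), t)

    def test_doubled_pace(self):
        assert time_reparam(79.0, np.log(2.0), 0.0, 75.0) == pytest.approx(83.0)

    def test_pure_shift_delays_events(self):
        # with tau = 5 the disease age reached at t is reached at t+5 instead
        psi_ref = time_reparam(72.0, 0.0, 0.0, 75.0)
        assert time_reparam(77.0, 0.0, 5.0, 75.0) == pytest.approx(psi_ref)


class TestIndividualCurve:
    @pytest.fixture
    def params(self):
        return default_population_params(list(SIM_ENDPOINTS[:4]), seed=1)

    def test_inflexion_at_half(self, params):
        effects = IndividualEffects.null(params)
        t = params.t0 + params.delta[2]
        assert individual_curve(t, params, effects, 2) == pytest.approx(0.5)

    def test_null_effects_give_population_curve(self, params):
        effects = IndividualEffects.null(params)
        ages = np.linspace(60, 95, 20)
        for k in range(params.n_endpoints):
            pop = 1.0 / (1.0 + np.exp(-params.rates[k] * (ages - params.t0 - params.delta[k])))
            assert np.allclose(individual_curve(ages, params, effects, k), pop)

    def test_space_shift_symmetric_on_logit_scale(self, params):
        from scipy.special import logit
        c = 0.7
        plus = dataclasses.replace(IndividualEffects.null(params))
        plus.space_shift = np.full(params.n_endpoints, c)
        minus = dataclasses.replace(IndividualEffects.null(params))
        minus.space_shift = np.full(params.n_endpoints, -c)
        v_plus = individual_curve(80.0, params, plus, 1)
        v_minus = individual_curve(80.0, params, minus, 1)
        base = logit(individual_curve(80.0, params, IndividualEffects.null(params), 1))
        assert logit(v_plus) - base == pytest.approx(base - logit(v_minus))


class TestAverageInstances:
    def _frame(self, values):
        return pd.DataFrame({"mmse": values}, index=pd.Index([78.0, 80.0], name="age"))

    def test_idempotent_and_arithmetic(self):
        f = self._frame([24.0, 28.0])
        assert average_instances([f, f]).equals(f)
        two = average_instances([self._frame([24.0, 24.0]), self._frame([28.0, 28.0])])
        assert np.allclose(two["mmse"], 26.0)

    def test_permutation_invariant(self):
        frames = [self._frame([20.0 + i, 25.0 + i]) for i in range(4)]
        fwd = average_instances(frames)
        rev = average_instances(frames[::-1])
        pd.testing.assert_frame_equal(fwd, rev)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_instances([self._frame([1, 2]),
                               self._frame([1, 2]).rename(columns={"mmse": "adas13"})])


class TestCalibration:
    def test_recovery_on_known_truth(self, dense_cohort, fitted_model):
        table, truth = dense_cohort
        est, tru = fitted_model.params_, truth.params
        assert abs(est.t0 - tru.t0) < 1.5
        assert list(np.argsort(est.delta)) == list(np.argsort(tru.delta))
        assert np.all(np.abs(est.rates - tru.rates) / tru.rates < 0.2)
        assert abs(est.sigma_tau - tru.sigma_tau) / tru.sigma_tau < 0.3

    def test_degenerate_heterogeneity_recovered_as_zero(self):
        cfg = SimConfig(cohorts=(CohortSpec("SIM", 80),), endpoints=SIM_ENDPOINTS[:3],
                        sigma_xi=0.0, sigma_tau=0.0, source_scale=0.0,
                        visit_count_range=(5, 6), missingness=NO_MISSING, seed=9)
        table, truth = simulate_cohorts(cfg)
        model = CourseMap(n_sources=2, endpoints=list(SIM_ENDPOINTS[:3]),
                          normalizer=simulation_normalizer(SIM_ENDPOINTS[:3]),
                          max_outer=15).fit(table.to_frame())
        assert model.params_.sigma_xi < 0.08
        assert model.params_.sigma_tau < 1.0

    def test_time_dilation_halves_rates(self, dense_cohort, fitted_model):
        """Dilating all age offsets from t0 by 2 must halve the recovered
        logistic rates (time-rescaling oracle)."""
        table, truth = dense_cohort
        frame = table.to_frame()
        t0 = truth.params.t0
        dilated = frame.assign(age=t0 + 2.0 * (frame["age"] - t0))
        endpoints = list(truth.params.endpoints)
        model2 = CourseMap(n_sources=2, endpoints=endpoints,
                           normalizer=simulation_normalizer(endpoints),
                           max_outer=20).fit(dilated)
        ratio = model2.params_.rates / fitted_model.params_.rates
        assert np.all(np.abs(ratio - 0.5) < 0.1)

    def test_all_missing_endpoint_is_error(self, dense_cohort):
        table, truth = dense_cohort
        frame = table.to_frame()
        frame["tau_pet_suvr"] = np.nan
        with pytest.raises(CalibrationError, match="tau_pet_suvr"):
            CourseMap(endpoints=[*truth.params.endpoints, "tau_pet_suvr"]
                      ).fit(frame)

    def test_masked_objective_equals_bruteforce_subvector_sum(self, dense_cohort):
        """The missing-data likelihood is the likelihood of the observed
        sub-vector: compare the packed masked objective with an explicit
        loop over observed entries."""
        table, truth = dense_cohort
        frame = table.to_frame().head(40).copy()
        rng = np.random.default_rng(0)
        endpoints = list(truth.params.endpoints)
        for name in endpoints:
            frame.loc[rng.random(len(frame)) < 0.4, name] = np.nan
        frame = simulation_normalizer(endpoints).transform(frame)
        packed = _pack(frame, endpoints)
        N, J, K = packed.Y.shape
        q = 2
        rng = np.random.default_rng(1)
        theta = np.concatenate([
            [75.0], np.log(rng.uniform(0.1, 0.3, K)), rng.normal(0, 3, K),
            rng.normal(0, 0.2, K * q), rng.normal(0, 0.2, N), rng.normal(0, 2, N),
            rng.normal(0, 1, N * q)])
        sig_k = np.full(K, 0.05)
        loss, _ = _objective(theta, packed, sig_k, 0.3, 5.0, False)

        from coursemap.model import _unpack_theta
        from scipy.special import expit
        t0, a, delta, A, xi, tau, s = _unpack_theta(theta, N, K, q)
        brute = 0.0
        for i in range(N):
            for j in range(J):
                for k in range(K):
                    if packed.M[i, j, k]:
                        z = np.exp(xi[i]) * (packed.T[i, j] - t0 - tau[i])
                        u = a[k] * (z - delta[k]) + A[k] @ s[i]
                        brute += (packed.Y[i, j, k] - expit(u)) ** 2 / (2 * sig_k[k] ** 2)
        brute += np.sum(xi ** 2) / (2 * 0.3 ** 2) + np.sum(tau ** 2) / (2 * 5.0 ** 2) \
            + 0.5 * np.sum(s ** 2)
        assert loss == pytest.approx(brute, rel=1e-10)


def small_noise_clone(model, sigma=1e-4):
    """Same curves, near-zero observation noise: the MAP prior becomes
    negligible and noiseless data pin the effects down."""
    clone = CourseMap(n_sources=model.n_sources, normalizer=model.normalizer,
                      endpoints=model.endpoints_)
    clone.params_ = dataclasses.replace(
        model.params_, sigma_noise=np.full(model.params_.n_endpoints, sigma))
    clone.endpoints_ = model.endpoints_
    clone.effects_ = {}
    clone.history_ = []
    clone.n_iter_ = 0
    clone.converged_ = True
    return clone


class TestPersonalization:
    def _noiseless_subject(self, truth_model, xi=0.25, tau=3.0, s=(0.8, -0.5),
                           ages=(74.0, 76.0, 78.0, 80.0)):
        pp = truth_model.params_
        effects = IndividualEffects(xi, tau, np.asarray(s), pp.mixing @ np.asarray(s))
        frame = truth_model.forecast(effects, list(ages))
        frame = frame.reset_index().assign(subject_id="probe")
        return effects, frame

    def test_recovers_known_effects_as_noise_vanishes(self, truth_model):
        sharp = small_noise_clone(truth_model)
        true_effects, visits = self._noiseless_subject(sharp)
        est = sharp.personalize(visits)
        assert est.xi == pytest.approx(true_effects.xi, abs=1e-2)
        assert est.tau == pytest.approx(true_effects.tau, abs=1e-1)
        assert np.allclose(est.sources, true_effects.sources, atol=1e-2)

    def test_sparse_data_shrinks_toward_prior(self, truth_model):
        _, visits = self._noiseless_subject(truth_model)
        dense = truth_model.personalize(visits)
        single = visits.iloc[[0]][["subject_id", "age", "mmse"]]
        sparse = truth_model.personalize(single)
        assert abs(sparse.xi) < abs(dense.xi)
        assert abs(sparse.tau) < abs(dense.tau)

    def test_missing_modalities_need_no_imputation(self, truth_model):
        _, visits = self._noiseless_subject(truth_model)
        visits = visits.drop(columns=["csf_abeta42"], errors="ignore")
        visits["hippocampus_icv"] = np.nan
        effects = truth_model.personalize(visits)
        assert np.isfinite([effects.xi, effects.tau]).all()

    def test_no_observation_at_all_is_error(self, truth_model):
        empty = pd.DataFrame({"subject_id": ["p"], "age": [70.0],
                              "mmse": [np.nan]})
        with pytest.raises(ValueError, match="no observed measurement"):
            truth_model.personalize(empty)

    def test_objective_decreases_monotonically(self, truth_model):
        _, visits = self._noiseless_subject(truth_model)
        trace = []
        truth_model.personalize(visits, trace=trace)
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-9)


class TestForecast:
    def test_self_consistency_at_observed_ages(self, truth_model):
        sharp = small_noise_clone(truth_model)
        pp = sharp.params_
        s = np.array([0.5, 0.2])
        effects = IndividualEffects(0.1, -2.0, s, pp.mixing @ s)
        ages = [73.0, 75.0, 77.0]
        observed = sharp.forecast(effects, ages).reset_index()
        observed["subject_id"] = "probe"
        est = sharp.personalize(observed)
        refc = sharp.forecast(est, ages).reset_index()
        for name in sharp.endpoints_:
            assert np.allclose(refc[name], observed[name], atol=1e-3)

    def test_pathology_monotone_over_age(self, truth_model):
        effects = IndividualEffects.null(truth_model.params_)
        ages = np.linspace(60, 95, 30)
        fc = truth_model.forecast(effects, ages)
        assert np.all(np.diff(fc["mmse"]) <= 1e-12)       # MMSE declines
        assert np.all(np.diff(fc["adas13"]) >= -1e-12)    # ADAS rises

    def test_mmse_forecast_stays_on_scale(self, truth_model):
        pp = truth_model.params_
        s = np.array([2.0, -2.0])
        effects = IndividualEffects(1.0, -10.0, s, pp.mixing @ s)
        fc = truth_model.forecast(effects, np.linspace(50, 110, 50))
        assert fc["mmse"].between(0.0, 30.0).all()

    def test_vanishing_heterogeneity_returns_population_curve(self, truth_model):
        tight = CourseMap(n_sources=2, normalizer=truth_model.normalizer,
                          endpoints=truth_model.endpoints_)
        # source variance is carried by the mixing columns, so vanishing
        # heterogeneity means shrinking those too
        tight.params_ = dataclasses.replace(truth_model.params_,
                                            sigma_xi=1e-6, sigma_tau=1e-6,
                                            mixing=truth_model.params_.mixing * 1e-6)
        tight.endpoints_ = truth_model.endpoints_
        _, visits = TestPersonalization()._noiseless_subject(truth_model)
        effects = tight.personalize(visits)
        fc = tight.forecast(effects, [80.0])
        pop = tight.population_curve([80.0])
        assert np.allclose(fc.to_numpy(), pop.to_numpy(), atol=0.02)


class TestSerialization:
    def test_roundtrip_reproduces_forecasts_bit_identically(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        fitted_model.to_json(path)
        clone = CourseMap.from_json(path)
        visits = pd.DataFrame({"subject_id": ["p"] * 2, "age": [72.0, 73.0],
                               "mmse": [28.0, 27.0], "adas13": [12.0, 14.0]})
        a = fitted_model.predict(visits, [76.0, 78.0])
        b = clone.predict(visits, [76.0, 78.0])
        assert (a.to_numpy() == b.to_numpy()).all()
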