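"""State-space construction and the exact Kalman log-likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import arma_autocov, arwn_autocov, mvn_loglik
from noisyar import (
    ARMAParams,
    ARWNParams,
    StationarityError,
    TimeSeries,
    arwn_to_arma,
    build_statespace,
    filtered_states,
    inject_missing,
    kalman_loglik,
    simulate_arwn,
)
from noisyar.ml import loglik_function

valid_arwn = st.builds(
    ARWNParams,
    mu=st.floats(-3.0, 3.0),
    phi=st.floats(-0.95, 0.95),
    sigma2_eps=st.floats(0.05, 4.0),
    sigma2_omega=st.floats(0.0, 4.0),
)
valid_arma = st.builds(
    ARMAParams,
    mu=st.floats(-3.0, 3.0),
    phi=st.floats(-0.95, 0.95),
    theta=st.floats(-0.95, 0.95),
    sigma2_eps_star=st.floats(0.05, 4.0),
)


class TestBuild:
    def test_arwn_scalar_system(self, arwn_params):
        spec = build_statespace("ARWN", arwn_params)
        assert spec.r == 1
        assert spec.Sigma_omega[0, 0] == 0.5
        assert spec.A[0, 0] == 0.5

    def test_ar1_has_no_observation_noise(self):
        spec = build_statespace("AR1", ARWNParams(1.0, 0.3, 0.7, 0.9))
        assert spec.Sigma_omega[0, 0] == 0.0

    def test_arma_stationary_covariance_matches_closed_form(self):
        a = ARMAParams(0.0, 0.5, -0.2, 1.0)
        spec = build_statespace("ARMA11", a)
        _, P = spec.stationary_state()
        # observed component variance is gamma_0; one-step A P A' + Q gives gamma_1
        assert P[0, 0] == pytest.approx(arma_autocov(a, 0), abs=1e-10)
        g1 = (spec.A @ P)[0, 0]
        assert g1 == pytest.approx(arma_autocov(a, 1), abs=1e-10)

    def test_nonstationary_rejected(self):
        spec_ok = build_statespace("AR1", ARWNParams(0.0, 0.5, 1.0, 0.0))
        with pytest.raises(StationarityError):
            type(spec_ok)(
                d=spec_ok.d, F=spec_ok.F, Sigma_omega=spec_ok.Sigma_omega,
                c=spec_ok.c, A=np.array([[1.01]]), Sigma_eps=spec_ok.Sigma_eps,
            )


class TestLoglik:
    def test_iid_case(self):
        # phi=0: observations are iid Normal(mu, s2e + s2w)
        p = ARWNParams(2.0, 0.0, 0.6, 0.4)
        ts = simulate_arwn(p, 30, seed=2)
        ll = kalman_loglik(build_statespace("ARWN", p), ts)
        expected = stats.norm.logpdf(ts.values, loc=2.0, scale=1.0).sum()
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_matches_mvn_oracle(self, arwn_params, short_series):
        ll = kalman_loglik(build_statespace("ARWN", arwn_params), short_series)
        oracle = mvn_loglik(short_series, 2.0, lambda h: arwn_autocov(arwn_params, h))
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_missing_marginalizes(self, arwn_params, short_series):
        holey = TimeSeries(short_series.values.copy())
        holey.values[[2, 4]] = np.nan
        ll = kalman_loglik(build_statespace("ARWN", arwn_params), holey)
        oracle = mvn_loglik(holey, 2.0, lambda h: arwn_autocov(arwn_params, h))
        assert ll == pytest.approx(oracle, abs=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(p=valid_arwn, seed=st.integers(0, 1000))
    def test_arwn_equals_mvn_oracle_everywhere(self, p, seed):
        ts = inject_missing(simulate_arwn(p, 15, seed=seed), 2, seed=seed + 1)
        ll = kalman_loglik(build_statespace("ARWN", p), ts)
        oracle = mvn_loglik(ts, p.mu, lambda h: arwn_autocov(p, h))
        assert ll == pytest.approx(oracle, abs=1e-8)
        fast = loglik_function("ARWN", ts)(
            np.array([p.mu, p.phi, p.sigma2_eps, p.sigma2_omega])
        )
        assert fast == pytest.approx(oracle, abs=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(a=valid_arma, seed=st.integers(0, 1000))
    def test_arma_equals_mvn_oracle_everywhere(self, a, seed):
        ts = simulate_arwn(ARWNParams(a.mu, 0.3, 1.0, 0.5), 15, seed=seed)
        ll = kalman_loglik(build_statespace("ARMA11", a), ts)
        oracle = mvn_loglik(ts, a.mu, lambda h: arma_autocov(a, h))
        assert ll == pytest.approx(oracle, abs=1e-8)
        fast = loglik_function("ARMA11", ts)(
            np.array([a.mu, a.phi, a.theta, a.sigma2_eps_star])
        )
        assert fast == pytest.approx(oracle, abs=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(p=valid_arwn, seed=st.integers(0, 1000))
    def test_bridged_arma_loglik_equivalence(self, p, seed):
        # the AR(1)+WN likelihood and its bridged ARMA(1,1) twin agree on any series
        ts = simulate_arwn(p, 40, seed=seed)
        ll_arwn = kalman_loglik(build_statespace("ARWN", p), ts)
        ll_arma = kalman_loglik(build_statespace("ARMA11", arwn_to_arma(p)), ts)
        assert ll_arma == pytest.approx(ll_arwn, abs=1e-6)

    def test_all_missing_rejected(self, arwn_params):
        with pytest.raises(ValueError):
            kalman_loglik(build_statespace("ARWN", arwn_params),
                          TimeSeries(np.full(5, np.nan)))

    def test_statsmodels_cross_check(self):
        # independent engine: SARIMAX with exact stationary initialization
        sarimax = pytest.importorskip("statsmodels.tsa.statespace.sarimax")
        a = ARMAParams(0.0, 0.6, -0.3, 1.4)
        ts = simulate_arwn(ARWNParams(0.0, 0.6, 1.0, 0.3), 80, seed=13)
        mod = sarimax.SARIMAX(ts.values, order=(1, 0, 1))
        ref = float(mod.loglike(np.array([a.phi, a.theta, a.sigma2_eps_star])))
        ours = kalman_loglik(build_statespace("ARMA11", a), ts)
        assert ours == pytest.approx(ref, abs=1e-6)


class TestFilteredStates:
    def test_no_observation_noise_tracks_data(self):
        p = ARWNParams(2.0, 0.5, 0.5, 0.0)
        ts = simulate_arwn(p, 20, seed=3)
        res = filtered_states(build_statespace("ARWN", p), ts)
        np.testing.assert_allclose(res.filtered_mean[:, 0], ts.values - 2.0, atol=1e-10)
        np.testing.assert_allclose(res.filtered_cov[:, 0, 0], 0.0, atol=1e-10)

    def test_uninformative_observations_follow_prediction(self):
        p = ARWNParams(0.0, 0.5, 0.5, 1e6)
        ts = simulate_arwn(p, 20, seed=3)
        res = filtered_states(build_statespace("ARWN", p), ts)
        # the filter barely moves off the prediction when the data are pure
        # noise (observation sd is 1000, state movement stays below 0.01)
        np.testing.assert_allclose(res.filtered_mean, res.predicted_mean, atol=0.01)

    def test_manual_two_step_recursion(self):
        p = ARWNParams(0.0, 0.5, 1.0, 0.5)
        ts = TimeSeries(np.array([1.0, -0.5, 2.0]))
        res = filtered_states(build_statespace("ARWN", p), ts)
        # hand-rolled scalar filter
        x, P = 0.0, 1.0 / (1 - 0.25)
        means, variances = [], []
        for y in ts.values:
            F = P + 0.5
            K = P / F
            x = x + K * (y - x)
            P = P * (1 - K)
            means.append(x)
            variances.append(P)
            x, P = 0.5 * x, 0.25 * P + 1.0
        np.testing.assert_allclose(res.filtered_mean[:, 0], means, atol=1e-12)
        np.testing.assert_allclose(res.filtered_cov[:, 0, 0], variances, atol=1e-12)
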