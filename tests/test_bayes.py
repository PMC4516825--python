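"""MCMC estimation, convergence diagnostics, derived noise posteriors."""

import math

import numpy as np
import pandas as pd
import pytest

from noisyar import (
    ARWNParams,
    DegenerateProcessError,
    PriorSpec,
    arwn_to_arma,
    derived_noise_posterior,
    fit_bayes,
    fit_ml,
    gelman_rubin,
    posterior_coverage_interval,
    simulate_arwn,
)
from noisyar.bayes import PosteriorResult


@pytest.fixture(scope="module")
def long_fit(arwn_params=ARWNParams(2.0, 0.5, 0.5, 0.5)):
    """One long-series ARWN posterior shared across agreement tests."""
    ts = simulate_arwn(arwn_params, 2000, seed=11)
    priors = PriorSpec(var_prior_upper=20.0)
    post = fit_bayes("ARWN", ts, priors, n_chains=3, n_iter=4000, seed=5)
    ml = fit_ml("ARWN", ts, n_starts=5, seed=1)
    return arwn_params, ts, post, ml


class TestGelmanRubin:
    def test_common_distribution_is_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 10_000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 5000))
        chains[1] += 5.0
        assert gelman_rubin(chains) > 1.1

    def test_manual_arithmetic(self):
        # identical chains {1,2,3,4}: W=5/3, B=0, Vhat=(3/4)W -> sqrt(3/4)
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        assert gelman_rubin(chains) == pytest.approx(math.sqrt(0.75), abs=1e-12)

    def test_degenerate_chains(self):
        with pytest.raises(DegenerateProcessError):
            gelman_rubin(np.ones((2, 10)))

    def test_arviz_cross_check(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 2000))
        ours = gelman_rubin(chains)
        ref = float(az.rhat(az.convert_to_dataset(chains))["x"].values)
        assert ours == pytest.approx(ref, abs=0.05)


class TestCoverageInterval:
    def test_percentile_definition(self):
        draws = np.arange(1.0, 1001.0)
        lo, hi = posterior_coverage_interval(draws, 0.95)
        assert lo == pytest.approx(np.percentile(draws, 2.5))
        assert hi == pytest.approx(np.percentile(draws, 97.5))
        assert 25.0 < lo < 27.0 and 974.0 < hi < 976.0

    def test_constant_draws(self):
        lo, hi = posterior_coverage_interval(np.full(200, 3.3), 0.95)
        assert lo == hi == 3.3

    def test_level_one_spans_range(self):
        draws = np.arange(100.0)
        assert posterior_coverage_interval(draws, 1.0) == (0.0, 99.0)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            posterior_coverage_interval(np.arange(50.0), 0.95)


class TestFitBayes:
    def test_long_series_recovery_and_convergence(self, long_fit):
        p, _, post, _ = long_fit
        truth = {"mu": p.mu, "phi": p.phi, "sigma2_eps": p.sigma2_eps,
                 "sigma2_omega": p.sigma2_omega}
        for name, value in truth.items():
            sd = float(post.summary.loc[name, "sd"])
            assert abs(post.median(name) - value) < 3 * sd
            assert post.rhat[name] < 1.1

    def test_agrees_with_ml_on_long_series(self, long_fit):
        _, _, post, ml = long_fit
        for name in ml.estimates:
            assert abs(post.median(name) - ml.estimates[name]) < 2 * ml.se[name]

    def test_draws_respect_prior_support(self, long_fit):
        _, _, post, _ = long_fit
        assert np.all(np.abs(post.draws["phi"]) < 1.0)
        for name in ("sigma2_eps", "sigma2_omega"):
            d = post.draws[name]
            assert np.all(d > 0.0) and np.all(d < post.priors.var_prior_upper)

    def test_white_noise_posterior_centers_on_sample_mean(self):
        p = ARWNParams(3.0, 0.0, 1.0, 0.0)
        ts = simulate_arwn(p, 400, seed=15)
        post = fit_bayes("AR1", ts, PriorSpec(var_prior_upper=20.0),
                         n_chains=2, n_iter=2000, seed=2)
        assert post.median("mu") == pytest.approx(float(np.mean(ts.values)), abs=0.05)
        assert abs(post.median("phi")) < 0.15

    def test_reproducible(self):
        p = ARWNParams(2.0, 0.5, 0.5, 0.5)
        ts = simulate_arwn(p, 200, seed=16)
        priors = PriorSpec(var_prior_upper=20.0)
        a = fit_bayes("ARWN", ts, priors, n_chains=2, n_iter=1000, seed=9)
        b = fit_bayes("ARWN", ts, priors, n_chains=2, n_iter=1000, seed=9)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_arma_and_arwn_phi_intervals_overlap(self):
        p = ARWNParams(2.0, 0.5, 0.5, 0.5)
        ts = simulate_arwn(p, 300, seed=17)
        priors = PriorSpec(var_prior_upper=20.0)
        a = fit_bayes("ARWN", ts, priors, n_chains=2, n_iter=2000, seed=3)
        b = fit_bayes("ARMA11", ts, priors, n_chains=2, n_iter=2000, seed=4)
        lo_a, hi_a = a.credible_interval("phi")
        lo_b, hi_b = b.credible_interval("phi")
        assert max(lo_a, lo_b) <= min(hi_a, hi_b)

    def test_draws_frame_is_long_table(self):
        p = ARWNParams(2.0, 0.5, 0.5, 0.5)
        ts = simulate_arwn(p, 150, seed=18)
        post = fit_bayes("ARWN", ts, PriorSpec(var_prior_upper=20.0),
                         n_chains=2, n_iter=500, seed=6)
        df = post.draws_frame()
        assert set(df.columns) == {"chain", "iteration", "parameter", "value"}
        assert len(df) == 4 * 2 * post.n_iter


def _fake_arma_posterior(phi, theta, s2s):
    """Wrap given draw arrays in a PosteriorResult for the derived-noise map."""
    draws = {
        "mu": np.zeros_like(phi),
        "phi": phi,
        "theta": theta,
        "sigma2_eps_star": s2s,
    }
    return PosteriorResult(
        model="ARMA11", draws=draws, n_chains=phi.shape[0], n_iter=phi.shape[1],
        priors=PriorSpec(var_prior_upper=20.0), summary=pd.DataFrame(),
        rhat={}, autocorr={},
    )


class TestDerivedNoise:
    def test_zero_theta_gives_zero_noise(self):
        n = (2, 200)
        post = _fake_arma_posterior(np.full(n, 0.5), np.zeros(n), np.ones(n))
        der = derived_noise_posterior(post)
        np.testing.assert_allclose(der.draws["sigma2_omega"], 0.0)

    def test_worked_draw(self):
        post = _fake_arma_posterior(
            np.full((2, 100), 0.5), np.full((2, 100), -0.2), np.ones((2, 100))
        )
        der = derived_noise_posterior(post)
        assert der.draws["sigma2_omega"][0, 0] == pytest.approx(0.4, abs=1e-12)
        assert der.draws["sigma2_eps"][0, 0] == pytest.approx(0.54, abs=1e-12)

    def test_negative_draws_retained_and_counted(self):
        post = _fake_arma_posterior(
            np.full((2, 100), 0.5), np.full((2, 100), 0.3), np.ones((2, 100))
        )
        der = derived_noise_posterior(post)
        assert np.all(der.draws["sigma2_omega"] < 0.0)
        assert der.n_negative["sigma2_omega"] == 200

    def test_roundtrip_through_forward_bridge(self):
        rng = np.random.default_rng(4)
        phi = rng.uniform(0.2, 0.8, size=(1, 300))
        theta = rng.uniform(-0.5, -0.05, size=(1, 300))
        s2s = rng.uniform(0.5, 2.0, size=(1, 300))
        der = derived_noise_posterior(_fake_arma_posterior(phi, theta, s2s))
        for i in range(300):
            s2w = der.draws["sigma2_omega"][0, i]
            s2e = der.draws["sigma2_eps"][0, i]
            if s2w < 0 or s2e < 0:
                continue
            a = arwn_to_arma(ARWNParams(0.0, phi[0, i], s2e, s2w))
            assert a.theta == pytest.approx(theta[0, i], abs=1e-10)
            assert a.sigma2_eps_star == pytest.approx(s2s[0, i], abs=1e-10)
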