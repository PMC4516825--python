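"""Shared fixtures and independent closed-form oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from noisyar import ARMAParams, ARWNParams, TimeSeries, simulate_arwn


@pytest.fixture
def arwn_params() -> ARWNParams:
    """The workhorse generating condition: mu=2, phi=0.5, both variances 0.5."""
    return ARWNParams(mu=2.0, phi=0.5, sigma2_eps=0.5, sigma2_omega=0.5)


@pytest.fixture
def short_series(arwn_params) -> TimeSeries:
    return simulate_arwn(arwn_params, 12, seed=3)


def arwn_autocov(p: ARWNParams, h: int) -> float:
    """Closed-form autocovariance of the observed AR(1)+WN process."""
    g = p.phi ** abs(h) * p.sigma2_eps / (1.0 - p.phi**2)
    return g + (p.sigma2_omega if h == 0 else 0.0)


def arma_autocov(a: ARMAParams, h: int) -> float:
    """Closed-form autocovariance of an ARMA(1,1) process."""
    s2, phi, th = a.sigma2_eps_star, a.phi, a.theta
    if h == 0:
        return s2 * (1.0 + th**2 + 2.0 * phi * th) / (1.0 - phi**2)
    g1 = s2 * (1.0 + phi * th) * (phi + th) / (1.0 - phi**2)
    return phi ** (abs(h) - 1) * g1


def mvn_loglik(ts: TimeSeries, mu: float, autocov) -> float:
    """Brute-force joint Gaussian log-density of the observed subvector.

    ``autocov(h)`` supplies the process autocovariance; missing occasions are
    marginalized by simply dropping their rows/columns.
    """
    idx = np.flatnonzero(ts.observed)
    lag = np.abs(np.subtract.outer(idx, idx))
    cov = np.vectorize(autocov)(lag).astype(float)
    return float(
        stats.multivariate_normal.logpdf(ts.values[idx], mean=np.full(idx.size, mu), cov=cov)
    )
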