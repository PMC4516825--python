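"""Numba-compiled Kalman prediction-error log-likelihood kernels.

These are the hot paths behind ML optimization and MCMC: a scalar-state filter
for AR(1)/AR(1)+WN and a 2-state filter for ARMA(1,1) in Harvey form.  Both
initialize at the exact stationary state distribution, skip the measurement
update at missing occasions, and return -inf for invalid parameter points so
callers can treat them as zero-likelihood.  The generic matrix filter in
:mod:`noisyar.statespace` is the reference; agreement is enforced by tests.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_LOG2PI = math.log(2.0 * math.pi)


@njit(cache=False)
def arwn_loglik(y, obs, mu, phi, s2e, s2w):  # pragma: no cover - compiled
    """Exact Gaussian log-likelihood of an AR(1)+WN model (s2w=0 gives AR(1))."""
    if abs(phi) >= 1.0 or s2e < 0.0 or s2w < 0.0:
        return -np.inf
    n = y.shape[0]
    x = 0.0
    P = s2e / (1.0 - phi * phi)
    ll = 0.0
    for t in range(n):
        if obs[t]:
            F = P + s2w
            if F <= 0.0:
                return -np.inf
            v = y[t] - mu - x
            ll += -0.5 * (_LOG2PI + math.log(F) + v * v / F)
            K = P / F
            x += K * v
            P -= K * P
        x = phi * x
        P = phi * phi * P + s2e
    return ll


@njit(cache=False)
def arma11_loglik(y, obs, mu, phi, theta, s2):  # pragma: no cover - compiled
    """Exact Gaussian log-likelihood of an ARMA(1,1) model (Harvey 2-state form).

    State (x_t, theta*e_t) with transition [[phi, 1], [0, 0]] and innovation
    covariance s2 * [[1, theta], [theta, theta^2]]; the observation is the
    first state component plus mu.
    """
    if abs(phi) >= 1.0 or abs(theta) > 1.0 or s2 < 0.0:
        return -np.inf
    n = y.shape[0]
    a1 = 0.0
    a2 = 0.0
    # stationary state covariance
    p11 = s2 * (1.0 + theta * theta + 2.0 * phi * theta) / (1.0 - phi * phi)
    p12 = theta * s2
    p22 = theta * theta * s2
    ll = 0.0
    for t in range(n):
        if obs[t]:
            F = p11
            if F <= 0.0:
                return -np.inf
            v = y[t] - mu - a1
            ll += -0.5 * (_LOG2PI + math.log(F) + v * v / F)
            k1 = p11 / F
            k2 = p12 / F
            a1 += k1 * v
            a2 += k2 * v
            p22 -= k2 * p12
            p12 -= k1 * p12
            p11 -= k1 * p11
        # predict: a <- A a, P <- A P A' + Q
        a1 = phi * a1 + a2
        a2 = 0.0
        p11 = phi * phi * p11 + 2.0 * phi * p12 + p22 + s2
        p12 = theta * s2
        p22 = theta * theta * s2
    return ll
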