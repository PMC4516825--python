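"""Linear-Gaussian state-space representations and the exact Kalman likelihood.

All three models (AR(1), AR(1)+WN, ARMA(1,1)) are cast as

    y_t = d + F x_t + w_t,      w_t ~ N(0, Sigma_omega)
    x_t = c + A x_{t-1} + e_t,  e_t ~ N(0, Sigma_eps)

with the process mean carried in the observation intercept ``d`` (so ``c = 0``)
and the filter initialized at the stationary state distribution (mean
``(I - A)^{-1} c``, covariance from the discrete Lyapunov equation).  Because
every model here is stationary by constraint, this initialization makes the
prediction-error decomposition equal to the exact joint Gaussian log-density of
the observed values — missing occasions simply contribute no measurement
update, which is exact marginalization.

This module is the readable reference implementation (general m x r matrices);
the compiled scalar/2-state kernels in :mod:`noisyar._kernels` are the hot path
used by the estimators and are tested against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .exceptions import StationarityError
from .models import ARMAParams, ARWNParams, TimeSeries

__all__ = ["StateSpaceSpec", "build_statespace", "kalman_loglik", "filtered_states", "FilterResult"]

ModelName = Literal["AR1", "ARWN", "ARMA11"]
_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class StateSpaceSpec:
    """System matrices of a time-invariant linear-Gaussian state-space model."""

    d: np.ndarray  # (m,)   observation intercept
    F: np.ndarray  # (m, r) loadings
    Sigma_omega: np.ndarray  # (m, m) observation-noise covariance
    c: np.ndarray  # (r,)   state intercept
    A: np.ndarray  # (r, r) transition
    Sigma_eps: np.ndarray  # (r, r) state-noise covariance

    def __post_init__(self) -> None:
        m, r = self.F.shape
        if self.d.shape != (m,) or self.c.shape != (r,):
            raise ValueError("inconsistent intercept dimensions")
        if self.Sigma_omega.shape != (m, m) or self.Sigma_eps.shape != (r, r):
            raise ValueError("inconsistent covariance dimensions")
        if self.A.shape != (r, r):
            raise ValueError("inconsistent transition dimension")
        if np.max(np.abs(np.linalg.eigvals(self.A))) >= 1.0:
            raise StationarityError("transition matrix has an eigenvalue on/outside the unit circle")

    @property
    def r(self) -> int:
        return self.F.shape[1]

    def stationary_state(self) -> tuple[np.ndarray, np.ndarray]:
        """Stationary state mean and covariance (Lyapunov solve)."""
        mean = np.linalg.solve(np.eye(self.r) - self.A, self.c)
        cov = solve_discrete_lyapunov(self.A, self.Sigma_eps)
        return mean, cov


def build_statespace(model: ModelName, params: ARWNParams | ARMAParams) -> StateSpaceSpec:
    """Cast a parameter point into its state-space system matrices."""
    if model == "AR1":
        if not isinstance(params, ARWNParams):
            raise TypeError("AR1 expects ARWNParams (sigma2_omega ignored as 0)")
        return StateSpaceSpec(
            d=np.array([params.mu]),
            F=np.array([[1.0]]),
            Sigma_omega=np.array([[0.0]]),
            c=np.array([0.0]),
            A=np.array([[params.phi]]),
            Sigma_eps=np.array([[params.sigma2_eps]]),
        )
    if model == "ARWN":
        if not isinstance(params, ARWNParams):
            raise TypeError("ARWN expects ARWNParams")
        return StateSpaceSpec(
            d=np.array([params.mu]),
            F=np.array([[1.0]]),
            Sigma_omega=np.array([[params.sigma2_omega]]),
            c=np.array([0.0]),
            A=np.array([[params.phi]]),
            Sigma_eps=np.array([[params.sigma2_eps]]),
        )
    if model == "ARMA11":
        if not isinstance(params, ARMAParams):
            raise TypeError("ARMA11 expects ARMAParams")
        s = math.sqrt(params.sigma2_eps_star)
        H = np.array([[s, params.theta * s]])  # 1 x 2
        return StateSpaceSpec(
            d=np.array([params.mu]),
            F=np.array([[1.0, 0.0]]),
            Sigma_omega=np.array([[0.0]]),
            c=np.array([0.0, 0.0]),
            # Harvey form: state (x_t, theta*e_t); the MA term enters through
            # the second state component one step later.
            A=np.array([[params.phi, 1.0], [0.0, 0.0]]),
            Sigma_eps=H.T @ H,
        )
    raise ValueError(f"unknown model {model!r}")


def _filter(spec: StateSpaceSpec, ts: TimeSeries, mu_override: float | None):
    """Run the Kalman filter; yields loglik plus per-occasion moments."""
    if ts.n_observed < 1:
        raise ValueError("series has no observed values")
    if not np.all(np.isfinite(ts.observed_values)):
        raise ValueError("non-finite observed values")
    d = spec.d if mu_override is None else np.array([mu_override])
    if d.shape != spec.d.shape:
        raise ValueError("mu_override only supported for univariate observations")
    F, R, c, A, Q = spec.F, spec.Sigma_omega, spec.c, spec.A, spec.Sigma_eps
    x, P = spec.stationary_state()

    n, r = ts.n_total, spec.r
    pred_mean = np.empty((n, r))
    pred_cov = np.empty((n, r, r))
    filt_mean = np.empty((n, r))
    filt_cov = np.empty((n, r, r))
    ll = 0.0
    for t in range(n):
        pred_mean[t], pred_cov[t] = x, P
        if ts.observed[t]:
            v = ts.values[t] - (d + F @ x)
            S = F @ P @ F.T + R
            det = np.linalg.det(S)
            if det <= 0.0:
                raise FloatingPointError("singular innovation covariance")
            Sinv = np.linalg.inv(S)
            ll += -0.5 * (len(v) * _LOG2PI + math.log(det) + v @ Sinv @ v)
            K = P @ F.T @ Sinv
            x = x + K @ v
            P = P - K @ F @ P
        filt_mean[t], filt_cov[t] = x, P
        x = c + A @ x
        P = A @ P @ A.T + Q
    return ll, pred_mean, pred_cov, filt_mean, filt_cov


def kalman_loglik(
    spec: StateSpaceSpec,
    ts: TimeSeries,
    mu_override: float | None = None,
) -> float:
    """Exact Gaussian log-likelihood (nats) of the observed values under ``spec``.

    ``mu_override`` substitutes the observation intercept without rebuilding the
    system, which the estimators use when profiling over the mean.
    """
    return _filter(spec, ts, mu_override)[0]


@dataclass(frozen=True)
class FilterResult:
    """Per-occasion predicted and filtered state moments, plus the log-likelihood."""

    loglik: float
    predicted_mean: np.ndarray  # (n, r)
    predicted_cov: np.ndarray  # (n, r, r)
    filtered_mean: np.ndarray  # (n, r); equals the prediction at missing occasions
    filtered_cov: np.ndarray  # (n, r, r)


def filtered_states(spec: StateSpaceSpec, ts: TimeSeries) -> FilterResult:
    """Filtered (one-sided) state estimates; missing occasions carry the prediction."""
    ll, pm, pc, fm, fc = _filter(spec, ts, None)
    return FilterResult(ll, pm, pc, fm, fc)
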