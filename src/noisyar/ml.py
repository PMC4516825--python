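"""Frequentist estimation: bounded maximum likelihood over the Kalman likelihood.

Each model is fit by L-BFGS-B on the exact prediction-error log-likelihood,
with box bounds |phi|, |theta| <= 1 - 1e-6 and variances >= 0.  Variances are
optimized on their natural scale — a solution at the zero bound (a Heywood
case) is a finding of interest here, not a nuisance to be reparameterized away.
Multiple starting points are used: the first is method-of-moments based (for
AR(1)+WN the lag-2/lag-1 autocovariance ratio estimates phi free of
measurement-error contamination), the rest are seeded random restarts.

Standard errors come from the inverse numerical Hessian at the optimum; 95%
intervals are Wald-type for the mean and AR/MA coefficients (truncated to
[-1, 1] for the latter) and chi-square-based for variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import optimize, stats

from . import _kernels
from .bridge import arma_to_arwn, arwn_to_arma
from .exceptions import DegenerateProcessError, EstimationFailureError
from .models import ARMAParams, ARWNParams, TimeSeries

__all__ = [
    "MLFitResult",
    "fit_ml",
    "make_starts",
    "variance_ci",
    "detect_heywood",
    "param_names",
    "loglik_function",
]

ModelName = Literal["AR1", "ARWN", "ARMA11"]

_PHI_BOUND = 1.0 - 1e-6
_HEYWOOD_REL_TOL = 1e-6
_BOUNDS: dict[str, list[tuple[float | None, float | None]]] = {
    "AR1": [(None, None), (-_PHI_BOUND, _PHI_BOUND), (0.0, None)],
    "ARWN": [(None, None), (-_PHI_BOUND, _PHI_BOUND), (0.0, None), (0.0, None)],
    "ARMA11": [(None, None), (-_PHI_BOUND, _PHI_BOUND), (-_PHI_BOUND, _PHI_BOUND), (0.0, None)],
}
_NAMES: dict[str, list[str]] = {
    "AR1": ["mu", "phi", "sigma2_eps"],
    "ARWN": ["mu", "phi", "sigma2_eps", "sigma2_omega"],
    "ARMA11": ["mu", "phi", "theta", "sigma2_eps_star"],
}
_VARIANCE_PARAMS = {"sigma2_eps", "sigma2_omega", "sigma2_eps_star"}


def param_names(model: ModelName) -> list[str]:
    return list(_NAMES[model])


def loglik_function(model: ModelName, ts: TimeSeries) -> Callable[[np.ndarray], float]:
    """Fast log-likelihood of a flat parameter vector (order: :func:`param_names`)."""
    y = np.ascontiguousarray(ts.values, dtype=np.float64)
    obs = np.ascontiguousarray(ts.observed)
    yz = np.where(obs, y, 0.0)  # keep NaNs out of the compiled kernels
    if model == "AR1":
        return lambda x: _kernels.arwn_loglik(yz, obs, x[0], x[1], x[2], 0.0)
    if model == "ARWN":
        return lambda x: _kernels.arwn_loglik(yz, obs, x[0], x[1], x[2], x[3])
    if model == "ARMA11":
        return lambda x: _kernels.arma11_loglik(yz, obs, x[0], x[1], x[2], x[3])
    raise ValueError(f"unknown model {model!r}")


def _autocov(ts: TimeSeries, maxlag: int) -> np.ndarray:
    """Sample autocovariances up to ``maxlag``, using pairwise-complete occasions."""
    y = ts.values
    obs = ts.observed
    ybar = float(np.mean(y[obs]))
    d = np.where(obs, y - ybar, 0.0)
    out = np.empty(maxlag + 1)
    for h in range(maxlag + 1):
        pair = obs[: len(y) - h] & obs[h:]
        npair = int(pair.sum())
        if npair < 2:
            out[h] = np.nan
        else:
            out[h] = float(np.sum(d[: len(y) - h] * d[h:]) / npair)
    return out


def make_starts(
    model: ModelName,
    ts: TimeSeries,
    n_starts: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Starting parameter vectors: one moment-based start plus seeded restarts."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = _autocov(ts, 2)
    ybar = float(np.mean(ts.observed_values))
    g0 = g[0] if np.isfinite(g[0]) and g[0] > 0 else 1.0

    def moment_start() -> np.ndarray:
        if model == "AR1":
            phi = float(np.clip(g[1] / g0, -0.95, 0.95)) if np.isfinite(g[1]) else 0.3
            return np.array([ybar, phi, max(g0 * (1 - phi**2), 1e-8)])
        # gamma_2/gamma_1 = phi for AR(1)+WN: the ratio cancels the white noise.
        if np.isfinite(g[2]) and np.isfinite(g[1]) and abs(g[1]) > 1e-12 * g0:
            phi = float(np.clip(g[2] / g[1], -0.95, 0.95))
        else:
            phi = 0.3
        if abs(phi) > 1e-3 and np.isfinite(g[1]):
            gx0 = float(np.clip(g[1] / phi, 0.05 * g0, 0.95 * g0))
        else:
            gx0 = 0.5 * g0
        s2e = max(gx0 * (1 - phi**2), 1e-8)
        s2w = max(g0 - gx0, 1e-8)
        if model == "ARWN":
            return np.array([ybar, phi, s2e, s2w])
        try:
            a = arwn_to_arma(ARWNParams(ybar, phi, s2e, s2w))
            return np.array([a.mu, a.phi, a.theta, a.sigma2_eps_star])
        except Exception:
            return np.array([ybar, 0.3, -0.1, g0])

    starts = [moment_start()]
    for _ in range(n_starts - 1):
        phi = rng.uniform(-0.9, 0.9)
        u = rng.uniform(0.1, 0.9)
        mu = ybar + rng.normal(0.0, np.sqrt(g0 / max(ts.n_observed, 2)))
        if model == "AR1":
            starts.append(np.array([mu, phi, max(g0 * (1 - phi**2), 1e-8)]))
        elif model == "ARWN":
            starts.append(np.array([mu, phi, max(u * g0 * (1 - phi**2), 1e-8), (1 - u) * g0]))
        else:
            theta = rng.uniform(-0.9, 0.9)
            starts.append(np.array([mu, phi, theta, max(u * g0, 1e-8)]))
    return starts


@dataclass
class MLFitResult:
    """A maximum-likelihood fit with Wald/chi-square intervals and boundary flags."""

    model: ModelName
    estimates: dict[str, float]
    loglik: float
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    n_starts_used: int
    converged: bool
    heywood: dict[str, bool]
    n_obs: int
    derived: dict[str, float] = field(default_factory=dict)

    def params(self) -> ARWNParams | ARMAParams:
        e = self.estimates
        if self.model == "ARMA11":
            return ARMAParams(e["mu"], e["phi"], e["theta"], e["sigma2_eps_star"])
        return ARWNParams(e["mu"], e["phi"], e["sigma2_eps"], e.get("sigma2_omega", 0.0))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": self.estimates,
            "loglik": self.loglik,
            "se": self.se,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "n_starts_used": self.n_starts_used,
            "converged": self.converged,
            "heywood": self.heywood,
            "n_obs": self.n_obs,
            "derived": self.derived,
        }


def variance_ci(s2: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Chi-square interval for a variance: ((n-1)s2/q_hi, (n-1)s2/q_lo)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if s2 < 0.0:
        raise ValueError("s2 must be non-negative")
    if s2 == 0.0:
        return (0.0, 0.0)
    q_hi = stats.chi2.ppf(1.0 - alpha / 2.0, n - 1)
    q_lo = stats.chi2.ppf(alpha / 2.0, n - 1)
    return ((n - 1) * s2 / q_hi, (n - 1) * s2 / q_lo)


def detect_heywood(fit: MLFitResult, ts: TimeSeries) -> dict[str, bool]:
    """Flag variance estimates at (or, for derived ones, below) the zero bound."""
    tol = _HEYWOOD_REL_TOL * ts.sample_variance()
    flags: dict[str, bool] = {}
    if fit.model == "ARMA11":
        flags["sigma2_omega"] = fit.derived.get("sigma2_omega", np.nan) < tol
        flags["sigma2_eps"] = fit.derived.get("sigma2_eps", np.nan) < tol
    else:
        for name in fit.estimates:
            if name in _VARIANCE_PARAMS:
                flags[name] = fit.estimates[name] < tol
    return flags


def _num_hessian(f, x, bounds, rel_step=1e-4):
    """Central-difference Hessian; the point is nudged inside the box first."""
    k = len(x)
    h = np.array([rel_step * max(1.0, abs(v)) for v in x])
    xa = x.copy()
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None:
            xa[i] = max(xa[i], lo + h[i])
        if hi is not None:
            xa[i] = min(xa[i], hi - h[i])
    H = np.empty((k, k))
    f0 = f(xa)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(xa + ei) - 2.0 * f0 + f(xa - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(xa + ei + ej) - f(xa + ei - ej) - f(xa - ei + ej) + f(xa - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_ml(
    model: ModelName,
    ts: TimeSeries,
    n_starts: int = 5,
    seed: int | np.random.SeedSequence = 0,
) -> MLFitResult:
    """Bounded ML fit of ``model`` to ``ts``, best of ``n_starts`` starting points.

    Raises :class:`EstimationFailureError` when no start yields a finite
    optimum (the analogue of an optimizer failing to initialize), and
    :class:`DegenerateProcessError` for a constant series.
    """
    if ts.sample_variance() <= 0.0:
        raise DegenerateProcessError("zero-variance series cannot be fit")
    ll = loglik_function(model, ts)
    bounds = _BOUNDS[model]
    names = _NAMES[model]

    def nll(x: np.ndarray) -> float:
        v = ll(x)
        return -v if np.isfinite(v) else 1e12

    best = None
    best_success = False
    starts = make_starts(model, ts, n_starts, seed)
    for x0 in starts:
        try:
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        except Exception:
            continue
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
            best_success = bool(res.success)
        elif abs(res.fun - best.fun) <= 1e-12 and not best_success:
            best_success = bool(res.success)
    if best is None:
        raise EstimationFailureError(f"all {n_starts} starts failed for {model}")

    xhat = np.asarray(best.x, dtype=float)
    estimates = dict(zip(names, map(float, xhat)))
    loglik = -float(best.fun)

    H = _num_hessian(nll, xhat, bounds)
    se = {}
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
    except np.linalg.LinAlgError:
        diag = np.full(len(names), np.nan)
    for name, v in zip(names, diag):
        se[name] = float(np.sqrt(v)) if np.isfinite(v) and v > 0 else np.nan

    z = stats.norm.ppf(0.975)
    ci95: dict[str, tuple[float, float]] = {}
    for name in names:
        est = estimates[name]
        if name in _VARIANCE_PARAMS:
            ci95[name] = variance_ci(est, ts.n_observed)
        else:
            lo, hi = est - z * se[name], est + z * se[name]
            if name in ("phi", "theta"):
                lo, hi = max(lo, -1.0), min(hi, 1.0)
            ci95[name] = (float(lo), float(hi))

    derived: dict[str, float] = {}
    if model == "ARMA11":
        a = ARMAParams(estimates["mu"], estimates["phi"], estimates["theta"],
                       estimates["sigma2_eps_star"])
        if a.phi != 0.0:
            r = arma_to_arwn(a)
            derived = {"sigma2_omega": float(r.sigma2_omega), "sigma2_eps": float(r.sigma2_eps)}
        else:
            derived = {"sigma2_omega": np.nan, "sigma2_eps": np.nan}

    wald_names = [n for n in ("mu", "phi", "theta") if n in names]
    converged = best_success and all(np.isfinite(se[n]) for n in wald_names)
    fit = MLFitResult(
        model=model,
        estimates=estimates,
        loglik=loglik,
        se=se,
        ci95=ci95,
        n_starts_used=len(starts),
        converged=converged,
        heywood={},
        n_obs=ts.n_observed,
        derived=derived,
    )
    fit.heywood = detect_heywood(fit, ts)
    return fit
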