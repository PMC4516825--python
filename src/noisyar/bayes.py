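"""MCMC estimation of the AR(1), AR(1)+WN and ARMA(1,1) models.

Priors (all weakly informative): uniform(0, U) on every variance — the upper
bound U is scale-dependent and therefore a required user input (e.g. 20 on a
unit-variance simulation scale, 500 on a 1-100 diary scale) — uniform(-1, 1)
on phi and theta, and Normal(mean, precision) on mu with a small precision.

The sampler is a collapsed Metropolis-within-Gibbs on the Kalman *marginal*
likelihood: latent states and missing observations are integrated out exactly
by the filter, mu is drawn from its exact Gaussian full conditional (the
marginal likelihood is an exact quadratic in mu, so three filter evaluations
identify it), and phi, theta and the variances take adaptive random-walk
Metropolis steps truncated to their prior supports.  Proposal scales adapt
with diminishing step sizes during burn-in only and are frozen afterwards, so
the retained draws target the exact posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import DegenerateProcessError, NoisyARError
from .ml import loglik_function, make_starts, param_names
from .models import TimeSeries

__all__ = [
    "PriorSpec",
    "PosteriorResult",
    "fit_bayes",
    "gelman_rubin",
    "derived_noise_posterior",
    "posterior_coverage_interval",
    "DerivedNoisePosterior",
]

ModelName = Literal["AR1", "ARWN", "ARMA11"]
_TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters; ``var_prior_upper`` is scale-dependent and required."""

    var_prior_upper: float
    phi_prior: tuple[float, float] = (-1.0, 1.0)
    theta_prior: tuple[float, float] = (-1.0, 1.0)
    mu_prior_mean: float = 0.0
    mu_prior_precision: float = 0.001

    def __post_init__(self) -> None:
        if self.var_prior_upper <= 0.0:
            raise ValueError("var_prior_upper must be positive")
        if self.mu_prior_precision <= 0.0:
            raise ValueError("mu_prior_precision must be positive")


def _acf(x: np.ndarray, nlags: int) -> np.ndarray:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return np.full(nlags + 1, np.nan)
    return np.array([x[: len(x) - h] @ x[h:] / denom for h in range(nlags + 1)])


@dataclass
class PosteriorResult:
    """Posterior draws by chain plus standard summaries and diagnostics."""

    model: ModelName
    draws: dict[str, np.ndarray]  # parameter -> (n_chains, n_kept)
    n_chains: int
    n_iter: int  # retained (post-burn-in) draws per chain
    priors: PriorSpec
    summary: pd.DataFrame = field(repr=False)
    rhat: dict[str, float]
    autocorr: dict[str, np.ndarray] = field(repr=False)

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def median(self, name: str) -> float:
        return float(np.median(self.pooled(name)))

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        return posterior_coverage_interval(self.pooled(name), level)

    def draws_frame(self) -> pd.DataFrame:
        """Long table (chain, iteration, parameter, value) for serialization."""
        rows = []
        for name, arr in self.draws.items():
            for c in range(self.n_chains):
                rows.append(pd.DataFrame({
                    "chain": c + 1,
                    "iteration": np.arange(1, arr.shape[1] + 1),
                    "parameter": name,
                    "value": arr[c],
                }))
        return pd.concat(rows, ignore_index=True)


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential-scale-reduction factor R-hat from >= 2 equal-length chains."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    m, n = chains.shape
    if n < 4:
        raise ValueError("need >= 4 draws per chain")
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    if W == 0.0:
        raise DegenerateProcessError("zero within-chain variance in all chains")
    B_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    v_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return math.sqrt(v_hat / W)


def posterior_coverage_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Central percentile interval of the draws at the requested level."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValueError("need >= 100 draws for a percentile interval")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must lie in (0, 1]")
    if level == 1.0:
        return (float(draws.min()), float(draws.max()))
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [tail, 100.0 - tail])
    return (float(lo), float(hi))


def _chain_init(model: ModelName, ts: TimeSeries, priors: PriorSpec,
                rng: np.random.Generator) -> np.ndarray:
    x = make_starts(model, ts, 1, rng)[0]
    names = param_names(model)
    for i, name in enumerate(names):
        if name in ("phi", "theta"):
            x[i] = float(np.clip(x[i] + rng.normal(0.0, 0.1), -0.95, 0.95))
        elif name != "mu":
            x[i] = float(np.clip(x[i] * rng.lognormal(0.0, 0.3),
                                 1e-4 * priors.var_prior_upper,
                                 0.99 * priors.var_prior_upper))
        else:
            x[i] = x[i] + rng.normal(0.0, 0.5 * math.sqrt(ts.sample_variance() / ts.n_observed))
    return x


def _run_chain(model: ModelName, ts: TimeSeries, priors: PriorSpec,
               n_iter: int, rng: np.random.Generator) -> np.ndarray:
    names = param_names(model)
    k = len(names)
    ll = loglik_function(model, ts)
    supports: list[tuple[float, float] | None] = []
    for name in names:
        if name == "mu":
            supports.append(None)
        elif name == "phi":
            supports.append(priors.phi_prior)
        elif name == "theta":
            supports.append(priors.theta_prior)
        else:
            supports.append((0.0, priors.var_prior_upper))

    x = _chain_init(model, ts, priors, rng)
    cur_ll = ll(x)
    if not np.isfinite(cur_ll):
        x = np.array([float(np.mean(ts.observed_values)), 0.2]
                     + [0.25 * priors.var_prior_upper] * (k - 2))
        cur_ll = ll(x)
    if not np.isfinite(cur_ll):
        raise NoisyARError("sampler could not initialize at a finite posterior density")

    scale = ts.sample_variance()
    log_step = {i: math.log(0.15 if names[i] in ("phi", "theta") else 0.3 * scale)
                for i in range(k) if names[i] != "mu"}
    n_burn = n_iter // 2
    kept = np.empty((n_iter - n_burn, k))
    tau = priors.mu_prior_precision
    m0 = priors.mu_prior_mean
    i_mu = names.index("mu")

    for it in range(n_iter):
        # --- exact Gaussian conditional for mu (marginal loglik is quadratic in mu)
        xp = x.copy()
        xp[i_mu] = x[i_mu] + 1.0
        l_plus = ll(xp)
        xp[i_mu] = x[i_mu] - 1.0
        l_minus = ll(xp)
        a = (l_plus + l_minus - 2.0 * cur_ll) / 2.0
        b_u = (l_plus - l_minus) / 2.0
        prec = tau - 2.0 * a
        if prec > 0.0 and np.isfinite(prec):
            mean_u = (b_u - tau * (x[i_mu] - m0)) / prec
            x[i_mu] = x[i_mu] + mean_u + rng.normal(0.0, 1.0 / math.sqrt(prec))
            cur_ll = ll(x)
        # --- random-walk Metropolis for the remaining parameters
        for i in range(k):
            if i == i_mu:
                continue
            lo, hi = supports[i]
            prop = x[i] + rng.normal(0.0, math.exp(log_step[i]))
            if lo < prop < hi:
                xp = x.copy()
                xp[i] = prop
                new_ll = ll(xp)
                log_alpha = new_ll - cur_ll
                accept_p = math.exp(min(0.0, log_alpha)) if np.isfinite(log_alpha) else 0.0
                if rng.random() < accept_p:
                    x = xp
                    cur_ll = new_ll
            else:
                accept_p = 0.0
            if it < n_burn:
                log_step[i] += (it + 1.0) ** -0.6 * (accept_p - _TARGET_ACCEPT)
        if it >= n_burn:
            kept[it - n_burn] = x
    return kept


def fit_bayes(
    model: ModelName,
    ts: TimeSeries,
    priors: PriorSpec,
    n_chains: int = 3,
    n_iter: int = 4000,
    seed: int | np.random.SeedSequence = 0,
) -> PosteriorResult:
    """Sample the joint posterior; ``n_iter`` is per chain, first half burn-in."""
    if n_chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    if n_iter % 2 != 0 or n_iter < 8:
        raise ValueError("n_iter must be even and >= 8")
    if ts.sample_variance() <= 0.0:
        raise DegenerateProcessError("zero-variance series cannot be fit")
    names = param_names(model)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    chains = [
        _run_chain(model, ts, priors, n_iter, np.random.default_rng(child))
        for child in ss.spawn(n_chains)
    ]
    stacked = np.stack(chains)  # (n_chains, n_kept, k)
    draws = {name: np.ascontiguousarray(stacked[:, :, i]) for i, name in enumerate(names)}
    rhat = {name: gelman_rubin(draws[name]) for name in names}
    nlags = min(50, stacked.shape[1] - 1)
    autocorr = {
        name: np.mean([_acf(draws[name][c], nlags) for c in range(n_chains)], axis=0)
        for name in names
    }
    rows = []
    for name in names:
        pooled = draws[name].reshape(-1)
        lo, hi = posterior_coverage_interval(pooled, 0.95)
        rows.append({
            "parameter": name,
            "median": float(np.median(pooled)),
            "mean": float(np.mean(pooled)),
            "sd": float(np.std(pooled, ddof=1)),
            "ci_lower": lo,
            "ci_upper": hi,
            "rhat": rhat[name],
        })
    summary = pd.DataFrame(rows).set_index("parameter")
    return PosteriorResult(
        model=model,
        draws=draws,
        n_chains=n_chains,
        n_iter=stacked.shape[1],
        priors=priors,
        summary=summary,
        rhat=rhat,
        autocorr=autocorr,
    )


@dataclass
class DerivedNoisePosterior:
    """Per-draw measurement-error and innovation variances implied by ARMA draws."""

    draws: dict[str, np.ndarray]  # (n_chains, n_kept), NaN where not computable
    n_nonfinite: int  # draws with phi ~ 0 excluded from summaries
    n_negative: dict[str, int]  # retained draws below zero, by parameter
    summary: pd.DataFrame = field(repr=False)

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        pooled = self.draws[name].reshape(-1)
        return posterior_coverage_interval(pooled[np.isfinite(pooled)], level)


def derived_noise_posterior(arma_result: PosteriorResult) -> DerivedNoisePosterior:
    """Transform every retained ARMA(1,1) draw to (sigma2_omega, sigma2_eps).

    Draws with negative implied variances are retained untouched (they are the
    boundary-signal analogue for the Bayesian ARMA route, and the resulting
    credible intervals may include negative values); draws where the map is
    undefined (phi numerically zero) are excluded from summaries and counted.
    """
    if arma_result.model != "ARMA11":
        raise ValueError("derived_noise_posterior needs an ARMA11 posterior")
    phi = arma_result.draws["phi"]
    theta = arma_result.draws["theta"]
    s2s = arma_result.draws["sigma2_eps_star"]
    with np.errstate(divide="ignore", invalid="ignore"):
        s2w = -theta * s2s / phi
        s2e = (1.0 + theta**2) * s2s - (1.0 + phi**2) * s2w
    finite = np.isfinite(s2w) & np.isfinite(s2e)
    s2w = np.where(finite, s2w, np.nan)
    s2e = np.where(finite, s2e, np.nan)
    draws = {"sigma2_omega": s2w, "sigma2_eps": s2e}
    rows = []
    for name, arr in draws.items():
        ok = arr[np.isfinite(arr)]
        lo, hi = np.percentile(ok, [2.5, 97.5])
        rows.append({
            "parameter": name,
            "median": float(np.median(ok)),
            "mean": float(np.mean(ok)),
            "sd": float(np.std(ok, ddof=1)),
            "ci_lower": float(lo),
            "ci_upper": float(hi),
        })
    return DerivedNoisePosterior(
        draws=draws,
        n_nonfinite=int((~finite).sum()),
        n_negative={name: int((arr < 0).sum()) for name, arr in draws.items()},
        summary=pd.DataFrame(rows).set_index("parameter"),
    )
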