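"""Replicated parameter-recovery experiments: bias, absolute error, coverage.

Data are always generated from the AR(1)+WN model; each replication is fit by
any subset of {AR1, ARWN, ARMA11} x {ML, Bayes}.  Per parameter the harness
reports bias (mean estimate minus truth), mean absolute error, and the
fraction of nominal-95% intervals containing the truth; per condition it
reports the rate of boundary (Heywood) variance solutions and the count of
estimation failures.  Failed fits are excluded from the metrics but counted;
Heywood replications are retained in the metrics and counted separately.

Three ready-made condition grids vary (1) the measurement-error share of the
total variance, (2) the autoregression phi at a fixed error share of 0.3, and
(3) the series length at a fixed error share of 0.43.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .bayes import PriorSpec, fit_bayes
from .bridge import arwn_to_arma
from .exceptions import NoisyARError
from .ml import fit_ml
from .models import ARWNParams, TimeSeries, me_proportion, simulate_arwn

__all__ = [
    "StudyCondition",
    "RecoveryMetrics",
    "FitRecord",
    "grid_part1",
    "grid_part2",
    "grid_part3",
    "run_condition",
    "summarize_study",
]

log = logging.getLogger("noisyar.study")

MODELS = ("AR1", "ARWN", "ARMA11")
ESTIMATORS = ("ML", "Bayes")


@dataclass(frozen=True)
class StudyCondition:
    """One cell of the simulation design."""

    name: str
    true_params: ARWNParams
    n_obs: int
    n_reps: int
    models: tuple[str, ...] = ("AR1", "ARWN", "ARMA11")
    estimators: tuple[str, ...] = ("ML",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")
        for e in self.estimators:
            if e not in ESTIMATORS:
                raise ValueError(f"unknown estimator {e!r}")

    @property
    def me_share(self) -> float:
        return me_proportion(self.true_params)


@dataclass
class FitRecord:
    """A single replication's standardized fit outcome."""

    ok: bool
    estimates: dict[str, float] = field(default_factory=dict)
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    heywood: dict[str, bool] = field(default_factory=dict)


@dataclass
class RecoveryMetrics:
    """Aggregated recovery quality for one condition x model x estimator."""

    condition: str
    model: str
    estimator: str
    n_reps: int
    n_used: int
    failure_count: int
    heywood_rate: float
    bias: dict[str, float]
    mae: dict[str, float]
    coverage: dict[str, float]
    mean_estimate: dict[str, float]
    truth: dict[str, float]


# ---------------------------------------------------------------------------
# condition grids
# ---------------------------------------------------------------------------

_PART1_S2OMEGA = (0.0, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 2.0, 4.0, 12.0)
_PART2_PHI = (-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75)
_PART3_N = (100, 200, 500)


def grid_part1(n_reps: int = 1000, **kw) -> list[StudyCondition]:
    """Vary the measurement-error variance at mu=2, phi=0.5, sigma2_eps=0.5, n=100."""
    return [
        StudyCondition(
            name=f"part1_s2w={s2w:g}",
            true_params=ARWNParams(mu=2.0, phi=0.5, sigma2_eps=0.5, sigma2_omega=s2w),
            n_obs=100,
            n_reps=n_reps,
            **kw,
        )
        for s2w in _PART1_S2OMEGA
    ]


def grid_part2(n_reps: int = 1000, **kw) -> list[StudyCondition]:
    """Vary phi at a fixed measurement-error share of 0.3 (sigma2_omega = 0.5).

    The innovation variance solves ``me_proportion = 0.3`` at each phi:
    sigma2_eps = (1 - phi^2) * sigma2_omega * (1 - 0.3) / 0.3.
    """
    lam = 0.3
    out = []
    for phi in _PART2_PHI:
        s2e = (1.0 - phi**2) * 0.5 * (1.0 - lam) / lam
        out.append(
            StudyCondition(
                name=f"part2_phi={phi:g}",
                true_params=ARWNParams(mu=2.0, phi=phi, sigma2_eps=s2e, sigma2_omega=0.5),
                n_obs=100,
                n_reps=n_reps,
                **kw,
            )
        )
    return out


def grid_part3(n_reps: int = 1000, **kw) -> list[StudyCondition]:
    """Vary the series length at mu=2, phi=0.5, sigma2_eps=sigma2_omega=0.5."""
    return [
        StudyCondition(
            name=f"part3_n={n}",
            true_params=ARWNParams(mu=2.0, phi=0.5, sigma2_eps=0.5, sigma2_omega=0.5),
            n_obs=n,
            n_reps=n_reps,
            **kw,
        )
        for n in _PART3_N
    ]


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

def _truths(model: str, p: ARWNParams) -> dict[str, float]:
    """True parameter values on the fitted model's own scale."""
    base = {"mu": p.mu, "phi": p.phi, "sigma2_eps": p.sigma2_eps}
    if model == "AR1":
        return base
    if model == "ARWN":
        return base | {"sigma2_omega": p.sigma2_omega}
    if p.phi == 0.0 and p.sigma2_omega > 0.0:
        # with phi = 0 the process is white noise; the ARMA(1,1) limit is theta=0
        a_theta, a_s2 = 0.0, p.sigma2_eps + p.sigma2_omega
    else:
        a = arwn_to_arma(p)
        a_theta, a_s2 = a.theta, a.sigma2_eps_star
    return base | {
        "sigma2_omega": p.sigma2_omega,
        "theta": a_theta,
        "sigma2_eps_star": a_s2,
    }


# ---------------------------------------------------------------------------
# default fitters
# ---------------------------------------------------------------------------

def _ml_fitter(n_starts: int) -> Callable[[str, TimeSeries, np.random.SeedSequence], FitRecord]:
    def fit(model: str, ts: TimeSeries, seed: np.random.SeedSequence) -> FitRecord:
        try:
            res = fit_ml(model, ts, n_starts=n_starts, seed=seed)
        except NoisyARError:
            return FitRecord(ok=False)
        if not res.converged:
            return FitRecord(ok=False)
        estimates = dict(res.estimates)
        intervals = dict(res.ci95)
        if model == "ARMA11":
            estimates.update(res.derived)  # derived variances: points only
        return FitRecord(ok=True, estimates=estimates, intervals=intervals,
                         heywood=dict(res.heywood))

    return fit


def _bayes_fitter(
    priors: PriorSpec, n_chains: int, n_iter: int
) -> Callable[[str, TimeSeries, np.random.SeedSequence], FitRecord]:
    def fit(model: str, ts: TimeSeries, seed: np.random.SeedSequence) -> FitRecord:
        try:
            res = fit_bayes(model, ts, priors, n_chains=n_chains, n_iter=n_iter, seed=seed)
        except NoisyARError:
            return FitRecord(ok=False)
        estimates = {n: res.median(n) for n in res.draws}
        intervals = {n: res.credible_interval(n) for n in res.draws}
        if model == "ARMA11":
            from .bayes import derived_noise_posterior

            der = derived_noise_posterior(res)
            for name in der.draws:
                estimates[name] = float(der.summary.loc[name, "median"])
                intervals[name] = der.credible_interval(name)
        return FitRecord(ok=True, estimates=estimates, intervals=intervals)

    return fit


# ---------------------------------------------------------------------------
# the replication loop
# ---------------------------------------------------------------------------

def run_condition(
    c: StudyCondition,
    ml_starts: int = 5,
    bayes_priors: PriorSpec | None = None,
    bayes_chains: int = 3,
    bayes_iter: int = 4000,
    fitters: Mapping[tuple[str, str], Callable] | None = None,
) -> list[RecoveryMetrics]:
    """Run all replications of one condition for every model x estimator.

    ``fitters`` overrides the estimation step (used to test the harness
    bookkeeping in isolation); each fitter maps ``(model, ts, seed)`` to a
    :class:`FitRecord`.  Per-replication errors are captured, never raised.
    """
    if fitters is None:
        fitters = {}
        for est in c.estimators:
            if est == "ML":
                f = _ml_fitter(ml_starts)
            else:
                f = _bayes_fitter(bayes_priors or PriorSpec(var_prior_upper=20.0),
                                  bayes_chains, bayes_iter)
            for m in c.models:
                fitters[(m, est)] = f

    root = np.random.SeedSequence([c.seed, zlib.crc32(c.name.encode())])
    rep_seeds = root.spawn(c.n_reps)
    records: dict[tuple[str, str], list[FitRecord]] = {k: [] for k in fitters}
    for rep, rs in enumerate(rep_seeds):
        sim_seed, *fit_seeds = rs.spawn(1 + len(fitters))
        ts = simulate_arwn(c.true_params, c.n_obs, sim_seed)
        for (key, fitter), fs in zip(fitters.items(), fit_seeds):
            model, est = key
            try:
                rec = fitter(model, ts, fs)
            except Exception:  # never propagate a replication failure
                rec = FitRecord(ok=False)
            records[key].append(rec)
            log.debug("condition=%s rep=%d model=%s est=%s ok=%s",
                      c.name, rep, model, est, rec.ok)

    out = []
    for (model, est), recs in records.items():
        truths = _truths(model, c.true_params)
        used = [r for r in recs if r.ok]
        bias, mae, coverage, mean_est = {}, {}, {}, {}
        for name, truth in truths.items():
            ests = np.array([r.estimates[name] for r in used if name in r.estimates])
            if ests.size:
                mean_est[name] = float(np.mean(ests))
                bias[name] = float(np.mean(ests) - truth)
                mae[name] = float(np.mean(np.abs(ests - truth)))
            ivs = [r.intervals[name] for r in used if name in r.intervals]
            if ivs:
                hits = [lo <= truth <= hi for lo, hi in ivs]
                coverage[name] = float(np.mean(hits))
        heywood = [any(r.heywood.values()) for r in used if r.heywood]
        out.append(
            RecoveryMetrics(
                condition=c.name,
                model=model,
                estimator=est,
                n_reps=c.n_reps,
                n_used=len(used),
                failure_count=len(recs) - len(used),
                heywood_rate=float(np.mean(heywood)) if heywood else 0.0,
                bias=bias,
                mae=mae,
                coverage=coverage,
                mean_estimate=mean_est,
                truth=truths,
            )
        )
        log.info("condition=%s model=%s est=%s used=%d/%d heywood=%.3f",
                 c.name, model, est, len(used), c.n_reps,
                 out[-1].heywood_rate)
    return out


def summarize_study(metrics: Iterable[RecoveryMetrics]) -> pd.DataFrame:
    """Long-format table (condition, model, estimator, parameter, metric, value)."""
    metrics = list(metrics)
    if not metrics:
        raise ValueError("no metrics to summarize")
    rows = []
    for m in metrics:
        for metric_name, table in (("bias", m.bias), ("mae", m.mae), ("coverage", m.coverage)):
            for param, value in table.items():
                rows.append((m.condition, m.model, m.estimator, param, metric_name, value))
        rows.append((m.condition, m.model, m.estimator, "", "heywood_rate", m.heywood_rate))
        rows.append((m.condition, m.model, m.estimator, "", "failure_count", float(m.failure_count)))
        rows.append((m.condition, m.model, m.estimator, "", "n_used", float(m.n_used)))
    df = pd.DataFrame(rows, columns=["condition", "model", "estimator",
                                     "parameter", "metric", "value"])
    return df.sort_values(["condition", "model", "estimator", "parameter", "metric"],
                          kind="mergesort").reset_index(drop=True)
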