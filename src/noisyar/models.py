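"""Model parameterizations, stationary moments, and the data simulator.

Two parameterizations of a latent first-order autoregressive process observed
with (optional) additive white measurement noise:

* :class:`ARWNParams` — the AR(1)+WN form (mean ``mu``, autoregression ``phi``,
  innovation variance ``sigma2_eps``, measurement-error variance
  ``sigma2_omega``).  With ``sigma2_omega = 0`` this is a plain AR(1).
* :class:`ARMAParams` — the ARMA(1,1) form (``mu``, ``phi``, moving-average
  coefficient ``theta``, innovation variance ``sigma2_eps_star``).  Every
  AR(1)+WN process is a constrained ARMA(1,1); see :mod:`noisyar.bridge`.

The observed series is held in :class:`TimeSeries`, which uses NaN as the
internal missing-value marker and reads/writes a two-column ``t,y`` CSV with
``NA``/empty cells for missing occasions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateProcessError, StationarityError

__all__ = [
    "ARWNParams",
    "ARMAParams",
    "TimeSeries",
    "total_variance",
    "me_proportion",
    "attenuated_phi",
    "simulate_arwn",
    "inject_missing",
    "make_mood_fixtures",
]


@dataclass(frozen=True)
class ARWNParams:
    """AR(1) plus white-noise parameters.

    ``y_t = mu + x_t + w_t`` with latent ``x_t = phi * x_{t-1} + e_t``,
    ``e_t ~ N(0, sigma2_eps)`` and measurement error ``w_t ~ N(0, sigma2_omega)``.
    """

    mu: float
    phi: float
    sigma2_eps: float
    sigma2_omega: float = 0.0

    def __post_init__(self) -> None:
        if not abs(self.phi) < 1.0:
            raise StationarityError(f"|phi| must be < 1, got {self.phi}")
        if self.sigma2_eps < 0.0 or self.sigma2_omega < 0.0:
            raise ValueError("variances must be non-negative")


@dataclass(frozen=True)
class ARMAParams:
    """ARMA(1,1) parameters: ``x_t = phi x_{t-1} + theta e*_{t-1} + e*_t``."""

    mu: float
    phi: float
    theta: float
    sigma2_eps_star: float

    def __post_init__(self) -> None:
        if not abs(self.phi) < 1.0:
            raise StationarityError(f"|phi| must be < 1, got {self.phi}")
        if not abs(self.theta) < 1.0:
            raise StationarityError(f"|theta| must be < 1 (invertibility), got {self.theta}")
        if self.sigma2_eps_star < 0.0:
            raise ValueError("sigma2_eps_star must be non-negative")


@dataclass
class TimeSeries:
    """An equally spaced univariate series; NaN marks a missing occasion."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")

    @property
    def n_total(self) -> int:
        return self.values.size

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing occasions."""
        return ~np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def observed_values(self) -> np.ndarray:
        return self.values[self.observed]

    def sample_variance(self) -> float:
        v = self.observed_values
        if v.size < 2:
            raise DegenerateProcessError("need >= 2 observed values for a variance")
        return float(np.var(v, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": np.arange(1, self.n_total + 1), "y": self.values})

    def to_csv(self, path: str | Path) -> None:
        """Write a ``t,y`` CSV; missing values become empty cells.

        Floats use 17 significant digits so read/write round-trips bit-exactly.
        """
        self.to_frame().to_csv(path, index=False, na_rep="", float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        if not {"t", "y"} <= set(df.columns):
            raise ValueError("time-series CSV must have columns 't' and 'y'")
        t = df["t"].to_numpy()
        if not np.array_equal(t, np.arange(1, len(t) + 1)):
            raise ValueError("'t' must be consecutive integers starting at 1")
        return cls(df["y"].to_numpy(dtype=float))

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "TimeSeries":
        return cls(np.asarray(list(values), dtype=float))


# ---------------------------------------------------------------------------
# stationary moments
# ---------------------------------------------------------------------------

def total_variance(p: ARWNParams) -> float:
    """Marginal variance of the observed process: sigma2_eps/(1-phi^2) + sigma2_omega."""
    return p.sigma2_eps / (1.0 - p.phi**2) + p.sigma2_omega


def me_proportion(p: ARWNParams) -> float:
    """Share of the total variance due to measurement error (lambda, in [0, 1])."""
    tv = total_variance(p)
    if tv <= 0.0:
        raise DegenerateProcessError("total variance is zero; proportion undefined")
    return p.sigma2_omega / tv


def attenuated_phi(phi: float, lam: float) -> float:
    """Expected AR(1) estimate under a measurement-error share ``lam``: (1-lam)*phi.

    The bias of a naive AR(1) fit is ``attenuated_phi(phi, lam) - phi = -lam*phi``.
    """
    if not abs(phi) < 1.0:
        raise StationarityError(f"|phi| must be < 1, got {phi}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must lie in [0, 1], got {lam}")
    return (1.0 - lam) * phi


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_arwn(
    p: ARWNParams,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> TimeSeries:
    """Simulate ``n`` occasions from the AR(1)+WN model.

    The latent state starts in its stationary distribution (mean 0, variance
    sigma2_eps/(1-phi^2)), so the series is stationary from t = 1 with no
    burn-in.  Reproducible given the seed.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sd_eps = math.sqrt(p.sigma2_eps)
    x = np.empty(n)
    x[0] = rng.normal(0.0, math.sqrt(p.sigma2_eps / (1.0 - p.phi**2)))
    eps = rng.normal(0.0, sd_eps, size=n - 1)
    for t in range(1, n):
        x[t] = p.phi * x[t - 1] + eps[t - 1]
    y = p.mu + x
    if p.sigma2_omega > 0.0:
        y = y + rng.normal(0.0, math.sqrt(p.sigma2_omega), size=n)
    return TimeSeries(y)


def inject_missing(
    ts: TimeSeries,
    k: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> TimeSeries:
    """Return a copy of ``ts`` with ``k`` interior observed occasions set missing."""
    if k == 0:
        return TimeSeries(ts.values.copy())
    if k >= ts.n_observed:
        raise ValueError(f"cannot remove {k} of {ts.n_observed} observed values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    interior = np.flatnonzero(ts.observed)
    interior = interior[(interior > 0) & (interior < ts.n_total - 1)]
    if k > interior.size:
        raise ValueError("not enough interior observed occasions")
    drop = rng.choice(interior, size=k, replace=False)
    values = ts.values.copy()
    values[drop] = np.nan
    return TimeSeries(values)


# Ranges spanned by per-person AR(1)+WN estimates for daily mood diaries
# (1-100 scale, roughly three months of daily entries per person).
_MOOD_MU = (55.0, 76.0)
_MOOD_PHI = (-0.03, 0.69)
_MOOD_S2EPS = (16.0, 101.0)
_MOOD_S2OMEGA = (10.0, 112.0)
_MOOD_LEN = (90, 107)
_MOOD_MISSING_MEAN = 9.0


def make_mood_fixtures(
    n_persons: int,
    seed: int | np.random.SeedSequence,
) -> list[tuple[ARWNParams, TimeSeries]]:
    """Emulate a daily mood-diary cohort: integer 1-100 scores, ~9 missing days.

    Each person's generating parameters are drawn uniformly within ranges typical
    of AR(1)+WN fits to such diaries; scores are rounded to integers and clipped
    to the 1-100 scale, a deliberate (mild) departure from the Gaussian model.
    Returns ``(params, series)`` pairs so recovery against truth can be checked.
    """
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out: list[tuple[ARWNParams, TimeSeries]] = []
    for child in ss.spawn(n_persons):
        rng = np.random.default_rng(child)
        p = ARWNParams(
            mu=rng.uniform(*_MOOD_MU),
            phi=rng.uniform(*_MOOD_PHI),
            sigma2_eps=rng.uniform(*_MOOD_S2EPS),
            sigma2_omega=rng.uniform(*_MOOD_S2OMEGA),
        )
        n = int(rng.integers(_MOOD_LEN[0], _MOOD_LEN[1] + 1))
        ts = simulate_arwn(p, n, rng)
        values = np.clip(np.round(ts.values), 1.0, 100.0)
        k = min(int(rng.poisson(_MOOD_MISSING_MEAN)), n - 2)
        out.append((p, inject_missing(TimeSeries(values), k, rng)))
    return out
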