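"""Exact parameter maps between the AR(1)+WN and ARMA(1,1) parameterizations.

An AR(1) latent process observed with additive white noise is a constrained
ARMA(1,1): subtracting ``phi`` times the lagged observation leaves an MA(1)
disturbance ``e_t + w_t - phi w_{t-1}``.  Matching its lag-0/lag-1
autocovariances to ``e*_t + theta e*_{t-1}`` gives the maps implemented here.

Going ARMA -> AR+WN the closed forms are

    sigma2_omega   = -theta * sigma2_eps_star / phi
    sigma2_eps     = (1 + theta^2) sigma2_eps_star - (1 + phi^2) sigma2_omega

and are valid only when both right-hand sides are non-negative — an
unconstrained ARMA(1,1) need not correspond to any AR(1)+WN process.  A
negative derived variance is reported untouched (it is the boundary/Heywood
signal the study harness counts), never clamped.

Going AR+WN -> ARMA, ``theta`` is the invertible root of

    theta / (1 + theta^2) = -phi sigma2_omega / (sigma2_eps + (1+phi^2) sigma2_omega)

so ``theta`` always takes the opposite sign of ``phi`` when both variances are
positive, and ``sigma2_eps_star = -phi sigma2_omega / theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import IdentificationError
from .models import ARMAParams, ARWNParams

__all__ = [
    "InvalidARMA",
    "arma_to_arwn",
    "arwn_to_arma",
    "check_arma_constraints",
    "ConstraintReport",
]


@dataclass(frozen=True)
class InvalidARMA:
    """Raw derived variances for an ARMA(1,1) point outside the AR(1)+WN region."""

    mu: float
    phi: float
    sigma2_eps: float
    sigma2_omega: float

    @property
    def reason(self) -> str:
        bad = [
            name
            for name, v in (("sigma2_omega", self.sigma2_omega), ("sigma2_eps", self.sigma2_eps))
            if v < 0.0
        ]
        return "negative derived " + " and ".join(bad)


def arma_to_arwn(a: ARMAParams) -> ARWNParams | InvalidARMA:
    """Map ARMA(1,1) parameters to AR(1)+WN parameters, if the map exists.

    Returns :class:`InvalidARMA` (carrying the raw, possibly negative derived
    variances) when the ARMA point lies outside the AR(1)+WN-compatible region.
    Raises :class:`IdentificationError` for ``phi = 0``, where measurement and
    dynamic error cannot be separated.
    """
    if a.phi == 0.0:
        raise IdentificationError("phi = 0: AR(1)+WN is not identified")
    s2_omega = -a.theta * a.sigma2_eps_star / a.phi
    s2_eps = (1.0 + a.theta**2) * a.sigma2_eps_star - (1.0 + a.phi**2) * s2_omega
    if s2_omega < 0.0 or s2_eps < 0.0:
        return InvalidARMA(mu=a.mu, phi=a.phi, sigma2_eps=s2_eps, sigma2_omega=s2_omega)
    return ARWNParams(mu=a.mu, phi=a.phi, sigma2_eps=s2_eps, sigma2_omega=s2_omega)


def arwn_to_arma(p: ARWNParams) -> ARMAParams:
    """Map AR(1)+WN parameters to the equivalent invertible ARMA(1,1) point."""
    if p.sigma2_omega == 0.0:
        return ARMAParams(mu=p.mu, phi=p.phi, theta=0.0, sigma2_eps_star=p.sigma2_eps)
    # c = gamma_u(1)/gamma_u(0) of the MA(1) disturbance; |c| <= 1/2 always.
    denom = p.sigma2_eps + (1.0 + p.phi**2) * p.sigma2_omega
    c = -p.phi * p.sigma2_omega / denom
    if c == 0.0:
        theta = 0.0
        s2_star = p.sigma2_eps + p.sigma2_omega
    else:
        # theta/(1+theta^2) = c has reciprocal roots; keep the invertible one,
        # written in the cancellation-free form stable for small |c|.  In
        # s2_star = -phi*sigma2_omega/theta the noise variance cancels
        # analytically, which avoids garbage ratios of subnormal numbers.
        root = 1.0 + math.sqrt(1.0 - 4.0 * c * c)
        theta = 2.0 * c / root
        s2_star = denom * root / 2.0
    return ARMAParams(mu=p.mu, phi=p.phi, theta=theta, sigma2_eps_star=s2_star)


@dataclass(frozen=True)
class ConstraintReport:
    """Both sides of the AR(1)+WN-compatibility inequalities for an ARMA point."""

    valid: bool
    upper_bound: float  # 1/(1+phi^2)
    middle: float  # theta/(1+theta^2) * (-1/phi)

    def __bool__(self) -> bool:
        return self.valid


def check_arma_constraints(a: ARMAParams) -> ConstraintReport:
    """Check ``1/(1+phi^2) > theta/(1+theta^2) * (-1/phi) >= 0``.

    These hold exactly when the ARMA(1,1) point corresponds to an AR(1)+WN
    process with non-negative variances.
    """
    if a.phi == 0.0:
        raise IdentificationError("phi = 0: constraint undefined")
    upper = 1.0 / (1.0 + a.phi**2)
    middle = a.theta / (1.0 + a.theta**2) * (-1.0 / a.phi)
    return ConstraintReport(valid=(upper > middle >= 0.0), upper_bound=upper, middle=middle)
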