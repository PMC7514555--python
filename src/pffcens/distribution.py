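"""Inverse Weibull distribution: density, quantiles, hazard, and Shannon entropy.

The inverse Weibull law with shape ``alpha`` and scale ``lam`` has CDF
``F(x) = exp(-lam * x**(-alpha))`` on ``x > 0``.  Unlike the Weibull, its
hazard is unimodal, which makes it a common choice for lifetime data whose
empirical failure rate rises and then falls.

All logarithms are natural; the entropy is reported in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EULER_GAMMA",
    "IWDParams",
    "cdf",
    "pdf",
    "log_pdf",
    "quantile",
    "hazard",
    "entropy",
    "entropy_gradient",
    "entropy_hessian",
]

#: Euler-Mascheroni constant (double precision), used by the entropy formula.
EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class IWDParams:
    """Parameter pair of the inverse Weibull distribution.

    Attributes
    ----------
    alpha : float
        Shape parameter, dimensionless, strictly positive.
    lam : float
        Scale parameter (units of time**alpha), strictly positive.
    """

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"shape parameter must be finite and > 0, got {self.alpha}")
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError(f"scale parameter must be finite and > 0, got {self.lam}")


def _check_positive(x, name: str = "x"):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError(f"{name} must be strictly positive and finite")
    return x


def cdf(x, p: IWDParams):
    """CDF ``exp(-lam * x**(-alpha))`` evaluated at ``x > 0``."""
    x = _check_positive(x)
    return np.exp(-p.lam * x ** (-p.alpha))


def log_pdf(x, p: IWDParams):
    """Log density; computed directly in log space to avoid under/overflow."""
    x = _check_positive(x)
    return (
        np.log(p.alpha)
        + np.log(p.lam)
        - p.lam * x ** (-p.alpha)
        - (p.alpha + 1.0) * np.log(x)
    )


def pdf(x, p: IWDParams):
    """Density ``alpha*lam * exp(-lam*x**(-alpha)) * x**(-alpha-1)`` at ``x > 0``."""
    return np.exp(log_pdf(x, p))


def quantile(u, p: IWDParams):
    """Inverse CDF: ``(lam / (-log u))**(1/alpha)`` for ``u`` in (0, 1)."""
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("probability must lie strictly inside (0, 1)")
    return (p.lam / (-np.log(u))) ** (1.0 / p.alpha)


def hazard(x, p: IWDParams):
    """Failure-rate function ``pdf / (1 - cdf)``; unimodal in ``x``.

    The survival probability is computed as ``-expm1(-lam*x**(-alpha))`` so
    small exceedance probabilities do not lose precision.
    """
    x = _check_positive(x)
    u = p.lam * x ** (-p.alpha)
    surv = -np.expm1(-u)
    return pdf(x, p) / surv


def entropy(p: IWDParams) -> float:
    """Shannon entropy ``(alpha+1)/alpha*(gamma + log lam) + 1 - log(alpha*lam)``."""
    a, lam = p.alpha, p.lam
    return (a + 1.0) / a * (EULER_GAMMA + np.log(lam)) + 1.0 - np.log(a * lam)


def entropy_gradient(p: IWDParams) -> np.ndarray:
    """Gradient ``(dH/dalpha, dH/dlam)`` of the entropy.

    ``dH/dalpha = -(gamma + log lam)/alpha**2 - 1/alpha`` and
    ``dH/dlam = 1/(alpha*lam)``.
    """
    a, lam = p.alpha, p.lam
    g = EULER_GAMMA + np.log(lam)
    return np.array([-g / a**2 - 1.0 / a, 1.0 / (a * lam)])


def entropy_hessian(p: IWDParams) -> np.ndarray:
    """Hessian of the entropy in (alpha, lam); needed by the Lindley expansion."""
    a, lam = p.alpha, p.lam
    g = EULER_GAMMA + np.log(lam)
    h11 = 2.0 * g / a**3 + 1.0 / a**2
    h12 = -1.0 / (a**2 * lam)
    h22 = -1.0 / (a * lam**2)
    return np.array([[h11, h12], [h12, h22]])
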