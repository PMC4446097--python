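"""Zero-truncated Poisson and negative-binomial distributions.

Event-sharing counts are conditioned on being observed at least once, so the
models fitted to them are the corresponding count distributions truncated at
zero.  The negative binomial uses the size-theta parametrization: mean ``mu``
and (untruncated) variance ``mu + mu**2 / theta``; ``theta -> inf`` recovers
the Poisson.

Only plain functions live here; maximum-likelihood fitting is in
:mod:`splicecons.consistency`.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .exceptions import ValidationError

__all__ = [
    "ztpois_logpmf",
    "ztpois_pmf",
    "ztpois_mean",
    "ztnb_logpmf",
    "ztnb_pmf",
    "ztnb_rvs",
    "ztpois_rvs",
]


def _log1mexp(log_p0: np.ndarray | float) -> np.ndarray | float:
    """log(1 - exp(log_p0)) for log_p0 < 0, stable near both ends."""
    log_p0 = np.asarray(log_p0, dtype=float)
    return np.where(
        log_p0 > -0.693,  # exp(log_p0) > 1/2
        np.log(-np.expm1(log_p0)),
        np.log1p(-np.exp(log_p0)),
    )


# ---------------------------------------------------------------------------
# zero-truncated Poisson
# ---------------------------------------------------------------------------

def ztpois_logpmf(k, lam: float):
    """Log pmf of the Poisson(lam) distribution conditioned on k >= 1."""
    if lam <= 0:
        raise ValidationError("lam must be > 0")
    k = np.asarray(k, dtype=float)
    if np.any(k < 1):
        raise ValidationError("zero-truncated support is k >= 1")
    log_denom = _log1mexp(-lam)
    return k * np.log(lam) - lam - special.gammaln(k + 1.0) - log_denom


def ztpois_pmf(k, lam: float):
    return np.exp(ztpois_logpmf(k, lam))


def ztpois_mean(lam: float) -> float:
    """Mean of the zero-truncated Poisson: lam / (1 - exp(-lam))."""
    if lam <= 0:
        raise ValidationError("lam must be > 0")
    return lam / -np.expm1(-lam)


def ztpois_rvs(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draws from the zero-truncated Poisson by resampling zeros."""
    if lam <= 0:
        raise ValidationError("lam must be > 0")
    out = rng.poisson(lam, size=size)
    while True:
        zero = out == 0
        n_zero = int(zero.sum())
        if n_zero == 0:
            return out
        out[zero] = rng.poisson(lam, size=n_zero)


# ---------------------------------------------------------------------------
# zero-truncated negative binomial (size-theta parametrization)
# ---------------------------------------------------------------------------

def _nb_logpmf(k, mu: float, theta: float):
    k = np.asarray(k, dtype=float)
    return (
        special.gammaln(k + theta)
        - special.gammaln(theta)
        - special.gammaln(k + 1.0)
        + theta * np.log(theta / (theta + mu))
        + k * np.log(mu / (theta + mu))
    )


def nb_logp0(mu: float, theta: float) -> float:
    """log P(K = 0) for the untruncated NB: -theta * log1p(mu/theta)."""
    return -theta * np.log1p(mu / theta)


def ztnb_logpmf(k, mu: float, theta: float):
    """Log pmf of NB(mu, theta) conditioned on k >= 1.

    Variance of the untruncated distribution is ``mu + mu**2/theta``.
    """
    if mu <= 0 or theta <= 0:
        raise ValidationError("mu and theta must be > 0")
    k = np.asarray(k, dtype=float)
    if np.any(k < 1):
        raise ValidationError("zero-truncated support is k >= 1")
    return _nb_logpmf(k, mu, theta) - _log1mexp(nb_logp0(mu, theta))


def ztnb_pmf(k, mu: float, theta: float):
    return np.exp(ztnb_logpmf(k, mu, theta))


def ztnb_rvs(
    mu: float, theta: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws from the zero-truncated NB(mu, theta) by resampling zeros."""
    if mu <= 0 or theta <= 0:
        raise ValidationError("mu and theta must be > 0")
    p = theta / (theta + mu)
    out = rng.negative_binomial(theta, p, size=size)
    while True:
        zero = out == 0
        n_zero = int(zero.sum())
        if n_zero == 0:
            return out
        out[zero] = rng.negative_binomial(theta, p, size=n_zero)
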