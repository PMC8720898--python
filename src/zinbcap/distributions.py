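"""Negative binomial and zero-inflated negative binomial (ZINB) distributions.

The ZINB model for UMI counts mixes a point mass at zero (probability
``pi``, the zero-inflation parameter capturing dropout/false zeros plus
excess biological zeros) with a negative binomial count component of mean
``mu`` and size ``theta`` (dispersion ``phi = 1/theta``):

    P(Y = y) = pi * delta_0(y) + (1 - pi) * NB(y; mu, theta)

A cell-specific molecular capture rate ``p`` thins the true counts
binomially; the observed counts then follow ZINB(pi, mu * p, theta)
(see :mod:`zinbcap.capture`), so the capture-adjusted mean ``mu_prime =
mu * p`` is carried alongside the parameters.

All likelihood evaluation is done in log space via the log-gamma function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ZINBParams",
    "ObservedMoments",
    "nb_pmf",
    "nb_logpmf",
    "zinb_pmf",
    "zinb_logpmf",
    "zinb_sample",
    "observed_moments",
]


def _validate_y(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.all(np.isfinite(y)):
        raise ValueError("counts must be finite")
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    if not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("counts must be integer-valued")
    return y.astype(np.int64, copy=False)


def _validate_params(mu, theta, pi=None) -> None:
    if np.any(np.asarray(theta) <= 0):
        raise ValueError("theta (size parameter) must be > 0")
    if np.any(np.asarray(mu) < 0):
        raise ValueError("mu must be >= 0")
    if pi is not None and (np.any(np.asarray(pi) < 0) or np.any(np.asarray(pi) > 1)):
        raise ValueError("pi must lie in [0, 1]")


@dataclass(frozen=True)
class ZINBParams:
    """ZINB parameter triple with an optional capture rate.

    Parameters are stored as (pi, mu, theta); the dispersion ``phi`` is
    derived as ``1/theta``.  ``p`` is the molecular capture rate of the
    cell (1 means perfect capture), and ``mu_prime = mu * p`` is the mean
    of the observed-count model.
    """

    pi: float
    mu: float
    theta: float
    p: float = 1.0

    def __post_init__(self):
        _validate_params(self.mu, self.theta, self.pi)
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("capture rate p must lie in [0, 1]")

    @classmethod
    def from_phi(cls, pi: float, mu: float, phi: float, p: float = 1.0) -> "ZINBParams":
        """Construct from the dispersion parameterization (phi = 1/theta)."""
        if phi <= 0:
            raise ValueError("phi must be > 0")
        return cls(pi=pi, mu=mu, theta=1.0 / phi, p=p)

    @property
    def phi(self) -> float:
        return 1.0 / self.theta

    @property
    def mu_prime(self) -> float:
        """Capture-adjusted mean of the observed counts."""
        return self.mu * self.p

    def observed(self) -> "ZINBParams":
        """Parameters of the observed-count (capture-thinned) model."""
        return ZINBParams(pi=self.pi, mu=self.mu_prime, theta=self.theta, p=1.0)

    def pmf(self, y):
        """ZINB pmf of the observed counts (evaluated at ``mu_prime``)."""
        return zinb_pmf(y, self.pi, self.mu_prime, self.theta)


@dataclass(frozen=True)
class ObservedMoments:
    """First two moments of the observed (capture-thinned) counts."""

    mean: float
    variance: float


def nb_logpmf(y, mu, theta):
    """Log pmf of the negative binomial, NB(mu, theta), elementwise.

    Uses the (size, prob) parameterization prob = theta / (theta + mu).
    mu = 0 is the degenerate point mass at zero.
    """
    y = _validate_y(y)
    _validate_params(mu, theta)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prob = theta / (theta + mu)
        out = stats.nbinom.logpmf(y, theta, prob)
    # mu == 0: point mass at zero
    if np.any(mu == 0):
        zero_mu = np.broadcast_to(mu == 0, out.shape)
        y_b = np.broadcast_to(y, out.shape)
        out = np.where(zero_mu, np.where(y_b == 0, 0.0, -np.inf), out)
    return out


def nb_pmf(y, mu, theta):
    """Pmf of the negative binomial NB(mu, theta) (computed in log space)."""
    return np.exp(nb_logpmf(y, mu, theta))


def zinb_logpmf(y, pi, mu, theta):
    """Log pmf of ZINB(pi, mu, theta), elementwise."""
    y = _validate_y(y)
    _validate_params(mu, theta, pi)
    pi = np.asarray(pi, dtype=float)
    lnb = nb_logpmf(y, mu, theta)
    with np.errstate(divide="ignore"):
        log1mpi = np.log1p(-pi)
        count_part = log1mpi + lnb
        y_b = np.broadcast_to(y, count_part.shape)
        pi_b = np.broadcast_to(pi, count_part.shape)
        # at y == 0 add the point mass: log(pi + (1-pi) * NB(0))
        zero_part = np.logaddexp(np.log(np.where(pi_b > 0, pi_b, 1.0)), count_part)
        zero_part = np.where(pi_b > 0, zero_part, count_part)
    return np.where(y_b == 0, zero_part, count_part)


def zinb_pmf(y, pi, mu, theta):
    """Pmf of ZINB(pi, mu, theta): pi*delta_0(y) + (1-pi)*NB(y; mu, theta)."""
    return np.exp(zinb_logpmf(y, pi, mu, theta))


def zinb_sample(n, pi, mu, theta, seed=None):
    """Draw ``n`` i.i.d. ZINB(pi, mu, theta) counts.

    With probability ``pi`` a draw is a structural zero, otherwise it is
    NB(mu, theta).  ``mu`` may be a scalar or a length-``n`` vector of
    per-draw means.  Reproducible given ``seed`` (an int or a Generator).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _validate_params(mu, theta, pi)
    rng = np.random.default_rng(seed)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n,))
    prob = theta / (theta + mu)  # in (0, 1]; prob == 1 draws an exact 0
    counts = rng.negative_binomial(theta, prob)
    structural = rng.random(n) < pi
    return np.where(structural, 0, counts).astype(np.int64)


def observed_moments(params: ZINBParams, p: float | None = None) -> ObservedMoments:
    """Mean and variance of the observed (binomially thinned) counts.

    mean = (1-pi) * mu * p
    variance = (1-pi) * mu * p * (1 + pi*mu*p + mu*p*phi)

    equivalently variance = mean * {1 + mu*p*(pi + phi)}; at pi=0, p=1 this
    reduces to the plain NB variance mu + mu^2 * phi.
    """
    if p is None:
        p = params.p
    if not (0.0 <= p <= 1.0):
        raise ValueError("capture rate p must lie in [0, 1]")
    pi, mu, phi = params.pi, params.mu, params.phi
    mp = mu * p
    mean = (1.0 - pi) * mp
    variance = mean * (1.0 + pi * mp + mp * phi)
    return ObservedMoments(mean=mean, variance=variance)
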