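"""Binomial molecular-capture layer and capture-rate estimators.

Single-cell protocols capture only a fraction of the transcript molecules
in a cell's lysate.  Modeling that loss as binomial thinning — each of the
``z`` true molecules is observed independently with probability ``p`` —
has a key closure property: if the true counts are ZINB(pi, mu, theta)
and Y | Z=z ~ Binomial(z, p), the observed counts are again
ZINB(pi, mu*p, theta).  Only the mean is attenuated; zero inflation and
dispersion are untouched, so pi estimated from observed data estimates
the true-zero proportion.

Two per-cell capture-rate estimators are provided:

* spike-ins: per cell, regress the observed spike-in UMI counts on the
  known molecular concentrations; the slope estimates the capture rate.
* library size: map log10 library sizes linearly onto a user-supplied
  capture range (rho1, rho2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .distributions import zinb_pmf

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeInSet",
    "CaptureRateEstimate",
    "thin_counts",
    "thinned_pmf_oracle",
    "estimate_capture_spikeins",
    "estimate_capture_librarysize",
]


@dataclass
class SpikeInSet:
    """External RNA spike-in data for capture-rate calibration.

    ``concentrations``: molecular concentrations of the n spike-in
    transcripts added to each cell's lysate.  ``counts``: cells x n
    matrix of observed spike-in UMI counts.  Counts are nonnegative;
    non-integer values are tolerated only to represent the deterministic
    noise-free limit used in synthetic data.
    """

    concentrations: np.ndarray
    counts: np.ndarray
    transcript_ids: list | None = None
    cell_ids: list | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if self.concentrations.ndim != 1:
            raise ValueError("concentrations must be a 1-D vector")
        n = self.concentrations.size
        if n < 2:
            raise ValueError("need >= 2 spike-in transcripts for regression")
        if self.counts.shape[1] != n:
            raise ValueError(
                f"counts has {self.counts.shape[1]} columns but there are "
                f"{n} spike-in concentrations"
            )
        if np.any(self.counts < 0):
            raise ValueError("spike-in counts must be nonnegative")
        if self.transcript_ids is None:
            self.transcript_ids = [f"spike_{u}" for u in range(n)]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]


@dataclass
class CaptureRateEstimate:
    """Per-cell capture rates with the summaries the moment formulas use."""

    p_hat: np.ndarray
    method: str  # one of {"spikein", "librarysize", "fixed"}
    raw_slope: np.ndarray | None = None  # pre-clamp slopes (spikein only)
    intercept: np.ndarray | None = None
    range: tuple | None = None  # (rho1, rho2) for librarysize
    L_min: float | None = None
    L_max: float | None = None

    def __post_init__(self):
        self.p_hat = np.asarray(self.p_hat, dtype=float)
        if np.any(self.p_hat < 0) or np.any(self.p_hat > 1):
            raise ValueError("p_hat must lie in [0, 1] (clamp before constructing)")

    @classmethod
    def fixed(cls, p: float, n_cells: int) -> "CaptureRateEstimate":
        return cls(p_hat=np.full(n_cells, float(p)), method="fixed")

    @property
    def p_bar(self) -> float:
        """Mean capture rate over cells."""
        return float(np.mean(self.p_hat))

    @property
    def p2_bar(self) -> float:
        """Mean squared capture rate over cells."""
        return float(np.mean(self.p_hat**2))

    @property
    def var_p(self) -> float:
        """Population-divisor variance of the per-cell capture rates."""
        return float(np.var(self.p_hat))


def thin_counts(Z, p, seed=None):
    """Binomially thin a genes x cells matrix of true counts.

    Column i (cell i) is thinned with capture rate ``p[i]``; a scalar ``p``
    applies to every cell.  Y <= Z elementwise; p=1 reproduces Z exactly.
    """
    Z = np.asarray(Z)
    if np.any(Z < 0) or not np.all(np.equal(np.mod(Z, 1), 0)):
        raise ValueError("true counts must be nonnegative integers")
    Z = Z.astype(np.int64, copy=False)
    p = np.asarray(p, dtype=float)
    if p.ndim == 0:
        p = np.full(Z.shape[-1], float(p))
    if p.shape[0] != Z.shape[-1]:
        raise ValueError(
            f"capture vector length {p.shape[0]} does not match "
            f"{Z.shape[-1]} cells (matrix columns)"
        )
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("capture rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return rng.binomial(Z, np.broadcast_to(p, Z.shape))


def thinned_pmf_oracle(y, pi, mu, theta, p, z_max=None, tail_tol=1e-12):
    """Brute-force marginal pmf of binomially thinned ZINB counts.

    Computes sum_z Binomial(y | z, p) * ZINB(z; pi, mu, theta) by direct
    truncated summation.  By the capture theorem this must equal
    ``zinb_pmf(y; pi, mu*p, theta)``; the function exists as an
    independent oracle for that identity, not as a fast path.

    ``z_max`` truncates the sum; if omitted it is chosen so the ZINB tail
    mass beyond it is < ``tail_tol``.  An explicit ``z_max`` that leaves
    more tail mass than ``tail_tol`` is refused.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("capture rate p must lie in [0, 1]")
    y = int(y)
    if y < 0:
        raise ValueError("y must be a nonnegative integer")
    if mu == 0:
        return 1.0 if y == 0 else 0.0
    prob = theta / (theta + mu)
    auto_z = int(stats.nbinom.ppf(1.0 - tail_tol / 10.0, theta, prob)) + 10
    if z_max is None:
        z_max = auto_z
    else:
        tail = (1.0 - pi) * stats.nbinom.sf(z_max, theta, prob)
        if tail >= tail_tol:
            raise ValueError(
                f"z_max={z_max} leaves ZINB tail mass ~{tail:.3e} >= {tail_tol:.1e}; "
                f"use z_max >= {auto_z}"
            )
    z = np.arange(y, z_max + 1)
    pz = zinb_pmf(z, pi, mu, theta)
    bino = stats.binom.pmf(y, z, p)
    return float(np.sum(bino * pz))


def estimate_capture_spikeins(spikes: SpikeInSet) -> CaptureRateEstimate:
    """Estimate per-cell capture rates from external spike-in data.

    For each cell i, ordinary least squares of the observed spike-in UMI
    counts R_iu on the known concentrations C_u; the slope estimates the
    cell's capture rate (intercept retained as a diagnostic).  Slopes are
    clamped to [0, 1]; pre-clamp values are kept in ``raw_slope``.
    """
    C = spikes.concentrations
    Cc = C - C.mean()
    ssx = float(np.sum(Cc**2))
    if ssx <= 0:
        raise ValueError("spike-in concentrations are constant; OLS slope undefined")
    R = spikes.counts
    slopes = (R - R.mean(axis=1, keepdims=True)) @ Cc / ssx
    intercepts = R.mean(axis=1) - slopes * C.mean()
    n_out = int(np.sum((slopes < 0) | (slopes > 1)))
    if n_out:
        logger.warning(
            "%d of %d spike-in slopes fell outside [0, 1] and were clamped", n_out, R.shape[0]
        )
    return CaptureRateEstimate(
        p_hat=np.clip(slopes, 0.0, 1.0),
        method="spikein",
        raw_slope=slopes,
        intercept=intercepts,
    )


def estimate_capture_librarysize(library_sizes, rho1=0.1, rho2=0.9) -> CaptureRateEstimate:
    """Estimate per-cell capture rates from library sizes alone.

    With L_i = log10(S_i), capture rates are interpolated linearly between
    rho1 (smallest library) and rho2 (largest):

        p_hat_i = rho1 + (rho2 - rho1) * (L_i - L_min) / (L_max - L_min)

    If every cell has the same library size the interpolation is undefined
    and all cells receive the midpoint (rho1 + rho2) / 2 with a warning.
    """
    S = np.asarray(library_sizes, dtype=float)
    if np.any(S <= 0):
        raise ValueError("library sizes must be positive")
    if not (0.0 <= rho1 < rho2 <= 1.0):
        raise ValueError("need 0 <= rho1 < rho2 <= 1")
    L = np.log10(S)
    L_min, L_max = float(L.min()), float(L.max())
    if L_max == L_min:
        warnings.warn(
            "all library sizes are equal; returning the midpoint capture rate",
            stacklevel=2,
        )
        p_hat = np.full(S.shape, (rho1 + rho2) / 2.0)
    else:
        p_hat = rho1 + (rho2 - rho1) * (L - L_min) / (L_max - L_min)
    return CaptureRateEstimate(
        p_hat=p_hat,
        method="librarysize",
        range=(rho1, rho2),
        L_min=L_min,
        L_max=L_max,
    )
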