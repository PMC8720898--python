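"""Sampling distribution of gene-level sample means and variances.

For gene j the cluster-balanced sample mean and variance over cells are

    ybar_j = (1/K) sum_k (1/I_k) sum_{i in k} y_ijk
    s2_j   = (1/K) sum_k (1/(I_k - 1)) sum_{i in k} (y_ijk - ybar_j)^2

(the inner deviation uses the overall ybar_j, not the cluster mean).

Their model-implied first two moments follow from the per-cell observed
moments E(Y_i) = (1-pi) mu p_i and V(Y_i) = (1-pi) mu p_i (1 + pi mu p_i
+ mu p_i phi) under the homogeneity assumption (one (pi, mu, theta) per
gene; capture rate varies only by cell).  ``estimated_gene_stats``
computes E(ybar), V(ybar) and E(s2) *exactly* from those per-cell
moments via E(ybar^2) - {E(ybar)}^2 etc.; the coarser closed forms in
terms of (p_bar, p2_bar, var_p) alone are available as
``formula="printed"`` — they ignore the (1-pi) attenuation of the
between-cell spread and misplace a 1/I factor, and are retained only
for comparison (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capture import CaptureRateEstimate
from .distributions import ZINBParams

__all__ = ["GeneSampleStats", "observed_gene_stats", "estimated_gene_stats"]


@dataclass(frozen=True)
class GeneSampleStats:
    """Observed and model-implied sample statistics for one gene."""

    E_ybar: float
    V_ybar: float
    E_s2: float
    cv_ybar: float
    se_ybar: float
    sd_ybar: float
    ybar: float | None = None
    s2: float | None = None


def _cluster_groups(clusters, I):
    if clusters is None:
        return [np.arange(I)]
    clusters = np.asarray(clusters)
    if clusters.shape[0] != I:
        raise ValueError("cluster labels must have one entry per cell")
    groups = []
    for lev in np.unique(clusters):
        idx = np.flatnonzero(clusters == lev)
        if idx.size < 2:
            raise ValueError(
                f"cluster {lev!r} has {idx.size} cell(s); need >= 2 per cluster"
            )
        groups.append(idx)
    return groups


def observed_gene_stats(y, clusters=None):
    """Cluster-balanced sample mean and variance of one gene's counts.

    Every cluster must contain at least two cells (the within-cluster
    divisor is I_k - 1).  With a single cluster these are the ordinary
    sample mean and variance.
    """
    y = np.asarray(y, dtype=float)
    groups = _cluster_groups(clusters, y.shape[0])
    K = len(groups)
    ybar = sum(y[idx].mean() for idx in groups) / K
    s2 = sum(np.sum((y[idx] - ybar) ** 2) / (idx.size - 1) for idx in groups) / K
    return float(ybar), float(s2)


def estimated_gene_stats(
    fit: ZINBParams,
    capture,
    clusters=None,
    I: int | None = None,
    formula: str = "exact",
    y=None,
) -> GeneSampleStats:
    """Model-implied moments of the sample mean and variance of a gene.

    ``fit`` carries the gene-level (pi, mu, theta); ``capture`` a
    :class:`CaptureRateEstimate` or per-cell capture-rate vector.  With
    ``formula="exact"`` (default) the moments are computed exactly from
    the per-cell means/variances; ``formula="printed"`` evaluates the
    closed forms in (p_bar, p2_bar, var_p):

        E(ybar) = mu (1-pi) p_bar
        V(ybar) = mu (1-pi)/I (2 p_bar + mu phi p2_bar) + (1-pi)^2 mu^2 var_p
        E(s2)   = mu p_bar + mu^2 phi p2_bar + mu^2 var_p

    If ``y`` (the observed counts) is given, the observed ybar/s2 are
    filled in as well.
    """
    if isinstance(capture, CaptureRateEstimate):
        p = capture.p_hat
    else:
        p = np.asarray(capture, dtype=float)
    if p.ndim == 0:
        if I is None:
            raise ValueError("scalar capture rate needs an explicit cell count I")
        p = np.full(I, float(p))
    I = p.shape[0]
    if I <= 1:
        raise ValueError("need more than one cell")
    pi, mu, phi = fit.pi, fit.mu, fit.phi
    groups = _cluster_groups(clusters, I)
    K = len(groups)

    # per-cell observed moments (exact under the capture theorem)
    m = (1.0 - pi) * mu * p
    v = m * (1.0 + pi * mu * p + mu * p * phi)

    if formula == "exact":
        # weights of each cell in the cluster-balanced mean
        a = np.zeros(I)
        for idx in groups:
            a[idx] = 1.0 / (K * idx.size)
        E_ybar = float(a @ m)
        V_ybar = float(a**2 @ v)  # cells independent
        sum_a2v = V_ybar
        # E(y_i - ybar)^2 = V(y_i - ybar) + (m_i - E ybar)^2 with
        # V(y_i - ybar) = v_i (1 - 2 a_i) + sum_i' a_i'^2 v_i'
        E_s2 = 0.0
        for idx in groups:
            contrib = (
                v[idx] * (1.0 - 2.0 * a[idx]) + sum_a2v + (m[idx] - E_ybar) ** 2
            )
            E_s2 += float(np.sum(contrib)) / (idx.size - 1)
        E_s2 /= K
    elif formula == "printed":
        p_bar = float(np.mean(p))
        p2_bar = float(np.mean(p**2))
        var_p = float(np.var(p))
        E_ybar = mu * (1.0 - pi) * p_bar
        V_ybar = (
            mu * (1.0 - pi) / I * (2.0 * p_bar + mu * phi * p2_bar)
            + (1.0 - pi) ** 2 * mu**2 * var_p
        )
        E_s2 = mu * p_bar + mu**2 * phi * p2_bar + mu**2 * var_p
    else:
        raise ValueError("formula must be 'exact' or 'printed'")

    sd_ybar = float(np.sqrt(max(V_ybar, 0.0)))
    se_ybar = sd_ybar / np.sqrt(I)
    cv_ybar = sd_ybar / E_ybar if E_ybar > 0 else np.nan
    ybar = s2 = None
    if y is not None:
        ybar, s2 = observed_gene_stats(y, clusters)
    return GeneSampleStats(
        E_ybar=E_ybar,
        V_ybar=V_ybar,
        E_s2=E_s2,
        cv_ybar=cv_ybar,
        se_ybar=se_ybar,
        sd_ybar=sd_ybar,
        ybar=ybar,
        s2=s2,
    )
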