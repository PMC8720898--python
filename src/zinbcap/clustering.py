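"""Cell clustering and the WSS/BSS index for choosing the cluster number.

Cells are clustered by k-means on library-size-scaled, log1p-transformed
counts for a range of candidate cluster numbers h.  For each h the index

    r_h = WSS / BSS

is computed on per-cell mean expression values, where WSS/BSS are the
within- and between-cluster sums of squares of those values (the ANOVA
identity TSS = WSS + BSS holds exactly, with TSS independent of h).
As clusters tighten r_h decreases; the selected cluster number is the
point where the r_h curve flattens (elbow), with the plain argmax also
reported for reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = ["ClusterIndexCurve", "cluster_index", "optimal_cluster_number"]


@dataclass
class ClusterIndexCurve:
    h_values: np.ndarray
    r_h: np.ndarray
    wss: np.ndarray
    bss: np.ndarray
    tss: np.ndarray
    h_opt: int
    h_argmax: int
    labels_opt: np.ndarray
    labels: dict = field(default_factory=dict)
    no_structure: bool = False


def cluster_index(values, labels):
    """WSS, BSS, TSS and r = WSS/BSS of per-cell values under a partition.

    WSS = sum_k sum_{i in k} (Y_ik - Ybar_.k)^2,
    BSS = sum_k I_k (Ybar_.k - Ybar_..)^2; raises if BSS = 0 (all cluster
    means equal — the index is undefined for such a partition).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("need at least 2 non-empty clusters")
    grand = values.mean()
    wss = bss = 0.0
    for lev in levels:
        sub = values[labels == lev]
        wss += float(np.sum((sub - sub.mean()) ** 2))
        bss += sub.size * float((sub.mean() - grand) ** 2)
    tss = float(np.sum((values - grand) ** 2))
    if bss <= 0.0:
        raise ValueError(
            "BSS = 0 (all cluster means equal); the WSS/BSS index is undefined "
            "for this partition"
        )
    return wss, bss, tss, wss / bss


def _normalize(Y, mode):
    """Preprocess counts for clustering.

    mode True/"library": scale each cell to the median library size, then
    log1p (removes depth differences); "log": log1p only (keeps overall
    expression-level differences between cells); False: raw counts.
    """
    Y = np.asarray(Y, dtype=float)
    if mode is True or mode == "library":
        lib = Y.sum(axis=0)
        lib = np.where(lib > 0, lib, 1.0)
        return np.log1p(Y * (np.median(lib) / lib))
    if mode == "log":
        return np.log1p(Y)
    return Y


def optimal_cluster_number(
    counts,
    h_range=range(2, 11),
    seed=0,
    n_init=10,
    normalize=True,
    elbow_frac=0.05,
    max_retries=3,
):
    """Scan candidate cluster numbers and select by the flattening rule.

    ``counts`` is a genes x cells matrix (or UMICountMatrix).  For each h
    in ``h_range``, k-means (k-means++ initialization, ``n_init``
    restarts, seeded) partitions the cells; r_h = WSS/BSS is evaluated on
    the per-cell mean expression of the processed matrix.  The selected
    ``h_opt`` is the first h whose curve step |r_h - r_{h+1}| falls below
    ``elbow_frac`` of the initial step |r_2 - r_3|; a flat curve from the
    start yields h_opt = 2 with a "no structure" warning.
    """
    Y = getattr(counts, "counts", counts)
    if hasattr(Y, "toarray"):
        Y = Y.toarray()
    Y = np.asarray(Y, dtype=float)
    h_values = [int(h) for h in h_range]
    I = Y.shape[1]
    if min(h_values) < 2 or max(h_values) > I - 1:
        raise ValueError("candidate cluster numbers must lie in [2, n_cells - 1]")
    M = _normalize(Y, normalize)
    cell_values = M.mean(axis=0)  # per-cell mean expression
    X = M.T  # cells x genes for k-means
    rng = np.random.default_rng(seed)
    if np.ptp(cell_values) < 1e-12:
        # identical cells: the index is undefined (BSS = 0 everywhere)
        warnings.warn(
            "identical cells: no cluster structure detected; returning h_opt=2",
            stacklevel=2,
        )
        h0 = h_values[0]
        lab = KMeans(n_clusters=h0, n_init=n_init,
                     random_state=int(rng.integers(2**31 - 1))).fit_predict(X)
        nan = np.full(len(h_values), np.nan)
        return ClusterIndexCurve(
            h_values=np.asarray(h_values), r_h=nan, wss=nan, bss=nan, tss=nan,
            h_opt=int(h0), h_argmax=int(h0), labels_opt=lab, labels={h0: lab},
            no_structure=True,
        )
    wss_l, bss_l, tss_l, r_l, labels = [], [], [], [], {}
    for h in h_values:
        for attempt in range(max_retries + 1):
            km = KMeans(
                n_clusters=h,
                n_init=n_init,
                init="k-means++",
                random_state=int(rng.integers(2**31 - 1)),
            )
            lab = km.fit_predict(X)
            if len(np.unique(lab)) == h:
                break
            logger.warning("k-means returned an empty cluster at h=%d; retrying", h)
        labels[h] = lab
        w, b, t, r = cluster_index(cell_values, lab)
        wss_l.append(w)
        bss_l.append(b)
        tss_l.append(t)
        r_l.append(r)
    r_arr = np.asarray(r_l)
    h_argmax = h_values[int(np.argmax(r_arr))]
    no_structure = False
    if len(h_values) < 2:
        h_opt = h_values[0]
    else:
        base = abs(r_arr[0] - r_arr[1])
        scale = max(abs(r_arr[0]), 1e-12)
        if base <= 1e-6 * scale:
            no_structure = True
            warnings.warn(
                "index curve is flat from h=2: no cluster structure detected",
                stacklevel=2,
            )
            h_opt = h_values[0]
        else:
            h_opt = h_values[-1]
            for j in range(1, len(h_values) - 1):
                if abs(r_arr[j] - r_arr[j + 1]) < elbow_frac * base:
                    h_opt = h_values[j]
                    break
    return ClusterIndexCurve(
        h_values=np.asarray(h_values),
        r_h=r_arr,
        wss=np.asarray(wss_l),
        bss=np.asarray(bss_l),
        tss=np.asarray(tss_l),
        h_opt=int(h_opt),
        h_argmax=int(h_argmax),
        labels_opt=labels[int(h_opt)],
        labels=labels,
        no_structure=no_structure,
    )
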