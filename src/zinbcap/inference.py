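"""Likelihood-ratio tests for differential expression and zero inflation.

Two nested comparisons are made per gene, both within the joint ZINB-GLM
likelihood (cluster and covariate terms stay in both submodels so each
test isolates one parameter block):

* DE  — group contrasts removed from the log-mean model
        (H0: gamma_1j = 0); the statistic DS_j = -2 (l_constrained - l_full)
        is chi-square with L-1 df under H0 (1 df for two groups).
* DZI — group contrasts removed from the zero-inflation logit model
        (H10: beta_1j = 0); statistic DZ_j, same null distribution.

P-values are Benjamini-Hochberg adjusted across genes.  Each gene is then
classified from the two significance flags: DEZI (both), DE_only,
DZI_only, or non_influential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import DesignSpec, EMConfig, GeneGLMFit, _direct_matrices, _fit_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "GeneClass",
    "lrt_test",
    "adjust_pvalues",
    "classify_genes",
    "classify_label",
    "de_dzi_tests",
]

_LN2 = float(np.log(2.0))


@dataclass
class TestResult:
    gene_id: str
    target: str                # "DE" or "DZI"
    lfc: float                 # natural-log group coefficient
    lfc_log2: float
    stat: float
    df: int
    p_value: float
    p_adjusted: float | None = None
    fdr: float | None = None
    significant: bool | None = None
    reliable: bool = True


@dataclass(frozen=True)
class GeneClass:
    gene_id: str
    de_significant: bool
    dzi_significant: bool
    label: str


def classify_label(de_sig: bool, dzi_sig: bool) -> str:
    """Deterministic class label from the two significance flags."""
    if de_sig and dzi_sig:
        return "DEZI"
    if de_sig:
        return "DE_only"
    if dzi_sig:
        return "DZI_only"
    return "non_influential"


def _matrices(design: DesignSpec, capture=None):
    """Full and group-free model matrices, plus capture-adjusted offsets."""
    M_full, names_full, gcols = design.matrix(include_group=True)
    M_red, names_red, _ = design.matrix(include_group=False)
    if capture is None:
        log_p = np.zeros(design.n_cells)
    else:
        p_hat = getattr(capture, "p_hat", capture)
        log_p = np.log(np.clip(np.asarray(p_hat, dtype=float), 1e-8, 1.0))
    off_mu = design.offset_mu + log_p
    return M_full, names_full, gcols, M_red, names_red, off_mu, design.offset_pi


def _one_lrt(y, target, M_full, names_full, gcols, M_red, names_red,
             off_mu, off_pi, cfg, full_fit=None, gene_id="gene"):
    if full_fit is None:
        full_fit = _fit_matrices(
            y, M_full, M_full, names_full, names_full, gcols, gcols,
            off_mu, off_pi, cfg,
        )
    if target == "DE":
        fit_c = _fit_matrices(
            y, M_red, M_full, names_red, names_full, [], gcols, off_mu, off_pi, cfg
        )
        lfc = float(full_fit.coef_mu[gcols[0]]) if gcols else np.nan
    elif target == "DZI":
        fit_c = _fit_matrices(
            y, M_full, M_red, names_full, names_red, gcols, [], off_mu, off_pi, cfg
        )
        lfc = float(full_fit.coef_pi[gcols[0]]) if gcols else np.nan
    else:
        raise ValueError("target must be 'DE' or 'DZI'")
    stat = -2.0 * (fit_c.loglik - full_fit.loglik)
    reliable = True
    if stat < -1e-6:
        # constrained beat full: polish both with the simplex optimizer
        logger.info("gene %s %s: negative LRT %.3g; refitting", gene_id, target, stat)
        full_fit = _direct_matrices(
            y, M_full, M_full, names_full, names_full, gcols, gcols,
            off_mu, off_pi, cfg, init=full_fit,
        )
        if target == "DE":
            fit_c = _direct_matrices(y, M_red, M_full, names_red, names_full,
                                     [], gcols, off_mu, off_pi, cfg, init=fit_c)
            lfc = float(full_fit.coef_mu[gcols[0]]) if gcols else np.nan
        else:
            fit_c = _direct_matrices(y, M_full, M_red, names_full, names_red,
                                     gcols, [], off_mu, off_pi, cfg, init=fit_c)
            lfc = float(full_fit.coef_pi[gcols[0]]) if gcols else np.nan
        stat = -2.0 * (fit_c.loglik - full_fit.loglik)
        if stat < -1e-6:
            reliable = False
    stat = max(stat, 0.0)
    df = max(len(gcols), 1)
    p = float(stats.chi2.sf(stat, df))
    return TestResult(
        gene_id=gene_id, target=target, lfc=lfc, lfc_log2=lfc / _LN2,
        stat=float(stat), df=df, p_value=p, reliable=reliable,
    ), full_fit


def lrt_test(y, design: DesignSpec, target: str, capture=None,
             config: EMConfig | None = None, gene_id="gene") -> TestResult:
    """Likelihood-ratio test of one gene for DE or DZI.

    The full model carries group terms in both the mean and zero models;
    the constrained model removes them from the target block only.
    """
    if design.n_group_params < 1:
        raise ValueError("group design must have >= 2 groups to test")
    cfg = config or EMConfig()
    y = np.asarray(y, dtype=np.int64)
    mats = _matrices(design, capture)
    res, _ = _one_lrt(y, target, *mats, cfg, gene_id=gene_id)
    return res


def adjust_pvalues(p_values, method: str = "BH"):
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted, fdr); the BH-adjusted p-value of a gene is the
    smallest FDR level at which it would be declared significant, so the
    fdr column repeats the adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method.upper() != "BH":
        raise ValueError("only the BH procedure is implemented")
    adj = stats.false_discovery_control(p, method="bh")
    return adj, adj.copy()


def classify_genes(de, dzi, alpha: float = 0.05):
    """Classify genes from DE and DZI results (must cover the same genes).

    ``de``/``dzi`` are DataFrames with gene_id and p_adjusted columns (as
    produced by :func:`de_dzi_tests`) or lists of :class:`TestResult`.
    """
    def frame(res):
        if isinstance(res, pd.DataFrame):
            return res
        return pd.DataFrame(
            [{"gene_id": r.gene_id, "p_adjusted": r.p_adjusted} for r in res]
        )

    de_f, dzi_f = frame(de), frame(dzi)
    de_genes, dzi_genes = set(de_f.gene_id), set(dzi_f.gene_id)
    if de_genes != dzi_genes:
        raise ValueError(
            "DE and DZI results cover different gene sets; "
            f"only in DE: {sorted(de_genes - dzi_genes)[:10]}, "
            f"only in DZI: {sorted(dzi_genes - de_genes)[:10]}"
        )
    merged = de_f[["gene_id", "p_adjusted"]].merge(
        dzi_f[["gene_id", "p_adjusted"]], on="gene_id", suffixes=("_de", "_dzi")
    )
    out = []
    for _, row in merged.iterrows():
        de_sig = bool(row.p_adjusted_de <= alpha)
        dzi_sig = bool(row.p_adjusted_dzi <= alpha)
        out.append(
            GeneClass(
                gene_id=row.gene_id,
                de_significant=de_sig,
                dzi_significant=dzi_sig,
                label=classify_label(de_sig, dzi_sig),
            )
        )
    return out


def de_dzi_tests(counts, design: DesignSpec, capture=None, alpha: float = 0.05,
                 config: EMConfig | None = None, gene_ids=None) -> pd.DataFrame:
    """Run DE and DZI LRTs for every gene, sharing the full-model fit.

    Returns a tidy DataFrame with one row per gene and test, including
    BH-adjusted p-values (per test family), significance flags at
    ``alpha``, and the influence class label per gene.
    """
    from .io import UMICountMatrix

    cfg = config or EMConfig()
    if isinstance(counts, UMICountMatrix):
        Y = counts.dense()
        gene_ids = list(counts.gene_ids)
    else:
        Y = np.atleast_2d(np.asarray(counts))
        if gene_ids is None:
            gene_ids = [f"gene_{j}" for j in range(Y.shape[0])]
    mats = _matrices(design, capture)
    rows = []
    for j in range(Y.shape[0]):
        y = Y[j].astype(np.int64)
        if not np.any(y > 0):
            logger.warning("gene %s is all zero; skipped", gene_ids[j])
            continue
        de_res, full_fit = _one_lrt(y, "DE", *mats, cfg, gene_id=gene_ids[j])
        dzi_res, _ = _one_lrt(
            y, "DZI", *mats, cfg, full_fit=full_fit, gene_id=gene_ids[j]
        )
        rows.extend([de_res, dzi_res])
    frame = pd.DataFrame([r.__dict__ for r in rows])
    frame["p_adjusted"] = np.nan
    frame["fdr"] = np.nan
    frame["significant"] = False
    for target in ("DE", "DZI"):
        mask = frame.target == target
        adj, fdr = adjust_pvalues(frame.loc[mask, "p_value"].to_numpy())
        frame.loc[mask, "p_adjusted"] = adj
        frame.loc[mask, "fdr"] = fdr
        frame.loc[mask, "significant"] = adj <= alpha
    # per-gene class labels
    de_sig = frame[frame.target == "DE"].set_index("gene_id").significant
    dzi_sig = frame[frame.target == "DZI"].set_index("gene_id").significant
    frame["gene_class"] = [
        classify_label(bool(de_sig[g]), bool(dzi_sig[g])) for g in frame.gene_id
    ]
    return frame
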