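"""Gene-wise ZINB-GLM estimation by EM with a direct-search fallback.

Each gene's counts across cells are modeled as ZINB with cell-specific
parameters tied to cell-level covariates through two GLMs:

    log mu'_i   = x_i' gamma + r_i' w + c_i' s + O_mu_i      (NB mean, log link)
    logit pi_i  = x_i' beta  + r_i' u + c_i' v + O_pi_i      (zero inflation)
    log theta   = omega                                      (gene-level size)

where x are group indicators (with intercept), r cluster indicators,
c further cell covariates, and O_mu / O_pi per-cell offsets.  Including
log(p_hat_i) in O_mu makes the fitted mean estimate the *true* expression
mu rather than the capture-attenuated mu' = mu * p.

Estimation treats the component membership of each count (structural zero
vs NB draw) as missing data: the E-step computes posterior membership
weights, the M-step runs a weighted logistic regression for the zero
model, a weighted NB regression for the mean model, and a profile
update of theta.  The observed-data log-likelihood is monitored and is
non-decreasing across iterations (a step-halving safeguard enforces this
against floating-point slack).  Genes where EM stalls fall back to
derivative-free Nelder-Mead maximization of the same likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "make_design",
    "EMConfig",
    "GeneGLMFit",
    "e_step_weights",
    "em_fit_gene",
    "direct_mle_fallback",
    "fit_all_genes",
    "fits_to_frame",
]

_ETA_MAX = 30.0


def _clip(x, lo, hi):
    return np.minimum(np.maximum(x, lo), hi)


def _nb_logpmf_fast(y, mu, theta, gly1=None):
    """Weighted-likelihood workhorse: NB log pmf without scipy dispatch."""
    mu = np.maximum(mu, 1e-12)
    if gly1 is None:
        gly1 = special.gammaln(y + 1.0)
    lt = np.log(theta + mu)
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - gly1
        + theta * (np.log(theta) - lt)
        + y * (np.log(mu) - lt)
    )


def _zinb_loglik(y, mu, pi, theta, gly1=None, at0=None):
    """Observed-data (incomplete) ZINB log-likelihood, summed over cells."""
    lnb = _nb_logpmf_fast(y, mu, theta, gly1)
    pi = _clip(pi, 0.0, 1.0 - 1e-12)
    ll = np.log1p(-pi) + lnb
    if at0 is None:
        at0 = y == 0
    if np.any(at0):
        with np.errstate(divide="ignore"):
            ll0 = np.logaddexp(np.log(np.maximum(pi, 1e-300)), ll)
        ll0 = np.where(pi > 0, ll0, ll)
        ll = np.where(at0, ll0, ll)
    return float(np.sum(ll))


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignSpec:
    """Covariate structure shared by the mean and zero-inflation GLMs.

    ``X`` is the cells x L group design whose first column is the
    intercept (all ones); remaining columns are group contrasts.  ``R``
    is an optional cells x K one-hot cluster design (the first cluster is
    absorbed into the intercept), ``C`` optional further covariates.
    ``offset_mu`` / ``offset_pi`` are per-cell offsets; capture
    adjustment adds log(p_hat) to ``offset_mu`` downstream.
    """

    X: np.ndarray
    R: np.ndarray | None = None
    C: np.ndarray | None = None
    offset_mu: np.ndarray | None = None
    offset_pi: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        I = self.X.shape[0]
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be the intercept (all ones)")
        if self.R is not None:
            self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
            if self.R.shape[0] != I:
                raise ValueError("R must have one row per cell")
            if not (np.all((self.R == 0) | (self.R == 1)) and np.allclose(self.R.sum(1), 1)):
                raise ValueError("R rows must be one-hot over clusters")
        if self.C is not None:
            self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
            if self.C.shape[0] != I:
                raise ValueError("C must have one row per cell")
        for name in ("offset_mu", "offset_pi"):
            off = getattr(self, name)
            if off is None:
                setattr(self, name, np.zeros(I))
            else:
                off = np.asarray(off, dtype=float)
                if off.shape != (I,):
                    raise ValueError(f"{name} must be a length-{I} vector")
                setattr(self, name, off)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_group_params(self) -> int:
        """Number of group-contrast parameters (L - 1 for L groups)."""
        return self.X.shape[1] - 1

    def matrix(self, include_group: bool = True):
        """Assemble the model matrix [1 | group | cluster | covariates].

        Aliased (rank-deficient) columns are dropped with a warning, e.g.
        when cluster membership is confounded with group membership.
        Returns (matrix, names, group_cols) where ``group_cols`` indexes
        the group-contrast columns in the assembled matrix.
        """
        blocks = [self.X[:, :1]]
        names = ["intercept"]
        group_cols = []
        if include_group and self.X.shape[1] > 1:
            blocks.append(self.X[:, 1:])
            group_cols = list(range(1, self.X.shape[1]))
            names += [f"group{j}" for j in range(1, self.X.shape[1])]
        if self.R is not None and self.R.shape[1] > 1:
            blocks.append(self.R[:, 1:])  # first cluster absorbed by intercept
            names += [f"cluster{k}" for k in range(1, self.R.shape[1])]
        if self.C is not None:
            blocks.append(self.C)
            names += [f"cov{m}" for m in range(self.C.shape[1])]
        M = np.column_stack(blocks)
        keep = _independent_columns(M)
        if len(keep) < M.shape[1]:
            dropped = [names[j] for j in range(M.shape[1]) if j not in keep]
            logger.warning("dropping aliased design columns: %s", dropped)
            group_cols = [keep.index(j) for j in group_cols if j in keep]
            M = M[:, keep]
            names = [names[j] for j in keep]
        else:
            group_cols = list(group_cols)
        return M, names, group_cols


def _independent_columns(M: np.ndarray) -> list:
    """Greedy left-to-right selection of linearly independent columns."""
    keep: list[int] = []
    rank = 0
    for j in range(M.shape[1]):
        sub = M[:, keep + [j]]
        r = np.linalg.matrix_rank(sub)
        if r > rank:
            keep.append(j)
            rank = r
    return keep


def make_design(
    groups,
    clusters=None,
    covariates=None,
    offset_mu=None,
    offset_pi=None,
) -> DesignSpec:
    """Build a :class:`DesignSpec` from per-cell labels.

    ``groups``/``clusters`` are categorical label vectors; ``covariates``
    an optional cells x M numeric array or DataFrame.
    """
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    I = groups.shape[0]
    X = np.ones((I, len(levels)))
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (groups == lev).astype(float)
    R = None
    if clusters is not None:
        clusters = np.asarray(clusters)
        clevels = pd.unique(clusters)
        R = np.zeros((I, len(clevels)))
        for k, lev in enumerate(clevels):
            R[:, k] = (clusters == lev).astype(float)
    C = None
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != I:
            C = C.T
    return DesignSpec(X=X, R=R, C=C, offset_mu=offset_mu, offset_pi=offset_pi)


# ---------------------------------------------------------------------------
# configuration and fit container


@dataclass
class EMConfig:
    tol: float = 1e-6          # |delta loglik| convergence threshold
    max_iter: int = 100
    theta_min: float = 1e-2
    theta_max: float = 1e4
    ridge: float = 1e-8        # numerical ridge in the M-step solves
    fallback: bool = True      # Nelder-Mead on EM non-convergence
    irls_iter: int = 50
    irls_tol: float = 1e-9


@dataclass
class GeneGLMFit:
    """Per-gene fit: coefficient vectors, theta, weights, likelihood."""

    coef_mu: np.ndarray
    coef_pi: np.ndarray
    names_mu: list
    names_pi: list
    log_theta: float
    loglik: float
    weights: np.ndarray          # posterior count-component weights w_i
    converged: bool
    n_iter: int
    method: str                  # "em" or "direct"
    group_cols_mu: list = field(default_factory=list)
    group_cols_pi: list = field(default_factory=list)
    loglik_trace: np.ndarray | None = None
    fitted_mu: np.ndarray | None = None   # per-cell NB mean incl. offsets
    fitted_pi: np.ndarray | None = None

    @property
    def theta(self) -> float:
        return float(np.exp(self.log_theta))

    @property
    def phi(self) -> float:
        return 1.0 / self.theta

    def _block(self, coef, names, prefix):
        return np.array([c for c, n in zip(coef, names) if n.startswith(prefix)])

    @property
    def gamma(self):
        """Intercept + group effects on the log mean."""
        return np.concatenate(
            [self.coef_mu[:1], self._block(self.coef_mu, self.names_mu, "group")]
        )

    @property
    def w(self):
        return self._block(self.coef_mu, self.names_mu, "cluster")

    @property
    def s(self):
        return self._block(self.coef_mu, self.names_mu, "cov")

    @property
    def beta(self):
        """Intercept + group effects on the zero-inflation logit."""
        return np.concatenate(
            [self.coef_pi[:1], self._block(self.coef_pi, self.names_pi, "group")]
        )

    @property
    def u(self):
        return self._block(self.coef_pi, self.names_pi, "cluster")

    @property
    def v(self):
        return self._block(self.coef_pi, self.names_pi, "cov")

    def point_params(self):
        """Reference-cell ZINB parameters (pi, mu, theta) from the intercepts.

        With an intercept-only design these are the gene's MLEs; with
        covariates they describe the reference group/cluster.
        """
        from .distributions import ZINBParams

        return ZINBParams(
            pi=float(special.expit(self.coef_pi[0])),
            mu=float(np.exp(self.coef_mu[0])),
            theta=self.theta,
        )


# ---------------------------------------------------------------------------
# E-step


def e_step_weights(y, pi, mu_prime, theta):
    """Posterior probability that each count came from the NB component.

    w_i = (1-pi_i) f_NB(y_i) / (pi_i delta_0(y_i) + (1-pi_i) f_NB(y_i));
    exactly 1 for y_i > 0 since the point mass vanishes off zero.
    """
    y = np.asarray(y)
    pi = np.broadcast_to(np.asarray(pi, dtype=float), y.shape)
    mu_prime = np.broadcast_to(np.asarray(mu_prime, dtype=float), y.shape)
    w = np.ones(y.shape, dtype=float)
    if np.any((pi >= 1.0) & (y > 0)):
        warnings.warn(
            "pi = 1 with a positive count: weight defined as 1", stacklevel=2
        )
    at0 = y == 0
    if np.any(at0):
        th = theta
        f0 = np.exp(th * (np.log(th) - np.log(th + np.clip(mu_prime[at0], 1e-12, None))))
        num = (1.0 - pi[at0]) * f0
        w[at0] = num / (pi[at0] + num)
    return w


# ---------------------------------------------------------------------------
# M-step solvers (damped Newton / IRLS)


def _weighted_logistic(v, X, offset, coef0, cfg: EMConfig, ridge=None):
    """Weighted logistic regression with fractional response v in [0,1]."""
    ridge = cfg.ridge if ridge is None else ridge
    coef = coef0.copy()
    eye = np.eye(X.shape[1])

    def ll(c):
        eta = _clip(X @ c + offset, -_ETA_MAX, _ETA_MAX)
        return float(v @ eta - np.sum(np.logaddexp(0.0, eta))) - 0.5 * ridge * c @ c

    ll_old = ll(coef)
    for _ in range(cfg.irls_iter):
        eta = _clip(X @ coef + offset, -_ETA_MAX, _ETA_MAX)
        p = special.expit(eta)
        W = p * (1.0 - p) + 1e-10
        g = X.T @ (v - p) - ridge * coef
        H = X.T @ (W[:, None] * X) + ridge * eye
        step = np.linalg.solve(H, g)
        # damped Newton: halve until the penalized likelihood does not drop
        for _h in range(30):
            cand = coef + step
            ll_new = ll(cand)
            if ll_new >= ll_old - 1e-12:
                break
            step *= 0.5
        if np.max(np.abs(cand - coef)) < cfg.irls_tol:
            coef, ll_old = cand, ll_new
            break
        coef, ll_old = cand, ll_new
    if np.max(np.abs(coef)) > 25.0 and ridge < 1e-3:
        logger.warning("possible separation in the logistic step; ridge-stabilized refit")
        return _weighted_logistic(v, X, offset, coef0, cfg, ridge=1e-2)
    return coef


def _weighted_nb(y, X, offset, w, theta, coef0, cfg: EMConfig, gly1=None):
    """Weighted NB regression (log link, fixed theta) by damped Newton."""
    coef = coef0.copy()
    eye = np.eye(X.shape[1])
    wy = w * y
    wyt = w * (y + theta)

    def pll(c):
        # weighted NB log-likelihood minus terms constant in the coefficients
        eta = _clip(X @ c + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        return float(wy @ np.log(np.maximum(mu, 1e-12)) - wyt @ np.log(theta + mu))

    ll_old = pll(coef)
    for _ in range(cfg.irls_iter):
        eta = _clip(X @ coef + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        r = theta / (theta + mu)
        W = w * mu * r + 1e-12
        g = X.T @ (w * (y - mu) * r)
        H = X.T @ (W[:, None] * X) + cfg.ridge * eye
        step = np.linalg.solve(H, g)
        for _h in range(30):
            cand = coef + step
            ll_new = pll(cand)
            if ll_new >= ll_old - 1e-12:
                break
            step *= 0.5
        if np.max(np.abs(cand - coef)) < cfg.irls_tol:
            coef, ll_old = cand, ll_new
            break
        coef, ll_old = cand, ll_new
    return coef


def _profile_theta(y, mu, w, theta0, cfg: EMConfig):
    """Profile update of theta maximizing the weighted NB likelihood."""
    sw = float(np.sum(w))

    def nll(lt):
        th = np.exp(lt)
        # weighted NB ll terms that depend on theta only
        return -float(
            w @ special.gammaln(y + th)
            - sw * special.gammaln(th)
            + sw * th * np.log(th)
            - w * (y + th) @ np.log(th + mu)
        )

    res = optimize.minimize_scalar(
        nll,
        bounds=(np.log(cfg.theta_min), np.log(cfg.theta_max)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    # accept only an improvement over the current theta
    if -res.fun >= -nll(np.log(theta0)):
        return float(np.exp(res.x))
    return float(theta0)


def _profile_theta_observed(y, mu, pi, theta0, cfg: EMConfig, gly1, at0):
    """ECME-style dispersion update: profile theta on the observed-data
    log-likelihood directly (rather than the E-step surrogate), which
    breaks the slow pi-theta ridge that plain EM crawls along."""

    def nll(lt):
        return -_zinb_loglik(y, mu, pi, float(np.exp(lt)), gly1, at0)

    res = optimize.minimize_scalar(
        nll,
        bounds=(np.log(cfg.theta_min), np.log(cfg.theta_max)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    if -res.fun >= -nll(np.log(theta0)):
        return float(np.exp(res.x))
    return float(theta0)


# ---------------------------------------------------------------------------
# EM driver


def _initial_values(y, off_mu, off_pi, p_mu, p_pi, cfg: EMConfig):
    m = float(np.mean(y))
    v = float(np.var(y))
    theta0 = np.clip(m**2 / max(v - m, 1e-8), cfg.theta_min, 1e3)
    zero_frac = float(np.mean(y == 0))
    nb_zero = (theta0 / (theta0 + max(m, 1e-8))) ** theta0
    pi0 = float(np.clip(zero_frac - nb_zero, 0.01, 0.95))
    mean_off = float(np.mean(np.exp(np.clip(off_mu, -_ETA_MAX, _ETA_MAX))))
    coef_mu = np.zeros(p_mu)
    coef_mu[0] = np.log(max(m / max((1.0 - pi0) * mean_off, 1e-8), 1e-8))
    coef_pi = np.zeros(p_pi)
    coef_pi[0] = special.logit(pi0) - float(np.mean(off_pi))
    return coef_mu, coef_pi, float(theta0)


def _em_core(y, Xmu, Xpi, off_mu, off_pi, cfg: EMConfig):
    y = np.asarray(y, dtype=np.int64)
    gly1 = special.gammaln(y + 1.0)
    coef_mu, coef_pi, theta = _initial_values(
        y, off_mu, off_pi, Xmu.shape[1], Xpi.shape[1], cfg
    )
    no_zeros = not np.any(y == 0)
    if no_zeros:
        coef_pi = np.zeros(Xpi.shape[1])
        coef_pi[0] = -15.0  # pi ~ 3e-7: zero component empty

    at0 = y == 0

    def fitted(cm, cp):
        mu = np.exp(_clip(Xmu @ cm + off_mu, -_ETA_MAX, _ETA_MAX))
        pi = special.expit(_clip(Xpi @ cp + off_pi, -_ETA_MAX, _ETA_MAX))
        return mu, pi

    mu, pi = fitted(coef_mu, coef_pi)
    ll = _zinb_loglik(y, mu, pi, theta, gly1, at0)
    trace = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        # E-step: posterior count-component weights at current parameters
        w = e_step_weights(y, pi, mu, theta)
        v = 1.0 - w
        # M-step
        if no_zeros or v.max() < 1e-12:
            new_pi_coef = coef_pi
        else:
            new_pi_coef = _weighted_logistic(v, Xpi, off_pi, coef_pi, cfg)
        new_mu_coef = _weighted_nb(y, Xmu, off_mu, w, theta, coef_mu, cfg, gly1)
        mu_new = np.exp(_clip(Xmu @ new_mu_coef + off_mu, -_ETA_MAX, _ETA_MAX))
        # profiling theta on alternate sweeps keeps the update cheap
        if n_iter <= 3 or n_iter % 2 == 0:
            pi_new = special.expit(_clip(Xpi @ new_pi_coef + off_pi, -_ETA_MAX, _ETA_MAX))
            new_theta = _profile_theta_observed(y, mu_new, pi_new, theta, cfg, gly1, at0)
        else:
            new_theta = theta
        mu_c, pi_c = fitted(new_mu_coef, new_pi_coef)
        ll_new = _zinb_loglik(y, mu_c, pi_c, new_theta, gly1, at0)
        if ll_new < ll - 1e-10:
            # floating-point slack: pull the update back toward the
            # previous parameters until the likelihood does not decrease
            frac, ok = 0.5, False
            for _ in range(10):
                cm = coef_mu + frac * (new_mu_coef - coef_mu)
                cp = coef_pi + frac * (new_pi_coef - coef_pi)
                th = float(np.exp(np.log(theta) + frac * (np.log(new_theta) - np.log(theta))))
                mu_c, pi_c = fitted(cm, cp)
                ll_c = _zinb_loglik(y, mu_c, pi_c, th, gly1, at0)
                if ll_c >= ll - 1e-12:
                    new_mu_coef, new_pi_coef, new_theta, ll_new = cm, cp, th, ll_c
                    ok = True
                    break
                frac *= 0.5
            if not ok:
                break  # keep previous parameters; EM has stalled
        elif n_iter >= 2:
            # monotone acceleration: EM converges linearly, so try
            # extrapolating the sweep's step; keep only a strict improvement
            d_mu = new_mu_coef - coef_mu
            d_pi = new_pi_coef - coef_pi
            d_lt = np.log(new_theta) - np.log(theta)
            for mult in (4.0, 2.0):
                cm = coef_mu + mult * d_mu
                cp = coef_pi + mult * d_pi
                th = float(np.exp(np.clip(np.log(theta) + mult * d_lt,
                                          np.log(cfg.theta_min), np.log(cfg.theta_max))))
                mu_c, pi_c = fitted(cm, cp)
                ll_c = _zinb_loglik(y, mu_c, pi_c, th, gly1, at0)
                if ll_c > ll_new:
                    new_mu_coef, new_pi_coef, new_theta, ll_new = cm, cp, th, ll_c
                    break
        profiled = n_iter <= 3 or n_iter % 2 == 0
        coef_mu, coef_pi, theta = new_mu_coef, new_pi_coef, new_theta
        mu, pi = fitted(coef_mu, coef_pi)
        delta = ll_new - ll
        ll = ll_new
        trace.append(ll)
        if abs(delta) < cfg.tol and profiled:
            # convergence is only declared on sweeps that refreshed theta
            converged = True
            break
        if n_iter >= 25 and delta > 0.9 * (trace[-11] - trace[-12]):
            break  # likelihood creeping at a near-constant rate: stalled
    w = e_step_weights(y, pi, mu, theta)
    return dict(
        coef_mu=coef_mu,
        coef_pi=coef_pi,
        log_theta=float(np.log(theta)),
        loglik=ll,
        weights=w,
        converged=converged,
        n_iter=n_iter,
        trace=np.asarray(trace),
        fitted_mu=mu,
        fitted_pi=pi,
    )


def _lbfgs_polish(y, Xmu, Xpi, off_mu, off_pi, cfg, x0):
    """Quasi-Newton refinement of the observed-data likelihood with the
    analytic gradient; used to finish off genes where EM stalls on the
    pi-mu ridge.  Returns (x, loglik, success)."""
    y = np.asarray(y, dtype=np.int64)
    gly1 = special.gammaln(y + 1.0)
    at0 = y == 0
    p_mu, p_pi = Xmu.shape[1], Xpi.shape[1]
    lt_lo, lt_hi = np.log(cfg.theta_min), np.log(cfg.theta_max)

    def fun_grad(x):
        cm = x[:p_mu]
        cp = x[p_mu : p_mu + p_pi]
        lt = float(np.clip(x[-1], lt_lo, lt_hi))
        th = np.exp(lt)
        eta_mu = _clip(Xmu @ cm + off_mu, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta_mu)
        pi = special.expit(_clip(Xpi @ cp + off_pi, -_ETA_MAX, _ETA_MAX))
        ll = _zinb_loglik(y, mu, pi, th, gly1, at0)
        w = e_step_weights(y, pi, mu, th)
        v = 1.0 - w
        g_mu = Xmu.T @ (w * (y - mu) * th / (th + mu))
        g_pi = Xpi.T @ (v - pi)
        dlt = th * float(
            w
            @ (
                special.digamma(y + th)
                - special.digamma(th)
                + np.log(th)
                + 1.0
                - np.log(th + mu)
                - (y + th) / (th + mu)
            )
        )
        return -ll, -np.concatenate([g_mu, g_pi, [dlt]])

    bounds = [(None, None)] * (p_mu + p_pi) + [(lt_lo, lt_hi)]
    res = optimize.minimize(
        fun_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7},
    )
    return res.x, -float(res.fun), bool(res.success)


def _fit_matrices(y, Xmu, Xpi, names_mu, names_pi, gcols_mu, gcols_pi, off_mu, off_pi, cfg):
    res = _em_core(y, Xmu, Xpi, off_mu, off_pi, cfg)
    fit = GeneGLMFit(
        coef_mu=res["coef_mu"],
        coef_pi=res["coef_pi"],
        names_mu=names_mu,
        names_pi=names_pi,
        log_theta=res["log_theta"],
        loglik=res["loglik"],
        weights=res["weights"],
        converged=res["converged"],
        n_iter=res["n_iter"],
        method="em",
        group_cols_mu=gcols_mu,
        group_cols_pi=gcols_pi,
        loglik_trace=res["trace"],
        fitted_mu=res["fitted_mu"],
        fitted_pi=res["fitted_pi"],
    )
    if not fit.converged and cfg.fallback:
        x0 = np.concatenate([fit.coef_mu, fit.coef_pi, [fit.log_theta]])
        x, ll, ok = _lbfgs_polish(y, Xmu, Xpi, off_mu, off_pi, cfg, x0)
        if ok and ll >= fit.loglik - 1e-9:
            p_mu = Xmu.shape[1]
            cm, cp, lt = x[:p_mu], x[p_mu:-1], float(x[-1])
            mu = np.exp(_clip(Xmu @ cm + off_mu, -_ETA_MAX, _ETA_MAX))
            pi = special.expit(_clip(Xpi @ cp + off_pi, -_ETA_MAX, _ETA_MAX))
            theta = float(np.exp(lt))
            return GeneGLMFit(
                coef_mu=cm, coef_pi=cp, names_mu=names_mu, names_pi=names_pi,
                log_theta=lt, loglik=max(ll, fit.loglik),
                weights=e_step_weights(y, pi, mu, theta),
                converged=True, n_iter=fit.n_iter, method="direct",
                group_cols_mu=gcols_mu, group_cols_pi=gcols_pi,
                loglik_trace=np.append(fit.loglik_trace, max(ll, fit.loglik)),
                fitted_mu=mu, fitted_pi=pi,
            )
        fb = _direct_matrices(y, Xmu, Xpi, names_mu, names_pi, gcols_mu, gcols_pi,
                              off_mu, off_pi, cfg, init=fit)
        if fb.loglik > fit.loglik:
            return fb
    return fit


def em_fit_gene(y, design: DesignSpec, config: EMConfig | None = None) -> GeneGLMFit:
    """Fit one gene's ZINB-GLM by EM (with optional fallback on stall)."""
    y = np.asarray(y, dtype=np.int64)
    if not np.any(y > 0):
        raise ValueError("gene has no non-zero counts; filter before fitting")
    cfg = config or EMConfig()
    Xmu, names_mu, gm = design.matrix(include_group=True)
    Xpi, names_pi, gp = design.matrix(include_group=True)
    return _fit_matrices(
        y, Xmu, Xpi, names_mu, names_pi, gm, gp, design.offset_mu, design.offset_pi, cfg
    )


def _pack(fit_or_none, p_mu, p_pi, y, off_mu, off_pi, cfg):
    if fit_or_none is not None:
        return np.concatenate(
            [fit_or_none.coef_mu, fit_or_none.coef_pi, [fit_or_none.log_theta]]
        )
    cm, cp, th = _initial_values(np.asarray(y), off_mu, off_pi, p_mu, p_pi, cfg)
    return np.concatenate([cm, cp, [np.log(th)]])


def _direct_matrices(y, Xmu, Xpi, names_mu, names_pi, gcols_mu, gcols_pi,
                     off_mu, off_pi, cfg, init=None):
    y = np.asarray(y, dtype=np.int64)
    gly1 = special.gammaln(y + 1.0)
    p_mu, p_pi = Xmu.shape[1], Xpi.shape[1]

    at0 = y == 0

    def unpack(x):
        cm = x[:p_mu]
        cp = x[p_mu : p_mu + p_pi]
        lt = float(np.clip(x[-1], np.log(cfg.theta_min), np.log(cfg.theta_max)))
        mu = np.exp(_clip(Xmu @ cm + off_mu, -_ETA_MAX, _ETA_MAX))
        pi = special.expit(_clip(Xpi @ cp + off_pi, -_ETA_MAX, _ETA_MAX))
        return cm, cp, lt, mu, pi

    def nll(x):
        _, _, lt, mu, pi = unpack(x)
        return -_zinb_loglik(y, mu, pi, np.exp(lt), gly1, at0)

    x0 = _pack(init, p_mu, p_pi, y, off_mu, off_pi, cfg)
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"maxiter": 2000, "maxfev": 2000, "xatol": 1e-5, "fatol": 1e-7,
                 "adaptive": True},
    )
    cm, cp, lt, mu, pi = unpack(res.x)
    theta = float(np.exp(lt))
    loglik = -float(res.fun)
    if init is not None and init.loglik_trace is not None:
        trace = np.append(init.loglik_trace, max(loglik, init.loglik))
    else:
        trace = np.array([loglik])
    return GeneGLMFit(
        coef_mu=cm,
        coef_pi=cp,
        names_mu=names_mu,
        names_pi=names_pi,
        log_theta=lt,
        loglik=loglik,
        weights=e_step_weights(y, pi, mu, theta),
        converged=bool(res.success),
        n_iter=int(res.nit),
        method="direct",
        group_cols_mu=gcols_mu,
        group_cols_pi=gcols_pi,
        loglik_trace=trace,
        fitted_mu=mu,
        fitted_pi=pi,
    )


def direct_mle_fallback(y, design: DesignSpec, init: GeneGLMFit | None = None,
                        config: EMConfig | None = None) -> GeneGLMFit:
    """Maximize the observed-data likelihood by Nelder-Mead simplex search.

    Used when EM stalls; warm-starting from a partial EM fit (``init``)
    shortens the search considerably.
    """
    cfg = config or EMConfig()
    Xmu, names_mu, gm = design.matrix(include_group=True)
    Xpi, names_pi, gp = design.matrix(include_group=True)
    return _direct_matrices(
        np.asarray(y, dtype=np.int64), Xmu, Xpi, names_mu, names_pi, gm, gp,
        design.offset_mu, design.offset_pi, cfg, init=init,
    )


def fit_all_genes(counts, design: DesignSpec, capture=None,
                  config: EMConfig | None = None):
    """Fit every gene of a genes x cells matrix, with capture adjustment.

    ``capture`` is a :class:`~zinbcap.capture.CaptureRateEstimate` (or a
    per-cell vector, or None for p = 1).  log(p_hat) is added to the mean
    offset so the fitted NB mean estimates the true expression mu rather
    than the capture-attenuated mu' = mu * p.

    Returns (fits, status): a list of :class:`GeneGLMFit` (None where a
    gene could not be fit) and a status DataFrame.
    """
    from .io import UMICountMatrix

    cfg = config or EMConfig()
    if isinstance(counts, UMICountMatrix):
        Y = counts.dense()
        gene_ids = list(counts.gene_ids)
    else:
        Y = np.atleast_2d(np.asarray(counts))
        gene_ids = [f"gene_{j}" for j in range(Y.shape[0])]
    if capture is None:
        log_p = np.zeros(Y.shape[1])
    else:
        p_hat = getattr(capture, "p_hat", capture)
        log_p = np.log(np.clip(np.asarray(p_hat, dtype=float), 1e-8, 1.0))
    base = DesignSpec(
        X=design.X, R=design.R, C=design.C,
        offset_mu=design.offset_mu + log_p,
        offset_pi=design.offset_pi,
    )
    Xmu, names_mu, gm = base.matrix(include_group=True)
    fits, rows = [], []
    for j in range(Y.shape[0]):
        y = Y[j]
        if not np.any(y > 0):
            fits.append(None)
            rows.append((gene_ids[j], False, "all-zero", 0))
            continue
        try:
            fit = _fit_matrices(
                y, Xmu, Xmu, names_mu, names_mu, gm, gm,
                base.offset_mu, base.offset_pi, cfg,
            )
            fits.append(fit)
            rows.append((gene_ids[j], fit.converged, fit.method, fit.n_iter))
        except Exception as exc:  # individual failures are recorded, not fatal
            logger.warning("gene %s failed to fit: %s", gene_ids[j], exc)
            fits.append(None)
            rows.append((gene_ids[j], False, "error", 0))
    status = pd.DataFrame(rows, columns=["gene_id", "converged", "method", "n_iter"])
    return fits, status


def fits_to_frame(fits, gene_ids=None) -> pd.DataFrame:
    """Tabulate per-gene estimates (reference-cell pi/mu, theta, loglik)."""
    rows = []
    for j, fit in enumerate(fits):
        gid = gene_ids[j] if gene_ids is not None else f"gene_{j}"
        if fit is None:
            rows.append({"gene_id": gid})
            continue
        params = fit.point_params()
        rows.append(
            {
                "gene_id": gid,
                "pi_hat": params.pi,
                "mu_hat": params.mu,
                "theta_hat": fit.theta,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "method": fit.method,
                "n_iter": fit.n_iter,
            }
        )
    return pd.DataFrame(rows)
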