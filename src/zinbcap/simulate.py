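"""Synthetic UMI-count data with known ZINB truth and capture thinning.

The forward model mirrors the package's generative assumptions: per gene,
true counts Z ~ ZINB(pi, mu, theta) with group (and optional cluster)
effects on log mu and logit pi; observed counts Y | Z ~ Binomial(Z, p_i)
with a per-cell capture rate p_i.  The generator returns both matrices
plus full truth tables, so every estimator in the package can be
validated against known parameters.

Defaults (see docs/methods.md for rationale): 200 genes x 600 cells in
two equal groups; gene-level truth drawn as mu ~ log-uniform [0.5, 50],
theta ~ log-uniform [0.5, 10], pi ~ uniform [0.05, 0.6]; 10% of genes DE
with |gamma_1| = log 3 and 10% DZI with |beta_1| = 1.5 (random signs);
per-cell capture rates uniform on (0.1, 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .capture import SpikeInSet, thin_counts
from .distributions import zinb_sample

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_spikeins",
    "simulate_cell_populations",
    "default_spikein_ladder",
]


def default_spikein_ladder(n: int = 23, base: float = 0.5, rungs: int = 23) -> np.ndarray:
    """Two-fold concentration ladder (ERCC-like).

    ``rungs`` distinct concentrations, doubling from ``base``; if ``n``
    exceeds the number of rungs, concentrations repeat cyclically (ERCC
    panels carry several transcripts per abundance group).
    """
    ladder = base * 2.0 ** np.arange(min(n, rungs))
    return np.resize(ladder, n)


@dataclass
class SimulationConfig:
    n_genes: int = 200
    n_cells: int = 600
    n_groups: int = 2
    group_sizes: tuple | None = None        # default: equal split
    n_clusters: int = 1
    cluster_effect_sd: float = 0.0          # per-cluster log-mean shifts
    mu_range: tuple = (0.5, 50.0)           # log-uniform
    theta_range: tuple = (0.5, 10.0)        # log-uniform
    pi_range: tuple = (0.05, 0.6)           # uniform
    de_fraction: float = 0.1
    de_effect: float = float(np.log(3.0))   # |gamma_1| on log mean
    dzi_fraction: float = 0.1
    dzi_effect: float = 1.5                 # |beta_1| on logit pi
    capture: object = (0.1, 0.9)            # scalar p, per-cell vector, or uniform range
    seed: int | None = None

    def resolved_group_sizes(self):
        if self.group_sizes is not None:
            sizes = tuple(int(s) for s in self.group_sizes)
        else:
            base = self.n_cells // self.n_groups
            sizes = tuple(
                base + (1 if g < self.n_cells % self.n_groups else 0)
                for g in range(self.n_groups)
            )
        if sum(sizes) != self.n_cells or len(sizes) != self.n_groups:
            raise ValueError("group sizes must sum to n_cells across n_groups")
        return sizes

    def validate(self):
        if self.n_clusters > self.n_cells:
            raise ValueError("more clusters than cells")
        for frac in (self.de_fraction, self.dzi_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        self.resolved_group_sizes()


@dataclass
class SimulatedDataset:
    observed: np.ndarray          # genes x cells, capture-thinned
    true_counts: np.ndarray       # genes x cells, before thinning
    gene_truth: pd.DataFrame      # pi, mu, theta, de/dzi flags and effects
    cell_meta: pd.DataFrame       # group, cluster, p, library_size
    config: SimulationConfig

    @property
    def gene_ids(self):
        return list(self.gene_truth.gene_id)

    @property
    def cell_ids(self):
        return list(self.cell_meta.cell_id)


def _capture_rates(capture, n_cells, rng):
    if np.isscalar(capture):
        return np.full(n_cells, float(capture))
    arr = np.asarray(capture, dtype=float)
    if arr.shape == (2,) and arr[0] < arr[1] and n_cells != 2:
        return rng.uniform(arr[0], arr[1], size=n_cells)
    if arr.shape == (n_cells,):
        return arr
    raise ValueError("capture must be a scalar, a (lo, hi) range, or a per-cell vector")


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """Draw a full synthetic dataset with known truth.

    Reproducible given the seed (``seed`` argument overrides
    ``config.seed``).  Observed counts equal the true counts exactly when
    the capture rate is 1 everywhere.
    """
    config = config or SimulationConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    G, I = config.n_genes, config.n_cells
    sizes = config.resolved_group_sizes()
    group = np.repeat(np.arange(config.n_groups), sizes)
    cluster = rng.integers(0, config.n_clusters, size=I)
    p = _capture_rates(config.capture, I, rng)

    lo, hi = config.mu_range
    mu0 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))
    lo, hi = config.theta_range
    theta = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))
    pi0 = rng.uniform(*config.pi_range, size=G)

    n_de = int(round(config.de_fraction * G))
    n_dzi = int(round(config.dzi_fraction * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    dzi_idx = rng.choice(G, size=n_dzi, replace=False)
    gamma1 = np.zeros(G)
    gamma1[de_idx] = config.de_effect * rng.choice([-1.0, 1.0], size=n_de)
    beta1 = np.zeros(G)
    beta1[dzi_idx] = config.dzi_effect * rng.choice([-1.0, 1.0], size=n_dzi)

    clus_eff = (
        rng.normal(0.0, config.cluster_effect_sd, size=(G, config.n_clusters))
        if config.cluster_effect_sd > 0
        else np.zeros((G, config.n_clusters))
    )

    in_alt = (group > 0).astype(float)  # group 0 is the reference
    Z = np.empty((G, I), dtype=np.int64)
    for j in range(G):
        log_mu = np.log(mu0[j]) + gamma1[j] * in_alt + clus_eff[j, cluster]
        logit_pi = special.logit(pi0[j]) + beta1[j] * in_alt
        pi_cell = special.expit(logit_pi)
        mu_cell = np.exp(log_mu)
        nb = rng.negative_binomial(theta[j], theta[j] / (theta[j] + mu_cell))
        Z[j] = np.where(rng.random(I) < pi_cell, 0, nb)
    Y = thin_counts(Z, p, seed=rng)

    gene_truth = pd.DataFrame(
        {
            "gene_id": [f"gene_{j}" for j in range(G)],
            "pi": pi0,
            "mu": mu0,
            "theta": theta,
            "is_de": gamma1 != 0,
            "is_dzi": beta1 != 0,
            "gamma1": gamma1,
            "beta1": beta1,
        }
    )
    cell_meta = pd.DataFrame(
        {
            "cell_id": [f"cell_{i}" for i in range(I)],
            "group": [f"g{g}" for g in group],
            "cluster": cluster,
            "p": p,
            "library_size": Y.sum(axis=0),
        }
    )
    return SimulatedDataset(
        observed=Y, true_counts=Z, gene_truth=gene_truth,
        cell_meta=cell_meta, config=config,
    )


def simulate_spikeins(p, n_transcripts: int = 23, concentration_ladder=None,
                      noise: float = 0.05, seed: int | None = None) -> SpikeInSet:
    """Spike-in UMI counts matching the per-cell regression model.

    R_iu ~ NB(mean = p_i * C_u, size = 1/noise); ``noise = 0`` gives the
    deterministic limit R_iu = p_i * C_u exactly (values then need not be
    integers).  The default ladder is a 23-rung two-fold dilution series
    spanning well over one order of magnitude; the default dispersion
    (0.05) is the mildly super-Poissonian technical noise typical of
    deduplicated spike-in counts.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if concentration_ladder is None:
        C = default_spikein_ladder(n_transcripts)
    else:
        C = np.asarray(concentration_ladder, dtype=float)
    if C.max() / C.min() < 10.0:
        raise ValueError("concentration ladder must span >= 1 order of magnitude")
    mean = np.outer(p, C)
    if noise <= 0:
        R = mean
    else:
        size = 1.0 / noise
        rng = np.random.default_rng(seed)
        R = rng.negative_binomial(size, size / (size + mean))
    return SpikeInSet(concentrations=C, counts=R)


def simulate_cell_populations(n_pops: int, cells_per_pop: int = 100,
                              n_genes: int = 120, seed: int | None = None,
                              scale_step: float = 3.0, block_factor: float = 6.0,
                              pi: float = 0.1, theta: float = 5.0):
    """Well-separated cell populations for cluster-number recovery tests.

    Population c (c = 0..n_pops-1) scales its overall expression by
    ``scale_step**c`` and additionally upregulates a dedicated block of
    genes by ``block_factor``, so populations differ both in level and in
    composition.  Returns (counts genes x cells, labels).
    """
    rng = np.random.default_rng(seed)
    I = n_pops * cells_per_pop
    labels = np.repeat(np.arange(n_pops), cells_per_pop)
    base_mu = np.exp(rng.uniform(np.log(1.0), np.log(10.0), size=n_genes))
    block = max(1, n_genes // n_pops)
    Y = np.empty((n_genes, I), dtype=np.int64)
    for j in range(n_genes):
        mu_cell = base_mu[j] * scale_step ** labels.astype(float)
        owner = j // block if j // block < n_pops else None
        if owner is not None:
            mu_cell = mu_cell * np.where(labels == owner, block_factor, 1.0)
        nb = rng.negative_binomial(theta, theta / (theta + mu_cell))
        Y[j] = np.where(rng.random(I) < pi, 0, nb)
    return Y, labels
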