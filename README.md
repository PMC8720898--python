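# zinbcap

Statistical modeling of single-cell RNA-seq UMI counts that treats the
molecular capture process as part of the model, for analysts who need
differential expression results that are not confounded by dropout.

## The model

Single-cell protocols capture only a fraction of the transcript molecules
present in a cell, so observed UMI counts are a thinned, zero-heavy
reflection of true expression. `zinbcap` models the true count of gene *j*
in cell *i* as zero-inflated negative binomial,

    Z_ij ~ ZINB(pi_j, mu_j, theta_j),

and the observed count as a binomial draw over the captured molecules,

    Y_ij | Z_ij = z ~ Binomial(z, p_i),

with a per-cell capture rate `p_i`. Marginally `Y_ij ~ ZINB(pi_j,
mu_j * p_i, theta_j)`: thinning attenuates only the mean (`mu' = mu p`),
leaving the zero-inflation `pi` (the dropout/true-zero mixture weight) and
the dispersion `phi = 1/theta` untouched. The package builds on that
closure property:

* **Capture rates** are estimated per cell either by regressing spike-in
  UMI counts on known spike-in concentrations (the OLS slope is `p_hat_i`)
  or, without spike-ins, by mapping log10 library sizes linearly onto a
  range `(rho1, rho2)`.
* **Gene-wise estimation** ties `log mu'` and `logit pi` to cell-level
  covariates (group, cluster, cell cycle, ...) through two GLMs and
  maximizes the likelihood by EM, treating the zero-component membership
  as missing data. Including `log p_hat_i` as a mean offset makes the
  fitted mean estimate *true* expression rather than observed expression.
* **Sample statistics**: model-implied mean/variance of per-gene sample
  means and variances, with standard errors and coefficients of variation.
* **Cluster number**: k-means over a range of *h* plus the index
  `r_h = WSS/BSS` on per-cell mean expression; the elbow of the `r_h`
  curve selects the number of cell clusters.
* **Inference**: likelihood-ratio tests for differential expression
  (group effect on `log mu`, H0: gamma_1j = 0) and differential zero
  inflation (group effect on `logit pi`, H0: beta_1j = 0), chi-square
  with L−1 df, BH-adjusted; genes are classified as DEZI / DE-only /
  DZI-only / non-influential from the two significance flags.
* **Simulator**: generates UMI matrices from exactly this forward model
  with known truth, so every estimator is testable against ground truth.

## Worked example

```python
import zinbcap as z

# simulate a small study: 60 genes, 2 groups of 150 cells, known truth
sim = z.simulate_dataset(z.SimulationConfig(n_genes=60, n_cells=300, seed=7))

counts = z.UMICountMatrix(sim.observed, sim.gene_ids, sim.cell_ids)
counts = z.filter_genes(counts, min_cells=5)
capture = z.estimate_capture_librarysize(counts.library_sizes, rho1=0.1, rho2=0.9)
print(f"capture: p_bar={capture.p_bar:.3f}, var(p_hat)={capture.var_p:.4f}")

design = z.make_design(sim.cell_meta.group.to_numpy())
fits, status = z.fit_all_genes(counts, design, capture=capture)
params = fits[0].point_params()
print(f"gene_0: pi_hat={params.pi:.3f}, mu_hat={params.mu:.2f}, "
      f"theta_hat={params.theta:.2f}")

res = z.de_dzi_tests(counts, design, capture=capture, alpha=0.05)
per_gene = res[res.target == "DE"]
print("classes:", per_gene.gene_class.value_counts().to_dict())
top = per_gene.nsmallest(1, "p_adjusted").iloc[0]
print(f"top DE gene: {top.gene_id}, log2FC={top.lfc_log2:.2f}, "
      f"p_adj={top.p_adjusted:.2e}")
```

prints

```
capture: p_bar=0.565, var(p_hat)=0.0270
gene_0: pi_hat=0.258, mu_hat=9.39, theta_hat=1.11
classes: {'non_influential': 54, 'DE_only': 3, 'DZI_only': 3}
top DE gene: gene_36, log2FC=1.56, p_adj=1.61e-25
```

The simulated truth for `gene_0` was `pi=0.353, mu=9.58, theta=1.11`:
with the capture offset the fitted mean recovers true expression (9.39 vs
9.58) even though the cells captured only ~56% of molecules on average.
The top DE gene's `log2FC=1.56` matches the planted three-fold change
(`log2(3) = 1.58`). The class counts partition the 60 genes into those
with mean differences, zero-inflation differences, both, or neither.

The same pipeline is scriptable from the shell:

```sh
zinbcap simulate --n-genes 200 --n-cells 600 --seed 1 --outdir data/
zinbcap capture  --counts data/matrix.mtx --out capture.tsv
zinbcap test     --counts data/matrix.mtx --metadata data/cell_metadata.tsv \
                 --capture-file capture.tsv --out results.tsv
```

## Documentation

`docs/methods.md` describes the model, the estimation algorithm, all
tunable parameters with defaults, the synthetic-data generator, and known
limitations.
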