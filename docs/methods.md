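# Methods

## Model

True UMI counts of gene *j* in cell *i* are zero-inflated negative
binomial, `Z_ij ~ ZINB(pi_j, mu_j, theta_j)`: with probability `pi_j` the
count is a structural zero, otherwise it is NB with mean `mu_j` and size
`theta_j` (dispersion `phi_j = 1/theta_j`). Sequencing captures each
molecule independently with a cell-specific probability `p_i`, so
`Y_ij | Z_ij = z ~ Binomial(z, p_i)`. Marginalizing the thinning gives
`Y_ij ~ ZINB(pi_j, mu_j p_i, theta_j)` — the package's central identity,
verified in the test suite by brute-force summation of
`sum_z Binom(y|z,p) ZINB(z)` against the closed form to 1e-10 over a
parameter grid. Consequences used throughout:

* observed moments: `E(Y) = (1-pi) mu p`,
  `V(Y) = E(Y) [1 + mu p (pi + phi)]`;
* `pi` and `theta` are invariant to capture, so zero inflation estimated
  from observed data estimates the true-zero mixture weight;
* a `log p_i` offset in the mean model converts observed-scale estimates
  to true-expression scale.

All pmfs are evaluated in log space through the log-gamma function;
`mu = 0` is handled as a point mass at zero.

## Capture-rate estimation

**Spike-ins.** For each cell, OLS of the spike-in UMI counts on the known
molecular concentrations; the slope estimates `p_i` (the intercept is
kept as a diagnostic). Slopes are clamped to [0, 1] with raw values
retained, since a regression slope is not constrained to be a
probability. Error is multiplicative (the top rungs of the dilution
ladder dominate the fit), so the absolute accuracy of `p_hat` scales with
`p` — about 12% relative error at the default panel and noise level.

**Library size.** Without spike-ins, `p_hat_i = rho1 + (rho2 - rho1)
(L_i - L_min)/(L_max - L_min)` with `L_i = log10` library size, default
`(rho1, rho2) = (0.1, 0.9)`. This is a monotone heuristic proxy, exact
only at the extreme cells; equal library sizes degrade gracefully to the
midpoint with a warning.

Capture rates are gene-constant within a cell by assumption; the API
enforces this (one `p` per cell).

## Estimation

Each gene's parameters follow two GLMs — `log mu' = X gamma + R w + C s +
O_mu` (log link, NB) and `logit pi = X beta + R u + C v + O_pi`
(logistic) — with a single `log theta` per gene (no covariates on the
dispersion). `X` carries the intercept and group contrasts, `R` cluster
one-hots (first cluster absorbed into the intercept), `C` further
covariates; aliased columns are dropped with a warning. Default offsets
are `O_mu = log p_hat` and `O_pi = 0`; nothing in the model motivates a
nonzero zero-inflation offset, and `mu' = mu p` makes `log p` the exact
mean offset.

Maximum likelihood is computed by EM over the latent zero-component
membership. The E-step weight of the count component is
`w_i = (1-pi_i) f_NB(y_i) / (pi_i d0(y_i) + (1-pi_i) f_NB(y_i))`
(exactly 1 for positive counts). The M-step runs a weighted logistic
regression of the zero-membership posteriors, a weighted NB regression
for the mean coefficients (both small damped-Newton/IRLS solvers; the NB
step is cross-checked against statsmodels GLM in the tests), and a
bounded 1-D profile of `log theta`. Numerical policies:

* initialization: `theta` by method of moments clamped to [0.01, 1000];
  `pi` from the excess zero fraction over the NB-implied zero probability
  clamped to [0.01, 0.95]; mean intercept from the average count
  corrected for offsets and `pi`;
* convergence at `|delta loglik| < 1e-6`, at most 100 sweeps; the
  observed-data log-likelihood is monitored every sweep and a
  step-halving safeguard makes the trace non-decreasing to within 1e-8;
* acceleration: EM converges linearly on the pi–mu ridge typical of
  zero-heavy genes, so each sweep's step is tentatively extrapolated
  (×2, ×4) and kept only if it strictly increases the likelihood, and
  `theta` is profiled against the observed likelihood (an ECME-type
  step). Both preserve monotonicity by construction;
* genes whose likelihood still creeps at a near-constant rate are
  finished by an L-BFGS step on the observed likelihood with analytic
  gradients, and as a last resort by Nelder–Mead simplex search
  (`direct_mle_fallback`, also available directly). Fits report which
  route produced them (`method`: em/direct);
* logistic separation (e.g. a vanishing zero component) triggers a
  ridge-stabilized refit; data with no zeros bypass the logistic step
  entirely with `pi ≈ 0`.

Degenerate inputs: all-zero genes are rejected (and skipped with a log
entry by `fit_all_genes`); a gene with a single positive count returns
finite estimates through the fallback.

## Sample statistics

The cluster-balanced sample mean and variance of a gene are
`ybar = (1/K) sum_k mean_k(y)` and
`s2 = (1/K) sum_k (1/(I_k - 1)) sum_{i in k} (y_i - ybar)^2` — note the
inner deviations use the overall `ybar`, and every cluster needs at least
two cells. Their model-implied moments are computed *exactly* from the
per-cell means `m_i = (1-pi) mu p_i` and variances `v_i` by expanding
`E(ybar^2) - E(ybar)^2` and `E(y_i - ybar)^2` for independent cells:

    E(ybar) = sum_i a_i m_i,      V(ybar) = sum_i a_i^2 v_i,
    E(s2)   = (1/K) sum_k (1/(I_k-1)) sum_{i in k}
              [ v_i (1 - 2 a_i) + sum_i' a_i'^2 v_i' + (m_i - E ybar)^2 ]

with `a_i = 1/(K I_k(i))`. A coarser closed form written only in terms of
`(p_bar, p2_bar, var_p)` circulates for these quantities; it misplaces a
`1/I` factor on the between-cell spread term and drops `(1-pi)` factors,
so it does not match simulation except at `pi = 0` with constant capture.
It is retained behind `formula="printed"` for comparison; the default
exact form is validated by Monte-Carlo (2000 replicate datasets) to
within 4 standard errors. `var(p_hat)` uses the population (1/I)
divisor. Derived quantities follow the reporting conventions
`sd = sqrt(V(ybar))`, `SE = sd/sqrt(I)`, `CV = sd/E(ybar)`.

## Cluster-number selection

Cells are clustered by k-means (k-means++ initialization, 10 restarts,
seeded) for each candidate `h`. By default the matrix is library-size
scaled to the median depth and log1p-transformed (`normalize="log"` keeps
depth differences; `False` uses raw counts). The index `r_h = WSS/BSS`
is computed on per-cell mean expression of the same processed matrix, so
the ANOVA identity `WSS + BSS = TSS` holds exactly and `TSS` is constant
across `h`. `r_h` decreases as clusters tighten; the selected `h_opt` is
where the curve flattens — the first `h` with `|r_h - r_{h+1}| < 5%` of
the initial step `|r_2 - r_3|` (threshold configurable); the plain argmax
is also reported for transparency, and identical cells short-circuit to
`h_opt = 2` with a "no structure" warning. Planted-population recovery
(3–6 well-separated populations, 20 seeded runs) succeeds in ≥ 18 runs in
the test suite.

## Differential testing and classification

For each gene the full model carries group contrasts in both the mean and
zero-inflation submodels. The DE statistic removes them from the mean
model only, the DZI statistic from the zero model only, so each test
isolates one parameter block within the joint likelihood:
`stat = -2 (l_constrained - l_full)`, chi-square with `L-1` df (1 df for
two groups). Negative statistics beyond optimizer noise trigger a
simplex refit of both models; residual small negatives are clamped to 0.
Fold changes are reported in log2 (converted from the natural-log
coefficient). P-values are Benjamini–Hochberg adjusted per test family
(the adjusted value is the q-value-style FDR column). Classes: DEZI
(both rejected), DE_only, DZI_only, non_influential — a deterministic
function of the two flags.

Calibration measured in the acceptance tests under the generator's
default conditions (600 cells, two groups): type-I error of both tests
within (0.03, 0.07) at nominal 0.05 over 1000 null genes, DE power > 0.9
at a three-fold change with 300 cells per group.

## Synthetic data

`simulate_dataset` draws gene truth `mu ~ log-uniform [0.5, 50]`,
`theta ~ log-uniform [0.5, 10]`, `pi ~ uniform [0.05, 0.6]` — spanning
weakly expressed, strongly dispersed and heavily inflated regimes — for
200 genes × 600 cells in two equal groups by default. 10% of genes are
DE with `|gamma_1| = log 3` and 10% DZI with `|beta_1| = 1.5` (random
signs). Per-cell capture rates default to Uniform(0.1, 0.9), the same
bracket as the library-size estimator's default range; library sizes
emerge from the simulation as column sums so the library-size estimator
can be exercised end-to-end. `simulate_spikeins` uses a 23-rung two-fold
concentration ladder (repeated cyclically for larger panels, as in
commercial spike-in mixes) with NB dispersion 0.05 — mildly
super-Poissonian technical noise, consistent with deduplicated counts;
`noise=0` yields the exact deterministic limit `R = p C` for degenerate
contract tests. `simulate_cell_populations` plants well-separated
populations differing in overall expression scale and in an upregulated
gene block per population.

What the generator does *not* emulate: batch effects, doublets, ambient
RNA, gene–gene correlation, cell-cycle structure, or capture rates that
vary by gene within a cell. Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to real-data violations of them.

## Known limitations

* The chi-square null for the DZI test is slightly conservative for
  genes whose zero-inflation parameter sits near the boundary (`pi_hat ~
  0`), a standard boundary effect of likelihood-ratio tests.
* The library-size capture estimator is a monotone heuristic; when true
  capture is uncorrelated with depth it mis-allocates offsets, biasing
  true-expression estimates (observed-scale inference is unaffected).
* Dispersion is a single value per gene with no shrinkage across genes;
  estimates for weakly expressed genes are noisy (≈ 15% median relative
  error at 500 cells, larger below).
* Problem sizes in the test suite (e.g. 1000 null genes for calibration,
  2000 replicate datasets for the moment checks, 20 clustering runs) are
  the package's chosen validation scales; estimates at other scales
  follow from standard Monte-Carlo error rates.
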