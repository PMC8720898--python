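"""EM estimation of the gene-wise ZINB-GLM."""

import numpy as np
import pytest

from zinbcap.capture import thin_counts
from zinbcap.distributions import nb_pmf, zinb_sample
from zinbcap.estimation import (
    DesignSpec,
    EMConfig,
    direct_mle_fallback,
    e_step_weights,
    em_fit_gene,
    fit_all_genes,
    make_design,
)


def intercept_design(I, **kw):
    return make_design(np.zeros(I, dtype=int), **kw)


class TestEStep:
    def test_positive_counts_have_unit_weight(self):
        w = e_step_weights(np.array([5, 1, 12]), pi=0.4, mu_prime=2.0, theta=1.0)
        np.testing.assert_allclose(w, 1.0)

    def test_zero_count_posterior_hand_computed(self):
        # f_NB(0) = 0.25 at theta=1, mu=3; w = 0.5*0.25 / (0.5 + 0.5*0.25) = 0.2
        mu = 3.0
        assert nb_pmf(0, mu, 1.0) == pytest.approx(0.25)
        w = e_step_weights(np.array([0]), pi=0.5, mu_prime=mu, theta=1.0)
        assert w[0] == pytest.approx(0.2)

    def test_no_inflation_gives_unit_weights(self):
        y = np.array([0, 0, 3, 7])
        np.testing.assert_allclose(e_step_weights(y, 0.0, 2.0, 1.0), 1.0)

    def test_pi_one_with_positive_count_warns(self):
        with pytest.warns(UserWarning, match="pi = 1"):
            w = e_step_weights(np.array([4]), pi=1.0, mu_prime=2.0, theta=1.0)
        assert w[0] == 1.0


class TestDesignSpec:
    def test_requires_intercept_column(self):
        with pytest.raises(ValueError, match="intercept"):
            DesignSpec(X=np.zeros((4, 2)))

    def test_requires_one_hot_clusters(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError, match="one-hot"):
            DesignSpec(X=X, R=np.full((4, 2), 0.5))

    def test_aliased_columns_dropped(self):
        # cluster membership identical to group membership: aliased
        groups = np.array([0, 0, 1, 1])
        design = make_design(groups, clusters=groups)
        M, names, gcols = design.matrix(include_group=True)
        assert np.linalg.matrix_rank(M) == M.shape[1]
        assert "group1" in names and "cluster1" not in names

    def test_group_columns_tracked(self):
        design = make_design(np.array([0, 1, 2, 0, 1, 2]))
        M, names, gcols = design.matrix(include_group=True)
        assert [names[j] for j in gcols] == ["group1", "group2"]
        M0, names0, g0 = design.matrix(include_group=False)
        assert g0 == [] and M0.shape[1] == 1


class TestEMFit:
    def test_parameter_recovery_intercept_only(self):
        y = zinb_sample(1000, 0.3, 5.0, 2.0, seed=5)
        fit = em_fit_gene(y, intercept_design(1000))
        params = fit.point_params()
        assert abs(params.pi - 0.3) < 0.05
        assert abs(params.mu - 5.0) / 5.0 < 0.10
        assert abs(params.theta - 2.0) / 2.0 < 0.25

    def test_loglik_nondecreasing(self):
        for seed in range(5):
            y = zinb_sample(400, 0.4, 2.0, 1.0, seed=seed)
            fit = em_fit_gene(y, intercept_design(400))
            assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_no_zeros_drives_pi_to_zero(self, rng):
        y = rng.poisson(20, size=300) + 1  # strictly positive
        fit = em_fit_gene(y, intercept_design(300))
        assert fit.point_params().pi < 1e-3

    def test_weights_are_one_for_positive_counts(self):
        y = zinb_sample(500, 0.3, 4.0, 2.0, seed=9)
        fit = em_fit_gene(y, intercept_design(500))
        np.testing.assert_allclose(fit.weights[y > 0], 1.0)
        assert np.all((fit.weights >= 0) & (fit.weights <= 1))

    def test_all_zero_gene_rejected(self):
        with pytest.raises(ValueError, match="non-zero"):
            em_fit_gene(np.zeros(100, dtype=int), intercept_design(100))

    def test_group_effect_recovered(self):
        rng = np.random.default_rng(12)
        I = 800
        groups = np.repeat([0, 1], I // 2)
        gamma1 = np.log(3.0)
        mu = np.where(groups == 0, 4.0, 4.0 * np.exp(gamma1))
        y = zinb_sample(I, 0.2, mu, 2.0, seed=13)
        fit = em_fit_gene(y, make_design(groups))
        est = fit.coef_mu[fit.group_cols_mu[0]]
        assert abs(est - gamma1) < 0.2

    def test_matches_statsmodels_weighted_nb_mstep(self):
        # independent oracle for the weighted NB M-step regression
        sm = pytest.importorskip("statsmodels.api")
        from zinbcap.estimation import _weighted_nb

        rng = np.random.default_rng(3)
        I = 400
        X = np.column_stack([np.ones(I), rng.integers(0, 2, I).astype(float)])
        off = rng.normal(0, 0.1, I)
        theta = 2.0
        mu_true = np.exp(X @ np.array([1.0, 0.7]) + off)
        y = rng.negative_binomial(theta, theta / (theta + mu_true))
        w = rng.uniform(0.3, 1.0, I)
        ours = _weighted_nb(y, X, off, w, theta, np.zeros(2), EMConfig())
        glm = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=1.0 / theta),
            offset=off, var_weights=w,
        ).fit()
        np.testing.assert_allclose(ours, glm.params, atol=1e-5)


class TestFallback:
    def test_agrees_with_em_at_optimum(self):
        y = zinb_sample(400, 0.3, 5.0, 2.0, seed=21)
        design = intercept_design(400)
        em = em_fit_gene(y, design, EMConfig(fallback=False))
        direct = direct_mle_fallback(y, design, init=em)
        assert direct.method == "direct"
        assert abs(direct.loglik - em.loglik) < 1e-3

    def test_degenerate_single_count_is_finite(self):
        y = np.zeros(120, dtype=int)
        y[0] = 1
        fit = direct_mle_fallback(y, intercept_design(120))
        assert np.isfinite(fit.loglik)
        assert np.all(np.isfinite(fit.coef_mu))

    def test_warm_start_reduces_iterations(self):
        y = zinb_sample(400, 0.4, 3.0, 1.0, seed=30)
        design = intercept_design(400)
        em = em_fit_gene(y, design, EMConfig(fallback=False))
        warm = direct_mle_fallback(y, design, init=em)
        cold = direct_mle_fallback(y, design, init=None)
        assert warm.n_iter < cold.n_iter


class TestFitAllGenes:
    def test_unit_capture_equals_unadjusted(self, small_dataset):
        Y = small_dataset.true_counts[:8]
        design = make_design(small_dataset.cell_meta.group.to_numpy())
        fits_a, _ = fit_all_genes(Y, design, capture=None)
        fits_b, _ = fit_all_genes(Y, design, capture=np.ones(Y.shape[1]))
        for a, b in zip(fits_a, fits_b):
            assert a.loglik == pytest.approx(b.loglik, abs=1e-9)
            np.testing.assert_allclose(a.coef_mu, b.coef_mu, atol=1e-9)

    def test_capture_offset_recovers_true_mean(self):
        # thin at p=0.25: with the log-p offset mu_hat estimates the true
        # mean (10); without it, the attenuated mean (2.5)
        I, p = 2000, 0.25
        Z = zinb_sample(I, 0.2, 10.0, 3.0, seed=40).reshape(1, -1)
        Y = thin_counts(Z, np.full(I, p), seed=41)
        design = intercept_design(I)
        with_off, _ = fit_all_genes(Y, design, capture=np.full(I, p))
        without, _ = fit_all_genes(Y, design, capture=None)
        assert abs(with_off[0].point_params().mu - 10.0) / 10.0 < 0.15
        assert abs(without[0].point_params().mu - 2.5) / 2.5 < 0.15

    def test_pi_estimate_invariant_to_capture(self):
        # zero inflation is untouched by thinning; refitting at two very
        # different capture rates recovers the same pi
        I = 3000
        Z = zinb_sample(I, 0.35, 12.0, 2.0, seed=50).reshape(1, -1)
        design = intercept_design(I)
        pis = []
        for seed, p in ((51, 0.9), (52, 0.35)):
            Y = thin_counts(Z, np.full(I, p), seed=seed)
            fits, _ = fit_all_genes(Y, design, capture=np.full(I, p))
            pis.append(fits[0].point_params().pi)
        assert abs(pis[0] - pis[1]) < 0.05
        assert abs(pis[0] - 0.35) < 0.05

    def test_convergence_rate_on_fixture(self, small_dataset):
        design = make_design(small_dataset.cell_meta.group.to_numpy())
        fits, status = fit_all_genes(
            small_dataset.observed, design,
            capture=small_dataset.cell_meta.p.to_numpy(),
        )
        assert status.converged.mean() >= 0.95
        assert list(status.gene_id) == small_dataset.gene_ids
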