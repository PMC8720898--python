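"""Binomial thinning, the capture theorem oracle, and capture estimators."""

import numpy as np
import pytest
from scipy import stats

from zinbcap.capture import (
    SpikeInSet,
    estimate_capture_librarysize,
    estimate_capture_spikeins,
    thin_counts,
    thinned_pmf_oracle,
)
from zinbcap.distributions import ZINBParams, observed_moments, zinb_pmf, zinb_sample


class TestThinning:
    def test_full_capture_is_identity(self, rng):
        Z = rng.integers(0, 50, size=(20, 30))
        np.testing.assert_array_equal(thin_counts(Z, 1.0, seed=0), Z)

    def test_zero_capture_gives_zeros(self, rng):
        Z = rng.integers(0, 50, size=(5, 8))
        assert np.all(thin_counts(Z, 0.0, seed=0) == 0)

    def test_never_exceeds_truth(self, rng):
        Z = rng.integers(0, 100, size=(10, 40))
        p = rng.uniform(0.1, 0.9, 40)
        Y = thin_counts(Z, p, seed=1)
        assert np.all(Y <= Z)

    def test_thinned_mean_matches_model(self):
        pi, mu, theta, p = 0.3, 8.0, 2.0, 0.25
        Z = zinb_sample(100_000, pi, mu, theta, seed=3).reshape(1, -1)
        Y = thin_counts(Z, np.full(Z.shape[1], p), seed=4)
        m = observed_moments(ZINBParams(pi, mu, theta), p)
        se = np.sqrt(m.variance / Z.shape[1])
        assert abs(Y.mean() - m.mean) < 4 * se

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            thin_counts(np.zeros((3, 4), dtype=int), np.full(5, 0.5))


class TestCaptureTheorem:
    """Marginalizing Binomial(y|z,p) over ZINB(z) gives ZINB(pi, mu*p, theta)."""

    def test_zero_count_worked_example(self):
        val = thinned_pmf_oracle(0, pi=0.3, mu=2, theta=1, p=0.5)
        assert val == pytest.approx(0.3 + 0.7 * 0.5, abs=1e-10)
        assert val == pytest.approx(float(zinb_pmf(0, 0.3, 1.0, 1)), abs=1e-10)

    def test_identity_thinning(self):
        for y in range(10):
            assert thinned_pmf_oracle(y, 0.2, 3, 1.5, p=1.0) == pytest.approx(
                float(zinb_pmf(y, 0.2, 3, 1.5)), abs=1e-12
            )

    @pytest.mark.parametrize("pi", [0.0, 0.3, 0.7])
    @pytest.mark.parametrize("mu", [0.5, 2.0, 10.0])
    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_closed_form_equivalence(self, pi, mu, p):
        theta = 1.0
        y = np.arange(25)
        closed = zinb_pmf(y, pi, mu * p, theta)
        oracle = np.array(
            [thinned_pmf_oracle(int(t), pi, mu, theta, p) for t in y]
        )
        assert np.max(np.abs(oracle - closed)) < 1e-10

    def test_refuses_insufficient_truncation(self):
        with pytest.raises(ValueError, match="tail mass"):
            thinned_pmf_oracle(0, pi=0.0, mu=50, theta=1, p=0.5, z_max=10)

    def test_thinned_samples_match_thinned_distribution(self):
        # two-sample GOF: thin(ZINB(mu)) vs ZINB(mu * p) should agree
        n = 50_000
        pi, mu, theta, p = 0.3, 8.0, 2.0, 0.4
        Z = zinb_sample(n, pi, mu, theta, seed=10).reshape(1, -1)
        a = thin_counts(Z, np.full(n, p), seed=11).ravel()
        b = zinb_sample(n, pi, mu * p, theta, seed=12)
        hi = int(max(a.max(), b.max()))
        ca = np.bincount(a, minlength=hi + 1)
        cb = np.bincount(b, minlength=hi + 1)
        # pool sparse tail cells for a valid chi-square comparison
        keep = (ca + cb) >= 10
        ca_p = np.append(ca[keep], ca[~keep].sum())
        cb_p = np.append(cb[keep], cb[~keep].sum())
        res = stats.chi2_contingency(np.vstack([ca_p, cb_p]))
        assert res.pvalue > 0.01

    def test_zero_probability_nonincreasing_in_capture(self):
        vals = [thinned_pmf_oracle(0, 0.3, 5, 2, p) for p in (0.1, 0.4, 0.8, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestSpikeInEstimator:
    def test_exact_proportionality(self):
        C = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        R = 0.5 * C[None, :].repeat(3, axis=0)
        est = estimate_capture_spikeins(SpikeInSet(C, R))
        np.testing.assert_allclose(est.p_hat, 0.5, atol=1e-12)
        np.testing.assert_allclose(est.intercept, 0.0, atol=1e-12)

    def test_identity_line(self):
        C = np.array([1.0, 2.0, 4.0])
        est = estimate_capture_spikeins(SpikeInSet(C, C[None, :]))
        assert est.p_hat[0] == pytest.approx(1.0)
        assert est.intercept[0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_ols_on_three_points(self):
        # C=(1,2,3), R=(1,1,2): slope = cov/var = 0.5
        C = np.array([1.0, 2.0, 3.0])
        R = np.array([[1.0, 1.0, 2.0]])
        est = estimate_capture_spikeins(SpikeInSet(C, R))
        assert est.p_hat[0] == pytest.approx(0.5)
        assert est.intercept[0] == pytest.approx(4.0 / 3 - 0.5 * 2.0)

    def test_slopes_clamped_with_raw_diagnostics(self):
        C = np.array([1.0, 2.0, 4.0])
        R = np.array([2.0 * C, -0.5 * C + 3.0])
        est = estimate_capture_spikeins(SpikeInSet(C, R))
        assert est.p_hat[0] == 1.0 and est.p_hat[1] == 0.0
        assert est.raw_slope[0] == pytest.approx(2.0)
        assert est.raw_slope[1] == pytest.approx(-0.5)

    def test_constant_concentrations_rejected(self):
        C = np.array([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            estimate_capture_spikeins(SpikeInSet(C, np.ones((2, 3))))

    def test_summaries_consistent(self):
        C = np.array([1.0, 2.0, 4.0, 8.0])
        R = np.vstack([0.2 * C, 0.6 * C, 0.9 * C])
        est = estimate_capture_spikeins(SpikeInSet(C, R))
        assert est.p2_bar >= est.p_bar**2 - 1e-12
        assert est.var_p == pytest.approx(est.p2_bar - est.p_bar**2, abs=1e-12)


class TestLibrarySizeEstimator:
    def test_worked_log_interpolation(self):
        est = estimate_capture_librarysize([10, 100, 1000], rho1=0.1, rho2=0.9)
        np.testing.assert_allclose(est.p_hat, [0.1, 0.5, 0.9], atol=1e-12)

    def test_extremes_hit_bounds(self, rng):
        S = rng.integers(100, 100_000, size=50)
        est = estimate_capture_librarysize(S, 0.2, 0.8)
        assert est.p_hat[np.argmin(S)] == pytest.approx(0.2)
        assert est.p_hat[np.argmax(S)] == pytest.approx(0.8)
        assert np.all((est.p_hat >= 0.2) & (est.p_hat <= 0.8))

    def test_equal_sizes_fall_back_to_midpoint(self):
        with pytest.warns(UserWarning, match="equal"):
            est = estimate_capture_librarysize([500, 500, 500], 0.1, 0.9)
        np.testing.assert_allclose(est.p_hat, 0.5)

    @pytest.mark.parametrize("rho", [(-0.1, 0.9), (0.5, 0.5), (0.2, 1.1)])
    def test_invalid_range_rejected(self, rho):
        with pytest.raises(ValueError):
            estimate_capture_librarysize([10, 100], *rho)
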