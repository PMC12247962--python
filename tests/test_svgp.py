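"""Sparse variational GP: kernel, conditional prior, marginal posterior, KL, ELBO."""

import numpy as np
import pytest

from cytogpnet.data import ParameterError
from cytogpnet.svgp import (
    InducingState,
    MarginalPosterior,
    SEKernel,
    conditional_prior,
    exact_gp_regression,
    fit_gaussian_svgp,
    gaussian_elbo,
    kernel_matrix,
    kl_term,
    marginal_variational_posterior,
    sample_f,
    stable_cholesky,
)

RNG = np.random.default_rng(42)


def test_kernel_values_and_psd():
    k = SEKernel(lengthscale=0.1, variance=1.0)
    a = RNG.normal(size=(1, 3))
    # identical points -> variance (= 1)
    assert kernel_matrix(a, a, k)[0, 0] == pytest.approx(1.0)
    # points at distance sigma -> exp(-1/2)
    b = a + np.array([[0.1, 0.0, 0.0]])
    assert kernel_matrix(a, b, k)[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-9)
    # Gram matrix of 20 random points is PSD
    P = RNG.normal(size=(20, 3))
    G = kernel_matrix(P, P, k)
    np.testing.assert_allclose(G, G.T)
    assert np.linalg.eigvalsh(G).min() >= -1e-8
    with pytest.raises(ParameterError):
        SEKernel(lengthscale=-1.0)


def test_conditional_prior_scalar_hand_case():
    # one point, one inducing point at distance sigma, u = 2:
    # mean = k * u / v = exp(-1/2) * 2, var = v - k^2 / v = 1 - exp(-1)
    k = SEKernel(lengthscale=0.5, variance=1.0)
    Z = np.array([[0.0]])
    H = np.array([[0.5]])
    state = InducingState(Z=Z, mu=np.zeros(1), L=np.eye(1))
    cp = conditional_prior(H, state, k)
    assert cp.mean(np.array([2.0]))[0] == pytest.approx(2 * np.exp(-0.5), rel=1e-5)
    assert cp.var()[0] == pytest.approx(1 - np.exp(-1.0), rel=1e-4)


def test_conditional_prior_interpolates_at_inducing_inputs():
    k = SEKernel(lengthscale=0.3)
    H = RNG.normal(size=(6, 2))
    state = InducingState(Z=H.copy(), mu=np.zeros(6), L=np.eye(6))
    cp = conditional_prior(H, state, k)
    # Z = H: conditional covariance collapses, mean is linear with A ~ I
    assert np.abs(cp.var()).max() < 1e-4
    np.testing.assert_allclose(cp.mean(np.zeros(6)), 0.0, atol=1e-12)


def test_marginal_posterior_matches_dense_gaussian_integration():
    """q(f) must equal the integral of p(f|u) q(u) du, done by generic
    joint-Gaussian conditioning + the laws of total expectation/covariance."""
    k = SEKernel(lengthscale=0.7, variance=1.0)
    for seed in range(3):
        rng = np.random.default_rng(seed)
        H = rng.normal(size=(5, 2))
        Z = rng.normal(size=(4, 2))
        A_ = rng.normal(size=(4, 4))
        Sigma = A_ @ A_.T + 0.5 * np.eye(4)
        mu = rng.normal(size=4)
        state = InducingState(Z=Z, mu=mu, L=np.linalg.cholesky(Sigma))

        post = marginal_variational_posterior(H, state, k, diag_only=False)

        # independent oracle: joint prior covariance + Schur conditioning.
        # Both routes see the same regularized prior (the documented jitter
        # 1e-6 on Kzz), so agreement is pure linear algebra.
        Khh = k.variance * np.exp(
            -((H[:, None] - H[None]) ** 2).sum(-1) / (2 * k.lengthscale**2)
        )
        Khz = k.variance * np.exp(
            -((H[:, None] - Z[None]) ** 2).sum(-1) / (2 * k.lengthscale**2)
        )
        Kzz = k.variance * np.exp(
            -((Z[:, None] - Z[None]) ** 2).sum(-1) / (2 * k.lengthscale**2)
        ) + 1e-6 * np.eye(len(Z))
        W = Khz @ np.linalg.inv(Kzz)  # E[f | u] = W u
        cond_cov = Khh - W @ Khz.T
        mean_oracle = W @ mu  # E[f] = E_u[W u]
        cov_oracle = cond_cov + W @ Sigma @ W.T  # total covariance

        np.testing.assert_allclose(post.mu_f, mean_oracle, atol=1e-8)
        np.testing.assert_allclose(post.Sigma_f, cov_oracle, atol=1e-8)


def test_marginal_posterior_prior_recovery():
    # q(u) = p(u) -> q(f) is the GP prior marginal: mu_f = 0, diag = v
    k = SEKernel(lengthscale=0.5, variance=1.0)
    H = RNG.normal(size=(10, 2))
    Z = RNG.normal(size=(50, 2))
    state = InducingState.at_prior(Z, k)
    post = marginal_variational_posterior(H, state, k)
    np.testing.assert_allclose(post.mu_f, 0.0, atol=1e-12)
    np.testing.assert_allclose(post.var_f, 1.0, atol=1e-3)


def test_marginal_posterior_interpolation_limit():
    # Sigma -> 0 with Z = H: mu_f -> mu exactly at the data
    k = SEKernel(lengthscale=0.4)
    H = RNG.normal(size=(5, 2))
    mu = RNG.normal(size=5)
    state = InducingState(Z=H.copy(), mu=mu, L=1e-7 * np.eye(5))
    post = marginal_variational_posterior(H, state, k)
    np.testing.assert_allclose(post.mu_f, mu, atol=1e-3)
    assert np.abs(post.var_f).max() < 1e-3


def test_sample_f_moments_and_degenerate_cases():
    mu_f = np.array([1.0, -2.0, 0.5])
    var = np.array([0.5, 2.0, 0.1])
    post = MarginalPosterior(mu_f=mu_f, var_f=var)
    s = sample_f(post, 10_000, seed=0)
    se_mean = np.sqrt(var / 10_000)
    assert (np.abs(s.mean(axis=0) - mu_f) < 3 * se_mean + 1e-9).all()
    se_var = var * np.sqrt(2 / 9_999)
    assert (np.abs(s.var(axis=0) - var) < 3 * se_var).all()
    # zero variance -> every sample equals the mean
    s0 = sample_f(MarginalPosterior(mu_f=mu_f, var_f=np.zeros(3)), 5, seed=1)
    np.testing.assert_allclose(s0, np.tile(mu_f, (5, 1)), atol=1e-12)
    # determinism
    np.testing.assert_array_equal(sample_f(post, 4, seed=7), sample_f(post, 4, seed=7))


def test_kl_zero_at_prior_nonnegative_and_hand_formula():
    k = SEKernel(lengthscale=0.6)
    Z = RNG.normal(size=(4, 2))
    assert kl_term(InducingState.at_prior(Z, k), k) <= 1e-8

    # O = 2 hand instance against the scalar Gaussian-KL formula
    Z2 = np.array([[0.0, 0.0], [1.0, 0.0]])
    K = kernel_matrix(Z2, Z2, SEKernel(lengthscale=1.0)) + 1e-6 * np.eye(2)
    mu = np.array([0.3, -0.7])
    L = np.array([[0.9, 0.0], [0.2, 1.1]])
    S = L @ L.T
    Kinv = np.linalg.inv(K)
    by_hand = 0.5 * (
        np.trace(Kinv @ S)
        + mu @ Kinv @ mu
        - 2
        + np.log(np.linalg.det(K) / np.linalg.det(S))
    )
    got = kl_term(InducingState(Z=Z2, mu=mu, L=L), SEKernel(lengthscale=1.0))
    assert got == pytest.approx(by_hand, abs=1e-6)
    assert got >= 0.0

    for seed in range(5):
        rng = np.random.default_rng(seed)
        Lr = np.tril(rng.normal(size=(4, 4)))
        np.fill_diagonal(Lr, np.abs(np.diag(Lr)) + 0.1)
        st = InducingState(Z=Z, mu=rng.normal(size=4), L=Lr)
        assert kl_term(st, k) >= 0.0


def test_gaussian_elbo_bounded_by_and_tight_at_exact_evidence():
    """With Z = X the optimized bound equals the exact log evidence, and any
    other variational state stays below it."""
    rng = np.random.default_rng(3)
    X = rng.uniform(-2, 2, size=(20, 1))
    k = SEKernel(lengthscale=0.8, variance=1.0)
    noise = 0.1
    f_true = np.sin(2 * X[:, 0])
    y = f_true + 0.2 * rng.standard_normal(20)

    _, log_ev = exact_gp_regression(X, y, X, k, noise)

    # arbitrary states never exceed the evidence
    for seed in range(3):
        r2 = np.random.default_rng(seed)
        Lr = np.tril(r2.normal(size=(20, 20))) * 0.1
        np.fill_diagonal(Lr, np.abs(np.diag(Lr)) + 0.5)
        st = InducingState(Z=X.copy(), mu=r2.normal(size=20), L=Lr)
        assert gaussian_elbo(X, y, st, k, noise) <= log_ev + 1e-6

    st_opt = fit_gaussian_svgp(X, y, X.copy(), k, noise)
    elbo_opt = gaussian_elbo(X, y, st_opt, k, noise)
    assert elbo_opt <= log_ev + 1e-6
    assert abs(elbo_opt - log_ev) < 1e-3

    # and the variational predictive mean matches exact GP regression
    mean_exact, _ = exact_gp_regression(X, y, X, k, noise)
    post = marginal_variational_posterior(X, st_opt, k)
    rms = np.sqrt(np.mean((post.mu_f - mean_exact) ** 2))
    assert rms < 1e-3


def test_stable_cholesky_jitter_policy():
    # rank-deficient matrix succeeds with escalated jitter
    A = np.ones((4, 4))
    L, jit = stable_cholesky(A, 1.0)
    np.testing.assert_allclose(L @ L.T, A + jit * np.eye(4), atol=1e-8)
    assert jit >= 1e-6
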