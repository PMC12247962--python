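"""Sparse variational Gaussian process over cell embeddings.

A zero-mean GP prior with squared-exponential kernel maps each cell's
q-dimensional latent embedding h to a scalar f(h).  Exact inference costs
O(M^3) in the total cell count M, so the posterior is summarized by O
inducing points Z with a Gaussian variational posterior q(u) = N(mu, Sigma)
over the function values u at Z.  With the factorized joint posterior
q(f, u) = q(u) p(f | u), the marginal over f at inputs H is Gaussian with

    mu_f    = K_HZ Kzz^-1 mu
    Sigma_f = K_HH - K_HZ Kzz^-1 (Kzz - Sigma) Kzz^-1 K_ZH

and the evidence lower bound is  E_q(f)[log p(y | f)] - KL[q(u) || p(u)],
with the likelihood term estimated by Monte Carlo through the
reparameterization f = mu_f + L_f eps.  Only Kzz (O x O) is ever inverted.

Sigma is stored through its lower-triangular Cholesky factor with positive
diagonal, so it is positive definite by construction.  All solves share one
jitter policy: start at 1e-6 * variance and escalate tenfold up to 1e-2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from ._autodiff import Tensor, tensor
from .data import ParameterError

JITTER0_FACTOR = 1e-6
JITTER_MAX_FACTOR = 1e-2
VAR_FLOOR = 1e-8


class NumericalError(RuntimeError):
    """Factorization failed even at maximum jitter."""


@dataclass
class SEKernel:
    """Squared-exponential kernel k(a, b) = v * exp(-||a - b||^2 / (2 s^2))."""

    lengthscale: float = 0.1
    variance: float = 1.0

    def __post_init__(self):
        if self.lengthscale <= 0 or self.variance <= 0:
            raise ParameterError("lengthscale and variance must be positive")


def _sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    aa = (A * A).sum(axis=1)[:, None]
    bb = (B * B).sum(axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * (A @ B.T), 0.0)


def kernel_matrix(A: np.ndarray, B: np.ndarray, kernel: SEKernel) -> np.ndarray:
    """Gram matrix between two point sets in the latent space."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ParameterError(f"latent dims differ: {A.shape[1]} vs {B.shape[1]}")
    return kernel.variance * np.exp(-_sqdist(A, B) / (2.0 * kernel.lengthscale**2))


def stable_cholesky(K: np.ndarray, variance: float = 1.0) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of K + jitter*I under the escalating-jitter policy."""
    jitter = JITTER0_FACTOR * variance
    while jitter <= JITTER_MAX_FACTOR * variance * (1 + 1e-12):
        try:
            return np.linalg.cholesky(K + jitter * np.eye(K.shape[0])), jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
    cond = np.linalg.cond(K)
    raise NumericalError(
        f"Cholesky failed up to jitter {JITTER_MAX_FACTOR * variance:g} "
        f"(condition estimate {cond:.3g})"
    )


@dataclass
class InducingState:
    """Inducing inputs Z with variational posterior q(u) = N(mu, L L^T)."""

    Z: np.ndarray
    mu: np.ndarray
    L: np.ndarray  # lower-triangular, positive diagonal

    def __post_init__(self):
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=np.float64))
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.L = np.asarray(self.L, dtype=np.float64)
        O = self.Z.shape[0]
        if self.mu.shape != (O,) or self.L.shape != (O, O):
            raise ParameterError("mu must be (O,), L must be (O, O)")
        if np.any(np.diag(self.L) <= 0):
            raise ParameterError("L must have a positive diagonal")

    @property
    def n_inducing(self) -> int:
        return self.Z.shape[0]

    @property
    def Sigma(self) -> np.ndarray:
        return self.L @ self.L.T

    @classmethod
    def at_prior(cls, Z: np.ndarray, kernel: SEKernel) -> "InducingState":
        """Initialize q(u) = p(u): mu = 0, Sigma = Kzz (KL term starts at 0)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        L, _ = stable_cholesky(kernel_matrix(Z, Z, kernel), kernel.variance)
        return cls(Z=Z, mu=np.zeros(Z.shape[0]), L=L)


@dataclass
class ConditionalPrior:
    """p(f | u) = N(A u, K_HH - A Kzz A^T) with A = K_HZ Kzz^-1."""

    A: np.ndarray
    cov: np.ndarray
    jitter: float

    def mean(self, u: np.ndarray) -> np.ndarray:
        return self.A @ np.asarray(u, dtype=np.float64)

    def var(self) -> np.ndarray:
        return np.maximum(np.diag(self.cov), 0.0)


def conditional_prior(H: np.ndarray, state: InducingState, kernel: SEKernel) -> ConditionalPrior:
    """Conditional prior of GP values at H given the inducing values u."""
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    Kzz = kernel_matrix(state.Z, state.Z, kernel)
    Khz = kernel_matrix(H, state.Z, kernel)
    Khh = kernel_matrix(H, H, kernel)
    Lz, jit = stable_cholesky(Kzz, kernel.variance)
    A = sla.cho_solve((Lz, True), Khz.T).T  # K_HZ Kzz^-1
    cov = Khh - A @ Khz.T
    return ConditionalPrior(A=A, cov=cov, jitter=jit)


@dataclass
class MarginalPosterior:
    """Marginal variational posterior q(f) = N(mu_f, Sigma_f) at the inputs."""

    mu_f: np.ndarray
    var_f: np.ndarray  # diagonal of Sigma_f, floored at VAR_FLOOR
    Sigma_f: np.ndarray | None = None  # full matrix when diag_only=False
    _Lf: np.ndarray | None = field(default=None, repr=False)

    @property
    def Lf(self) -> np.ndarray:
        """Factor with Lf Lf^T = Sigma_f (diagonal sqrt in diag-only mode)."""
        if self._Lf is None:
            if self.Sigma_f is not None:
                L, _ = stable_cholesky(self.Sigma_f, max(self.var_f.max(), VAR_FLOOR))
                self._Lf = L
            else:
                self._Lf = np.diag(np.sqrt(self.var_f))
        return self._Lf


def marginal_variational_posterior(
    H: np.ndarray, state: InducingState, kernel: SEKernel, diag_only: bool = True
) -> MarginalPosterior:
    """q(f) = integral p(f | u) q(u) du, computed in closed form.

    ``diag_only=True`` keeps only the per-cell variances and never forms an
    M x M matrix, which is the mode used during training.
    """
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    Kzz = kernel_matrix(state.Z, state.Z, kernel)
    Khz = kernel_matrix(H, state.Z, kernel)
    Lz, _ = stable_cholesky(Kzz, kernel.variance)
    A = sla.cho_solve((Lz, True), Khz.T).T
    mu_f = A @ state.mu
    AL = A @ state.L
    if diag_only:
        var = kernel.variance - (A * Khz).sum(axis=1) + (AL * AL).sum(axis=1)
        return MarginalPosterior(mu_f=mu_f, var_f=np.maximum(var, VAR_FLOOR))
    Khh = kernel_matrix(H, H, kernel)
    Sigma_f = Khh - A @ Khz.T + AL @ AL.T
    var = np.maximum(np.diag(Sigma_f), VAR_FLOOR)
    return MarginalPosterior(mu_f=mu_f, var_f=var, Sigma_f=Sigma_f)


def sample_f(post: MarginalPosterior, B: int, seed=None) -> np.ndarray:
    """B reparameterized draws f = mu_f + L_f eps, eps ~ N(0, I); (B x M)."""
    if B < 1:
        raise ParameterError("B must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    M = post.mu_f.shape[0]
    eps = rng.standard_normal((B, M))
    if post.Sigma_f is None:
        return post.mu_f[None, :] + np.sqrt(post.var_f)[None, :] * eps
    return post.mu_f[None, :] + eps @ post.Lf.T


def kl_term(state: InducingState, kernel: SEKernel) -> float:
    """KL[q(u) || p(u)] with p(u) = N(0, Kzz); closed-form Gaussian KL, >= 0."""
    Kzz = kernel_matrix(state.Z, state.Z, kernel)
    Lz, jit = stable_cholesky(Kzz, kernel.variance)
    O = state.n_inducing
    Kinv_Sigma_tr = np.sum(sla.cho_solve((Lz, True), state.L) * state.L)
    alpha = sla.solve_triangular(Lz, state.mu, lower=True)
    logdet_K = 2.0 * np.sum(np.log(np.diag(Lz)))
    logdet_S = 2.0 * np.sum(np.log(np.diag(state.L)))
    kl = 0.5 * (Kinv_Sigma_tr + alpha @ alpha - O + logdet_K - logdet_S)
    return float(max(kl, 0.0))


# ---------------------------------------------------------------------------
# Gaussian-likelihood regression utilities (used to validate the bound)
# ---------------------------------------------------------------------------

def gaussian_elbo(
    H: np.ndarray, y: np.ndarray, state: InducingState, kernel: SEKernel, noise_var: float
) -> float:
    """Exact (no Monte Carlo) ELBO under a Gaussian likelihood N(y | f, s^2).

    E_q(f)[log N(y_i | f_i, s^2)] has closed form
    log N(y_i | mu_f_i, s^2) - var_f_i / (2 s^2).
    """
    post = marginal_variational_posterior(H, state, kernel)
    n = y.shape[0]
    ll = (
        -0.5 * n * np.log(2 * np.pi * noise_var)
        - 0.5 * np.sum((y - post.mu_f) ** 2) / noise_var
        - 0.5 * np.sum(post.var_f) / noise_var
    )
    return float(ll - kl_term(state, kernel))


def exact_gp_regression(
    X: np.ndarray, y: np.ndarray, Xstar: np.ndarray, kernel: SEKernel, noise_var: float
) -> tuple[np.ndarray, float]:
    """Reference exact GP regression: predictive mean at Xstar and log evidence."""
    K = kernel_matrix(X, X, kernel) + noise_var * np.eye(len(y))
    L = np.linalg.cholesky(K)
    alpha = sla.cho_solve((L, True), y)
    mean = kernel_matrix(Xstar, X, kernel) @ alpha
    log_ev = (
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * len(y) * np.log(2 * np.pi)
    )
    return mean, float(log_ev)


def fit_gaussian_svgp(
    X: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray,
    kernel: SEKernel,
    noise_var: float,
    max_iter: int = 3000,
) -> InducingState:
    """Optimize q(u) for the Gaussian-likelihood ELBO by L-BFGS.

    Only the variational parameters (mu and the Sigma factor) move; Z and
    the kernel stay fixed.  With Z = X the optimized bound is tight, so this
    doubles as a correctness check against exact GP regression.
    """
    from scipy.optimize import minimize

    X = np.atleast_2d(X)
    Z = np.atleast_2d(Z)
    O = Z.shape[0]
    state0 = InducingState.at_prior(Z, kernel)
    tril = np.tril_indices(O)
    H_t = tensor(X)
    y_t = tensor(np.asarray(y, dtype=np.float64))
    Kzz_np = kernel_matrix(Z, Z, kernel)
    _, jit = stable_cholesky(Kzz_np, kernel.variance)
    log_ls = tensor(np.log(kernel.lengthscale))
    Z_t = tensor(Z)

    # unconstrained packing: mu, strict-lower of L, log-diag of L
    def unpack(theta):
        mu = tensor(theta[:O], requires_grad=True)
        Lu = np.zeros((O, O))
        Lu[tril] = theta[O:]
        L_raw = tensor(Lu, requires_grad=True)
        return mu, L_raw

    strict_mask = tensor(np.tril(np.ones((O, O)), -1))
    eye = tensor(np.eye(O))

    def neg_elbo(theta):
        mu, L_raw = unpack(theta)
        L = L_raw * strict_mask + (L_raw.diag_part().exp()).diag_embed()
        mu_f, var_f = _marginal_diag_t(H_t, Z_t, mu, L, log_ls, kernel.variance, jit)
        n = y_t.data.shape[0]
        ll = (
            -0.5 * n * np.log(2 * np.pi * noise_var)
            - ((y_t - mu_f) ** 2).sum() * (0.5 / noise_var)
            - var_f.sum() * (0.5 / noise_var)
        )
        kl = _kl_t(mu, L, Z_t, log_ls, kernel.variance, jit, eye)
        loss = kl - ll
        loss.backward()
        grad = np.concatenate([mu.grad, L_raw.grad[tril]])
        return float(loss.data), grad

    # pack initial L: strict-lower entries raw, diagonal in log
    Lpack = state0.L[tril].copy()
    diag_pos = tril[0] == tril[1]
    Lpack[diag_pos] = np.log(np.diag(state0.L))
    theta0 = np.concatenate([state0.mu, Lpack])

    res = minimize(neg_elbo, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10})
    mu = res.x[:O]
    Lu = np.zeros((O, O))
    Lu[tril] = res.x[O:]
    L = np.tril(Lu, -1) + np.diag(np.exp(np.diag(Lu)))
    return InducingState(Z=Z, mu=mu, L=L)


# ---------------------------------------------------------------------------
# Differentiable (Tensor) counterparts used during end-to-end training
# ---------------------------------------------------------------------------

def _kernel_t(A: Tensor, B: Tensor, log_ls: Tensor, variance: float) -> Tensor:
    aa = (A * A).sum(axis=1, keepdims=True)
    bb = (B * B).sum(axis=1, keepdims=True)
    d2 = aa + bb.T - 2.0 * (A @ B.T)
    d2 = d2.relu()  # numerical floor at 0
    ls2 = (log_ls * 2.0).exp()
    return ((d2 * (-0.5)) / ls2).exp() * variance


def _marginal_diag_t(
    H: Tensor, Z: Tensor, mu: Tensor, L: Tensor, log_ls: Tensor, variance: float, jitter: float
) -> tuple[Tensor, Tensor]:
    """Differentiable (mu_f, var_f) of q(f); never forms an M x M matrix."""
    O = Z.data.shape[0]
    Kzz = _kernel_t(Z, Z, log_ls, variance) + tensor(jitter * np.eye(O))
    Khz = _kernel_t(H, Z, log_ls, variance)
    A = Khz @ Kzz.inv()
    mu_f = A @ mu
    AL = A @ L
    var = (A * Khz).sum(axis=1) * (-1.0) + (AL * AL).sum(axis=1) + variance
    var = (var - VAR_FLOOR).relu() + VAR_FLOOR
    return mu_f, var


def _kl_t(
    mu: Tensor, L: Tensor, Z: Tensor, log_ls: Tensor, variance: float, jitter: float, eye: Tensor
) -> Tensor:
    O = Z.data.shape[0]
    Kzz = _kernel_t(Z, Z, log_ls, variance) + eye * jitter
    Kinv = Kzz.inv()
    trace = (Kinv * (L @ L.T)).sum()
    quad = mu @ Kinv @ mu
    logdet_K = Kzz.logdet()
    logdet_S = L.diag_part().log().sum() * 2.0
    return (trace + quad + logdet_K - logdet_S - float(O)) * 0.5


def init_inducing_points(
    H: np.ndarray, n_inducing: int, seed: int, max_cells: int = 10_000
) -> np.ndarray:
    """k-means centroids of a random cell subsample of the embeddings.

    Falls back to a random subset when there are fewer distinct cells than
    requested centroids.
    """
    rng = np.random.default_rng(seed)
    H = np.atleast_2d(H)
    if H.shape[0] > max_cells:
        H = H[rng.choice(H.shape[0], size=max_cells, replace=False)]
    if H.shape[0] <= n_inducing:
        reps = int(np.ceil(n_inducing / H.shape[0]))
        out = np.tile(H, (reps, 1))[:n_inducing]
        return out + 1e-4 * rng.standard_normal(out.shape)
    from sklearn.cluster import KMeans

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=n_inducing, n_init=3, random_state=int(seed) % (2**31))
        km.fit(H)
    return km.cluster_centers_.astype(np.float64)
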