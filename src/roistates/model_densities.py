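"""Likelihoods and prior densities of the hierarchical latent-state model.

The joint model factorizes into two conditionally independent sub-models
given the latent state labels eta:

* a measurement model — a K-component Gaussian mixture over the R-vector of
  ROI intensities with diagonal covariances, where regions flagged as
  discriminatory (gamma_j = 1) have state-specific means mu_{k,j} and shared
  variance sigma_k, and non-discriminatory regions have mean 0 and variance
  sigma_0;
* an outcome model — logistic regression of the binary outcome on the state
  indicators (state K is the reference) and baseline covariates.

All densities are evaluated in log space. The spike-and-slab prior on mu
uses intrinsic CAR (ICAR) full conditionals; the joint evaluation here uses
their pseudo-likelihood product, which is exactly what the sampler's
Metropolis ratios require (the intrinsic prior has no proper joint
normalization). Isolated regions (degree 0) fall back to a N(0, c_k) slab.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, log_expit

from .data_model import Hyperparameters, ROIDataset
from .network_prior import ConnectivityNetwork, ising_log_prior

__all__ = [
    "ModelState",
    "design_row",
    "design_matrix",
    "measurement_loglik",
    "outcome_loglik",
    "pg_identity_check",
    "icar_conditional",
    "joint_log_posterior",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ModelState:
    """One complete MCMC state of the model.

    ``eta`` holds labels in {1, ..., K}; ``mu`` is K x R with mu[k, j] = 0
    wherever gamma[j] = 0; ``beta`` has length K + q laid out as
    (beta_0, beta_1, ..., beta_{K-1}, beta_U); ``omega`` holds the per-subject
    Polya-Gamma auxiliaries.
    """

    eta: np.ndarray
    pi: np.ndarray
    gamma: np.ndarray
    mu: np.ndarray
    sigma_k: np.ndarray
    sigma_0: float
    beta: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "eta", np.asarray(self.eta, dtype=int))
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=float))
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=int))
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma_k", np.asarray(self.sigma_k, dtype=float))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "omega", np.asarray(self.omega, dtype=float))

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def R(self) -> int:
        return self.gamma.shape[0]

    def validate(self) -> None:
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")
        if np.any((self.eta < 1) | (self.eta > self.K)):
            raise ValueError("eta labels must lie in 1..K")
        if np.any(self.mu[:, self.gamma == 0] != 0):
            raise ValueError("mu must be zero wherever gamma is zero")
        if np.any(self.sigma_k <= 0) or self.sigma_0 <= 0:
            raise ValueError("variances must be positive")
        if self.omega.size and np.any(self.omega <= 0):
            raise ValueError("omega must be positive")

    def n_k(self) -> np.ndarray:
        """Cluster occupancy counts (n_1, ..., n_K)."""
        return np.bincount(self.eta - 1, minlength=self.K)

    def region_variances(self) -> np.ndarray:
        """K x R matrix of per-region variances implied by gamma."""
        var = np.where(self.gamma == 1, self.sigma_k[:, None], self.sigma_0)
        return var

    def copy(self, **changes) -> "ModelState":
        base = {
            "eta": self.eta.copy(), "pi": self.pi.copy(), "gamma": self.gamma.copy(),
            "mu": self.mu.copy(), "sigma_k": self.sigma_k.copy(), "sigma_0": self.sigma_0,
            "beta": self.beta.copy(), "omega": self.omega.copy(),
        }
        base.update(changes)
        return ModelState(**base)


def design_row(eta_i: int, U_i: np.ndarray, K: int) -> np.ndarray:
    """xi_i = (1, I(eta_i = 1), ..., I(eta_i = K-1), U_i); state K is reference."""
    if not 1 <= eta_i <= K:
        raise ValueError(f"eta_i must lie in 1..{K}, got {eta_i}")
    rho = np.zeros(K - 1)
    if eta_i < K:
        rho[eta_i - 1] = 1.0
    return np.concatenate(([1.0], rho, np.asarray(U_i, dtype=float).ravel()))


def design_matrix(eta: np.ndarray, U: np.ndarray, K: int) -> np.ndarray:
    """Stack design rows for all subjects: n x (K + q)."""
    eta = np.asarray(eta, dtype=int)
    n = eta.shape[0]
    Xi = np.zeros((n, K + U.shape[1]))
    Xi[:, 0] = 1.0
    for k in range(1, K):
        Xi[:, k] = (eta == k).astype(float)
    Xi[:, K:] = U
    return Xi


def _gauss_logpdf(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (_LOG2PI + np.log(var) + (x - mean) ** 2 / var)


def measurement_loglik(X: np.ndarray, state: ModelState) -> float:
    """Gaussian mixture measurement log-likelihood given the allocations.

    sum_k sum_{i: eta_i = k} log N(X_i; mu_k, Sigma_k) with Sigma_k diagonal,
    variance sigma_k on selected regions and sigma_0 elsewhere.
    """
    if np.any(state.sigma_k <= 0) or state.sigma_0 <= 0:
        raise ValueError("variances must be positive")
    X = np.asarray(X, dtype=float)
    var = state.region_variances()
    total = 0.0
    for k in range(1, state.K + 1):
        members = state.eta == k
        if not members.any():
            continue
        total += _gauss_logpdf(X[members], state.mu[k - 1], var[k - 1]).sum()
    return float(total)


def outcome_loglik(Y: np.ndarray, eta: np.ndarray, U: np.ndarray, beta: np.ndarray) -> float:
    """Logistic-regression log-likelihood, overflow-safe.

    sum_i [ y_i psi_i - log(1 + exp(psi_i)) ] with psi_i = xi_i' beta.
    """
    K = beta.shape[0] - U.shape[1]
    Xi = design_matrix(np.asarray(eta, dtype=int), U, K)
    psi = Xi @ beta
    Y = np.asarray(Y, dtype=float)
    # y*psi + log(sigmoid(-psi)) = y*psi - log(1+exp(psi))
    return float(np.sum(Y * psi + log_expit(-psi)))


def pg_identity_check(psi: float, y: int, n_mc: int, rng: np.random.Generator) -> tuple[float, float]:
    """Monte-Carlo check of the Polya-Gamma likelihood identity.

    lhs = exp(psi)^y / (1 + exp(psi)); rhs = (1/2) exp(kappa psi) *
    E_{omega ~ PG(1,0)}[exp(-omega psi^2 / 2)] with kappa = y - 1/2.
    Intended for tests; the sampler never calls this.
    """
    from .polya_gamma import sample_pg

    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    lhs = float(np.exp(y * psi - np.logaddexp(0.0, psi)))
    omegas = np.array([sample_pg(1.0, 0.0, rng) for _ in range(n_mc)])
    rhs = float(0.5 * np.exp((y - 0.5) * psi) * np.mean(np.exp(-omegas * psi**2 / 2.0)))
    return lhs, rhs


def icar_conditional(
    j: int,
    k: int,
    mu_k: np.ndarray,
    network: ConnectivityNetwork,
    c_k: float,
) -> tuple[float, float]:
    """ICAR slab full conditional of mu_{k,j} given the other means.

    mean = (sum of neighbor means) / d_j, variance = c_k / d_j. An isolated
    region (d_j = 0) falls back to N(0, c_k).
    """
    d_j = int(network.degrees[j])
    if d_j == 0:
        return 0.0, float(c_k)
    nbr_sum = float(network.S[j] @ mu_k)
    return nbr_sum / d_j, float(c_k) / d_j


def _log_invgamma(x: float, a: float, b: float) -> float:
    return a * np.log(b) - gammaln(a) - (a + 1) * np.log(x) - b / x


def _mu_log_pseudo_prior(state: ModelState, network: ConnectivityNetwork, c_k: float) -> float:
    """Pseudo-likelihood product of the ICAR slab full conditionals.

    Only selected regions contribute; each factor is the Gaussian full
    conditional with neighbor sums taken over the full graph (non-selected
    neighbors contribute mu = 0).
    """
    sel = np.flatnonzero(state.gamma == 1)
    if sel.size == 0:
        return 0.0
    total = 0.0
    deg = network.degrees
    for k in range(state.K):
        mu_k = state.mu[k]
        for j in sel:
            d = deg[j]
            if d == 0:
                mean, var = 0.0, c_k
            else:
                mean, var = float(network.S[j] @ mu_k) / d, c_k / d
            total += _gauss_logpdf(np.array(mu_k[j]), mean, var)
    return float(total)


def joint_log_posterior(
    state: ModelState,
    data: ROIDataset,
    hyper: Hyperparameters,
    network: ConnectivityNetwork,
) -> float:
    """Unnormalized log joint of parameters and data (Ising constant omitted).

    Sum of: measurement and outcome log-likelihoods, Dirichlet log prior on
    pi, the allocation mass sum_i log pi_{eta_i}, the spike-and-slab/ICAR
    pseudo-prior on mu given gamma, inverse-gamma priors on sigma_k and
    sigma_0, the Gaussian prior on beta, and the Ising prior on gamma. The
    Polya-Gamma auxiliaries are not part of this (collapsed) joint.
    """
    state.validate()
    n_k = state.n_k()
    ll = measurement_loglik(data.X, state)
    ll += outcome_loglik(data.Y, state.eta, data.U, state.beta)
    alpha = hyper.alpha
    ll += float(np.sum((alpha - 1) * np.log(state.pi)) + gammaln(alpha.sum()) - gammaln(alpha).sum())
    ll += float(n_k @ np.log(state.pi))
    ll += _mu_log_pseudo_prior(state, network, hyper.c_k)
    ll += sum(_log_invgamma(s, hyper.a_k, hyper.b_k) for s in state.sigma_k)
    ll += _log_invgamma(state.sigma_0, hyper.a_0, hyper.b_0)
    m_beta, V_beta = hyper.beta_prior(data.q)
    dev = state.beta - m_beta
    sign, logdet = np.linalg.slogdet(V_beta)
    ll += float(-0.5 * (len(dev) * _LOG2PI + logdet + dev @ np.linalg.solve(V_beta, dev)))
    ll += ising_log_prior(state.gamma, network.S, hyper.e, hyper.f)
    return float(ll)
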