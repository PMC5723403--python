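"""MCMC engine: Gibbs blocks plus add-delete-swap Metropolis selection moves.

One sweep updates, in order: the Polya-Gamma auxiliaries omega, the logistic
coefficients beta, the latent states eta (using the exact logistic outcome
term, i.e. a partially collapsed step with omega refreshed at the start of
the next sweep), the mixture weights pi, the selection indicators gamma
(R Metropolis proposals with full-conditional mu proposals), the selected
cluster means mu (single-site Gibbs in randomized region order), and the
variances sigma_k / sigma_0.

Every Metropolis log-ratio is the difference of the collapsed joint log
posterior of the two states (plus the proposal correction); this is verified
against :func:`roistates.model_densities.joint_log_posterior` when the
chain is run with ``check_moves=True``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import log_expit, logsumexp

from .data_model import Hyperparameters, McmcSettings, ROIDataset
from .model_densities import ModelState, design_matrix, joint_log_posterior
from .network_prior import ConnectivityNetwork
from .polya_gamma import sample_pg_vector

__all__ = [
    "PosteriorDraws",
    "sample_polya_gamma",
    "update_omega",
    "update_beta",
    "update_eta",
    "update_pi",
    "update_mu",
    "update_sigma",
    "update_gamma",
    "run_chain",
    "run_chains",
    "save_draws",
    "load_draws",
]

_LOG2PI = np.log(2.0 * np.pi)


def sample_polya_gamma(b: float, c: float, rng: np.random.Generator) -> float:
    """Exact PG(b, c) draw (positive integer b); see :mod:`roistates.polya_gamma`."""
    from .polya_gamma import sample_pg

    return sample_pg(b, c, rng)


# ---------------------------------------------------------------------------
# Gibbs blocks. Each takes and returns a ModelState (inputs never mutated).
# ---------------------------------------------------------------------------

def _linear_predictor(state: ModelState, data: ROIDataset) -> np.ndarray:
    Xi = design_matrix(state.eta, data.U, state.K)
    return Xi @ state.beta


def update_omega(state: ModelState, data: ROIDataset, rng: np.random.Generator,
                 observed: np.ndarray | None = None) -> ModelState:
    """omega_i ~ PG(1, xi_i' beta) independently across subjects."""
    psi = _linear_predictor(state, data)
    omega = sample_pg_vector(psi, rng)
    if observed is not None:
        omega = np.where(observed, omega, state.omega)
    return state.copy(omega=omega)


def update_beta(state: ModelState, data: ROIDataset, hyper: Hyperparameters,
                rng: np.random.Generator, observed: np.ndarray | None = None) -> ModelState:
    """Conjugate Gaussian draw of beta given the Polya-Gamma auxiliaries.

    V* = (Xi' Omega Xi + V_beta^{-1})^{-1},
    m* = V* (Xi' kappa + V_beta^{-1} m_beta), kappa_i = y_i - 1/2.
    """
    m0, V0 = hyper.beta_prior(data.q)
    Xi = design_matrix(state.eta, data.U, state.K)
    kappa = data.Y - 0.5
    omega = state.omega
    if observed is not None:
        Xi = Xi[observed]
        kappa = kappa[observed]
        omega = omega[observed]
    V0_inv = np.linalg.inv(V0)
    prec = Xi.T @ (omega[:, None] * Xi) + V0_inv
    try:
        L = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError as err:
        raise ValueError("posterior precision of beta is not positive definite") from err
    mean = np.linalg.solve(prec, Xi.T @ kappa + V0_inv @ m0)
    z = rng.standard_normal(len(mean))
    beta = mean + np.linalg.solve(L.T, z)
    return state.copy(beta=beta)


def _state_loglik_matrix(state: ModelState, data: ROIDataset,
                         observed: np.ndarray | None = None) -> np.ndarray:
    """(n, K) matrix of log[pi_k f(x_i|k) p(y_i|k, beta)] up to constants."""
    X = data.X
    n = X.shape[0]
    K = state.K
    var = state.region_variances()
    L = np.empty((n, K))
    for k in range(K):
        resid = X - state.mu[k]
        L[:, k] = -0.5 * np.sum(_LOG2PI + np.log(var[k]) + resid**2 / var[k], axis=1)
    L += np.log(state.pi)
    # exact logistic outcome term per hypothetical state
    base = state.beta[0] + data.U @ state.beta[K:]
    for k in range(K):
        psi = base + (state.beta[1 + k] if k < K - 1 else 0.0)
        contrib = data.Y * psi + log_expit(-psi)
        if observed is not None:
            contrib = np.where(observed, contrib, 0.0)
        L[:, k] += contrib
    return L


def update_eta(state: ModelState, data: ROIDataset, hyper: Hyperparameters,
               rng: np.random.Generator, observed: np.ndarray | None = None) -> ModelState:
    """Categorical draw of each latent state from its collapsed conditional."""
    L = _state_loglik_matrix(state, data, observed)
    norm = logsumexp(L, axis=1, keepdims=True)
    if not np.all(np.isfinite(norm)):
        raise ValueError("all state masses vanished for at least one subject")
    P = np.exp(L - norm)
    u = rng.random(len(P))
    eta = 1 + (u[:, None] > np.cumsum(P, axis=1)).sum(axis=1)
    eta = np.minimum(eta, state.K)
    return state.copy(eta=eta)


def update_pi(state: ModelState, hyper: Hyperparameters, rng: np.random.Generator) -> ModelState:
    """pi ~ Dirichlet(alpha + occupancy counts)."""
    return state.copy(pi=rng.dirichlet(hyper.alpha + state.n_k()))


def _mu_full_conditional(
    k: int, j: int, mu: np.ndarray, n_k: np.ndarray, col_sums: np.ndarray,
    sigma_k: np.ndarray, network: ConnectivityNetwork, c_k: float,
) -> tuple[float, float]:
    """Mean and variance of mu_{k,j} | rest for a selected region.

    Precision n_k/sigma_k + d_j/c_k with the ICAR neighbor-mean prior pull;
    isolated regions use the N(0, c_k) slab fallback (precision ... + 1/c_k).
    """
    d = int(network.degrees[j])
    if d == 0:
        prior_prec = 1.0 / c_k
        prior_pull = 0.0
    else:
        prior_prec = d / c_k
        prior_pull = float(network.S[j] @ mu[k]) / c_k  # (d/c)*(nbr_mean) = nbr_sum/c
    prec = n_k[k] / sigma_k[k] + prior_prec
    v = 1.0 / prec
    m = v * (col_sums[k, j] / sigma_k[k] + prior_pull)
    return m, v


def update_mu(state: ModelState, data: ROIDataset, hyper: Hyperparameters,
              network: ConnectivityNetwork, rng: np.random.Generator) -> ModelState:
    """Single-site Gibbs refresh of mu on the selected regions, random order."""
    mu = state.mu.copy()
    n_k = state.n_k()
    col_sums = _cluster_col_sums(state.eta, data.X, state.K)
    selected = np.flatnonzero(state.gamma == 1)
    for k in range(state.K):
        for j in rng.permutation(selected):
            m, v = _mu_full_conditional(k, j, mu, n_k, col_sums, state.sigma_k,
                                        network, hyper.c_k)
            mu[k, j] = m + np.sqrt(v) * rng.standard_normal()
    return state.copy(mu=mu)


def update_sigma(state: ModelState, data: ROIDataset, hyper: Hyperparameters,
                 rng: np.random.Generator) -> ModelState:
    """Conjugate inverse-gamma draws of sigma_k (selected) and sigma_0 (rest)."""
    sel = state.gamma == 1
    n_sel = int(sel.sum())
    n_k = state.n_k()
    sigma_k = np.empty(state.K)
    for k in range(state.K):
        members = state.eta == k + 1
        ss = float(((data.X[members][:, sel] - state.mu[k, sel]) ** 2).sum()) if n_sel else 0.0
        shape = hyper.a_k + n_k[k] * n_sel / 2.0
        scale = hyper.b_k + 0.5 * ss
        sigma_k[k] = scale / rng.gamma(shape)
    ss0 = float((data.X[:, ~sel] ** 2).sum())
    shape0 = hyper.a_0 + data.n * (data.R - n_sel) / 2.0
    scale0 = hyper.b_0 + 0.5 * ss0
    sigma_0 = scale0 / rng.gamma(shape0)
    return state.copy(sigma_k=sigma_k, sigma_0=float(sigma_0))


# ---------------------------------------------------------------------------
# Add-delete-swap Metropolis moves on (gamma, mu)
# ---------------------------------------------------------------------------

def _cluster_col_sums(eta: np.ndarray, X: np.ndarray, K: int) -> np.ndarray:
    sums = np.zeros((K, X.shape[1]))
    for k in range(K):
        sums[k] = X[eta == k + 1].sum(axis=0)
    return sums


def _cluster_col_ssq(eta: np.ndarray, X: np.ndarray, K: int) -> np.ndarray:
    ssq = np.zeros((K, X.shape[1]))
    X2 = X**2
    for k in range(K):
        ssq[k] = X2[eta == k + 1].sum(axis=0)
    return ssq


def _feasible_moves(n_sel: int, R: int) -> list[str]:
    moves = []
    if n_sel < R:
        moves.append("add")
    if n_sel > 0:
        moves.append("delete")
    if 0 < n_sel < R:
        moves.append("swap")
    return moves


def _gauss_logpdf_scalar(x: float, m: float, v: float) -> float:
    return -0.5 * (_LOG2PI + np.log(v) + (x - m) ** 2 / v)


class _GammaMoveContext:
    """Scratch state for one sweep of selection moves.

    Holds mutable copies of (gamma, mu) plus the per-cluster column
    sufficient statistics, so each add/delete/swap evaluates its posterior
    log-ratio in O(K + selected neighbors) instead of a full joint recompute.
    """

    def __init__(self, state: ModelState, data: ROIDataset, hyper: Hyperparameters,
                 network: ConnectivityNetwork):
        self.gamma = state.gamma.copy()
        self.mu = state.mu.copy()
        self.eta = state.eta
        self.sigma_k = state.sigma_k
        self.sigma_0 = state.sigma_0
        self.K = state.K
        self.R = state.R
        self.n = data.n
        self.n_k = state.n_k()
        self.col_sums = _cluster_col_sums(state.eta, data.X, state.K)
        self.col_ssq = _cluster_col_ssq(state.eta, data.X, state.K)
        self.tot_ssq = (data.X**2).sum(axis=0)
        self.network = network
        self.hyper = hyper
        self.deg = [int(d) for d in network.degrees]
        self.neighbors = [list(map(int, np.flatnonzero(network.S[j]))) for j in range(self.R)]
        c = hyper.c_k
        # degree-dependent slab-conditional variances, fixed for the sweep
        self.prior_var = [c / d if d > 0 else c for d in self.deg]
        self.prior_log_var = [math.log(v) for v in self.prior_var]
        # full-conditional variances of mu_{k,j}: likelihood precision n_k/sigma_k
        # plus prior precision d_j/c (or 1/c for isolated regions)
        lik_prec = self.n_k / self.sigma_k
        self.fc_var = np.empty((self.R, self.K))
        for j in range(self.R):
            self.fc_var[j] = 1.0 / (lik_prec + 1.0 / self.prior_var[j])
        self.fc_logvar = np.log(self.fc_var)
        self.fc_sd = np.sqrt(self.fc_var)
        self.cs_term = self.col_sums / self.sigma_k[:, None]  # (K, R)
        self.log_sig_k = [math.log(s) for s in self.sigma_k]
        self.log_sig_0 = math.log(self.sigma_0)

    # -- local log-density pieces (scalar math: K and degrees are tiny) ----

    def _col_loglik_unselected(self, j: int) -> float:
        return -0.5 * (self.n * (_LOG2PI + self.log_sig_0) + self.tot_ssq[j] / self.sigma_0)

    def _col_loglik_selected(self, j: int, mu_col: np.ndarray) -> float:
        total = 0.0
        for k in range(self.K):
            m = mu_col[k]
            ss = self.col_ssq[k, j] - 2.0 * m * self.col_sums[k, j] + self.n_k[k] * m * m
            total += self.n_k[k] * (_LOG2PI + self.log_sig_k[k]) + ss / self.sigma_k[k]
        return -0.5 * total

    def _nbr_mean(self, k: int, r: int) -> float:
        d = self.deg[r]
        if d == 0:
            return 0.0
        mu_k = self.mu[k]
        return sum(mu_k[jp] for jp in self.neighbors[r]) / d

    def _pseudo_prior_local(self, j: int) -> float:
        """Pseudo-prior factors involving region j: its own (if selected) plus
        those of its selected neighbors."""
        gamma = self.gamma
        regions = [j] if gamma[j] else []
        regions += [jp for jp in self.neighbors[j] if gamma[jp]]
        total = 0.0
        for r in regions:
            var = self.prior_var[r]
            acc = 0.0
            for k in range(self.K):
                dev = self.mu[k, r] - self._nbr_mean(k, r)
                acc += dev * dev
            total += self.K * (_LOG2PI + self.prior_log_var[r]) + acc / var
        return -0.5 * total

    def _proposal_logdensity(self, j: int, mu_col: np.ndarray) -> float:
        """Density of drawing mu_col from the full conditionals at the current
        scratch state (own value excluded by construction)."""
        c = self.hyper.c_k
        total = 0.0
        for k in range(self.K):
            pull = 0.0 if self.deg[j] == 0 else self._nbr_mean(k, j) * self.deg[j] / c
            v = self.fc_var[j, k]
            m = v * (self.cs_term[k, j] + pull)
            dev = mu_col[k] - m
            total += _LOG2PI + self.fc_logvar[j, k] + dev * dev / v
        return -0.5 * total

    def _draw_proposal(self, j: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
        c = self.hyper.c_k
        mu_col = np.empty(self.K)
        logq = 0.0
        z = rng.standard_normal(self.K)
        for k in range(self.K):
            pull = 0.0 if self.deg[j] == 0 else self._nbr_mean(k, j) * self.deg[j] / c
            v = self.fc_var[j, k]
            m = v * (self.cs_term[k, j] + pull)
            mu_col[k] = m + self.fc_sd[j, k] * z[k]
            logq += _LOG2PI + self.fc_logvar[j, k] + z[k] * z[k]
        return mu_col, -0.5 * logq

    # -- atomic add / delete, applied in place, returning the joint delta --

    def _apply_add(self, j: int, mu_col: np.ndarray) -> float:
        before = self._col_loglik_unselected(j) + self._pseudo_prior_local(j)
        ising = self.hyper.e + 2.0 * self.hyper.f * float(self.network.S[j] @ self.gamma)
        self.gamma[j] = 1
        self.mu[:, j] = mu_col
        after = self._col_loglik_selected(j, mu_col) + self._pseudo_prior_local(j)
        return after - before + ising

    def _apply_delete(self, j: int) -> float:
        before = self._col_loglik_selected(j, self.mu[:, j]) + self._pseudo_prior_local(j)
        self.gamma[j] = 0
        self.mu[:, j] = 0.0
        ising = self.hyper.e + 2.0 * self.hyper.f * float(self.network.S[j] @ self.gamma)
        after = self._col_loglik_unselected(j) + self._pseudo_prior_local(j)
        return after - before - ising


def update_gamma(
    state: ModelState,
    data: ROIDataset,
    hyper: Hyperparameters,
    network: ConnectivityNetwork,
    rng: np.random.Generator,
    n_moves: int = 1,
    check_moves: bool = False,
    accept_counter: dict | None = None,
) -> ModelState:
    """Metropolis-Hastings add/delete/swap moves on the selection indicators.

    Each move picks a type uniformly among those feasible, proposes new mu
    components from their full conditionals (add/swap) or annihilates them
    (delete/swap), and accepts with probability
    exp(delta joint log posterior + proposal and selection corrections).
    ``check_moves`` recomputes each delta from the full joint (slow; tests).
    """
    ctx = _GammaMoveContext(state, data, hyper, network)
    R = ctx.R

    def selection_logprob(n_sel: int, move: str, j_count: int) -> float:
        return -np.log(len(_feasible_moves(n_sel, R))) - np.log(j_count)

    for _ in range(n_moves):
        n_sel = int(ctx.gamma.sum())
        moves = _feasible_moves(n_sel, R)
        move = moves[rng.integers(len(moves))]
        gamma_before = ctx.gamma.copy()
        mu_before = ctx.mu.copy()
        if move == "add":
            candidates = np.flatnonzero(ctx.gamma == 0)
            j = int(candidates[rng.integers(len(candidates))])
            mu_col, logq = ctx._draw_proposal(j, rng)
            delta = ctx._apply_add(j, mu_col)
            log_fwd = selection_logprob(n_sel, "add", R - n_sel) + logq
            log_rev = selection_logprob(n_sel + 1, "delete", n_sel + 1)
            log_ratio = delta + log_rev - log_fwd
        elif move == "delete":
            sel = np.flatnonzero(ctx.gamma == 1)
            j = int(sel[rng.integers(len(sel))])
            mu_old = ctx.mu[:, j].copy()
            delta = ctx._apply_delete(j)
            logq_rev = ctx._proposal_logdensity(j, mu_old)
            log_fwd = selection_logprob(n_sel, "delete", n_sel)
            log_rev = selection_logprob(n_sel - 1, "add", R - n_sel + 1) + logq_rev
            log_ratio = delta + log_rev - log_fwd
        else:  # swap
            sel = np.flatnonzero(ctx.gamma == 1)
            unsel = np.flatnonzero(ctx.gamma == 0)
            j_del = int(sel[rng.integers(len(sel))])
            j_add = int(unsel[rng.integers(len(unsel))])
            mu_old = ctx.mu[:, j_del].copy()
            delta = ctx._apply_delete(j_del)
            logq_rev = ctx._proposal_logdensity(j_del, mu_old)
            mu_col, logq_fwd = ctx._draw_proposal(j_add, rng)
            delta += ctx._apply_add(j_add, mu_col)
            # move-type and index selection probabilities are symmetric
            log_ratio = delta + logq_rev - logq_fwd

        if check_moves:
            s_before = state.copy(gamma=gamma_before, mu=mu_before)
            s_after = state.copy(gamma=ctx.gamma.copy(), mu=ctx.mu.copy())
            full_delta = joint_log_posterior(s_after, data, hyper, network) - \
                joint_log_posterior(s_before, data, hyper, network)
            if not np.isclose(full_delta, delta, atol=1e-8):
                raise AssertionError(
                    f"{move} move delta {delta:.10f} != joint difference {full_delta:.10f}"
                )

        accepted = np.log(rng.random()) < log_ratio
        if not accepted:
            ctx.gamma = gamma_before
            ctx.mu = mu_before
        if accept_counter is not None:
            accept_counter.setdefault(move, [0, 0])
            accept_counter[move][1] += 1
            accept_counter[move][0] += int(accepted)
    return state.copy(gamma=ctx.gamma, mu=ctx.mu)


# ---------------------------------------------------------------------------
# Chain driver
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned snapshots of one chain, stored columnwise."""

    eta: np.ndarray        # (T, n)
    pi: np.ndarray         # (T, K)
    gamma: np.ndarray      # (T, R)
    mu: np.ndarray         # (T, K, R)
    sigma_k: np.ndarray    # (T, K)
    sigma_0: np.ndarray    # (T,)
    beta: np.ndarray       # (T, K + q)
    settings: McmcSettings
    acceptance_rates: dict
    chain_id: int = 0

    @property
    def T(self) -> int:
        return self.eta.shape[0]

    @property
    def K(self) -> int:
        return self.pi.shape[1]

    def state(self, t: int, omega: np.ndarray | None = None) -> ModelState:
        n = self.eta.shape[1]
        return ModelState(
            eta=self.eta[t], pi=self.pi[t], gamma=self.gamma[t], mu=self.mu[t],
            sigma_k=self.sigma_k[t], sigma_0=float(self.sigma_0[t]), beta=self.beta[t],
            omega=np.ones(n) if omega is None else omega,
        )

    def to_dataframe(self) -> pd.DataFrame:
        T, K = self.T, self.K
        n = self.eta.shape[1]
        R = self.gamma.shape[1]
        cols: dict[str, np.ndarray] = {"chain_id": np.full(T, self.chain_id),
                                       "sweep": np.arange(T)}
        for i in range(n):
            cols[f"eta_{i}"] = self.eta[:, i]
        for k in range(K):
            cols[f"pi_{k}"] = self.pi[:, k]
        for j in range(R):
            cols[f"gamma_{j}"] = self.gamma[:, j]
        for k in range(K):
            for j in range(R):
                cols[f"mu_{k}_{j}"] = self.mu[:, k, j]
        for k in range(K):
            cols[f"sigma_{k + 1}"] = self.sigma_k[:, k]
        cols["sigma_0"] = self.sigma_0
        for p in range(self.beta.shape[1]):
            cols[f"beta_{p}"] = self.beta[:, p]
        return pd.DataFrame(cols)


def _initial_state(data: ROIDataset, hyper: Hyperparameters, settings: McmcSettings,
                   chain_id: int, rng: np.random.Generator) -> ModelState:
    K, R, n = hyper.K, data.R, data.n
    gamma = np.zeros(R, dtype=int)
    count = settings.init_gamma_count
    if count is None:
        count = min(R, 2 + 4 * chain_id)  # chains start from different |gamma|
    if count > 0:
        gamma[rng.choice(R, size=min(count, R), replace=False)] = 1
    if settings.init_allocation == "kmeans":
        from scipy.cluster.vq import kmeans2

        _, labels = kmeans2(data.X, K, seed=int(rng.integers(2**31)), minit="++")
        eta = labels + 1
    else:
        eta = rng.integers(1, K + 1, size=n)
    # make sure every label occurs at least once so chains start distinctly
    for k in range(1, K + 1):
        if not np.any(eta == k):
            eta[rng.integers(n)] = k
    return ModelState(
        eta=eta, pi=np.full(K, 1.0 / K), gamma=gamma, mu=np.zeros((K, R)),
        sigma_k=np.ones(K), sigma_0=1.0, beta=np.zeros(K + data.q), omega=np.ones(n),
    )


def run_chain(
    data: ROIDataset,
    hyper: Hyperparameters,
    network: ConnectivityNetwork,
    settings: McmcSettings,
    chain_id: int = 0,
    outcome_observed: np.ndarray | None = None,
    check_moves: bool = False,
    progress_every: int = 0,
) -> PosteriorDraws:
    """Run one MCMC chain and return the stored posterior draws.

    ``outcome_observed`` masks subjects whose outcome is held out (their
    measurement rows still inform the mixture; used by cross-validation).
    Deterministic given ``settings.seed`` and ``chain_id``.
    """
    rng = np.random.default_rng([settings.seed, chain_id])
    state = _initial_state(data, hyper, settings, chain_id, rng)
    T = settings.n_kept
    n, R, K, q = data.n, data.R, hyper.K, data.q
    draws = PosteriorDraws(
        eta=np.empty((T, n), dtype=np.int16), pi=np.empty((T, K)),
        gamma=np.empty((T, R), dtype=np.int8), mu=np.empty((T, K, R)),
        sigma_k=np.empty((T, K)), sigma_0=np.empty(T), beta=np.empty((T, K + q)),
        settings=settings, acceptance_rates={}, chain_id=chain_id,
    )
    counter: dict[str, list[int]] = {}
    kept = 0
    for sweep in range(settings.n_iter):
        try:
            state = update_omega(state, data, rng, observed=outcome_observed)
            state = update_beta(state, data, hyper, rng, observed=outcome_observed)
            state = update_eta(state, data, hyper, rng, observed=outcome_observed)
            state = update_pi(state, hyper, rng)
            state = update_gamma(state, data, hyper, network, rng, n_moves=R,
                                 check_moves=check_moves, accept_counter=counter)
            state = update_mu(state, data, hyper, network, rng)
            state = update_sigma(state, data, hyper, rng)
        except Exception as err:
            raise RuntimeError(f"chain {chain_id} failed at sweep {sweep}: {err}") from err
        if sweep >= settings.burn_in and (sweep - settings.burn_in) % settings.thin == 0 \
                and kept < T:
            draws.eta[kept] = state.eta
            draws.pi[kept] = state.pi
            draws.gamma[kept] = state.gamma
            draws.mu[kept] = state.mu
            draws.sigma_k[kept] = state.sigma_k
            draws.sigma_0[kept] = state.sigma_0
            draws.beta[kept] = state.beta
            kept += 1
        if progress_every and (sweep + 1) % progress_every == 0:
            print(f"[chain {chain_id}] sweep {sweep + 1}/{settings.n_iter} "
                  f"|gamma|={int(state.gamma.sum())}")
    draws.acceptance_rates = {
        m: (c[0] / c[1] if c[1] else float("nan")) for m, c in counter.items()
    }
    return draws


def run_chains(
    data: ROIDataset,
    hyper: Hyperparameters,
    network: ConnectivityNetwork,
    settings: McmcSettings,
    outcome_observed: np.ndarray | None = None,
    progress_every: int = 0,
) -> list[PosteriorDraws]:
    """Run ``settings.n_chains`` chains with distinct initializations."""
    return [
        run_chain(data, hyper, network, settings, chain_id=c,
                  outcome_observed=outcome_observed, progress_every=progress_every)
        for c in range(settings.n_chains)
    ]


def save_draws(draws_list: Sequence[PosteriorDraws], out_dir: str | Path) -> None:
    """Serialize chains as one CSV table per chain plus a JSON settings sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = []
    for d in draws_list:
        d.to_dataframe().to_csv(out / f"draws_chain{d.chain_id}.csv", index=False)
        s = d.settings
        meta.append({
            "chain_id": d.chain_id, "n_iter": s.n_iter, "burn_in": s.burn_in,
            "thin": s.thin, "seed": s.seed, "acceptance_rates": d.acceptance_rates,
            "shape": {"n": d.eta.shape[1], "K": d.K, "R": d.gamma.shape[1],
                      "p": d.beta.shape[1]},
        })
    (out / "draws_meta.json").write_text(json.dumps(meta, indent=2))


def load_draws(out_dir: str | Path) -> list[PosteriorDraws]:
    """Reload chains written by :func:`save_draws`."""
    out = Path(out_dir)
    meta = json.loads((out / "draws_meta.json").read_text())
    result = []
    for m in meta:
        df = pd.read_csv(out / f"draws_chain{m['chain_id']}.csv")
        n, K, R, p = m["shape"]["n"], m["shape"]["K"], m["shape"]["R"], m["shape"]["p"]
        T = len(df)
        settings = McmcSettings(n_iter=m["n_iter"], burn_in=m["burn_in"],
                                thin=m["thin"], seed=m["seed"], n_chains=len(meta))
        result.append(PosteriorDraws(
            eta=df[[f"eta_{i}" for i in range(n)]].to_numpy(),
            pi=df[[f"pi_{k}" for k in range(K)]].to_numpy(),
            gamma=df[[f"gamma_{j}" for j in range(R)]].to_numpy(),
            mu=df[[f"mu_{k}_{j}" for k in range(K) for j in range(R)]]
                .to_numpy().reshape(T, K, R),
            sigma_k=df[[f"sigma_{k + 1}" for k in range(K)]].to_numpy(),
            sigma_0=df["sigma_0"].to_numpy(),
            beta=df[[f"beta_{j}" for j in range(p)]].to_numpy(),
            settings=settings, acceptance_rates=m["acceptance_rates"],
            chain_id=m["chain_id"],
        ))
    return result
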