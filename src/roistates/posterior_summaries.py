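"""Posterior inference outputs: PPIs, relabeling, diagnostics, DIC and PBF.

Mixture labels are not identified during sampling; :func:`relabel_draws`
permutes each draw's labels to best match a reference partition before any
label-dependent summary (allocation probabilities, beta, per-state means).
Selection summaries (PPIs, median model) are label-invariant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_expit, logsumexp

from .data_model import Hyperparameters, ROIDataset
from .sampler import PosteriorDraws

__all__ = [
    "PosteriorSummary",
    "relabel_draws",
    "compute_ppi",
    "median_model",
    "allocation_probabilities",
    "beta_summary",
    "geweke_z",
    "gelman_rubin",
    "chain_agreement",
    "observed_data_loglik",
    "dic",
    "posterior_bayes_factor",
    "summarize",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class PosteriorSummary:
    ppi: np.ndarray
    selected_regions: list[str]
    allocation: np.ndarray          # n x K posterior state probabilities
    modal_state: np.ndarray         # length-n modal labels in 1..K
    beta_mean: np.ndarray
    beta_ci: np.ndarray             # (p, 2) equal-tailed interval bounds
    prob_or_gt1: np.ndarray         # P(exp(beta_j) > 1 | data) = P(beta_j > 0)
    diagnostics: pd.DataFrame
    dic: float
    region_labels: list[str]


# ---------------------------------------------------------------------------
# Relabeling
# ---------------------------------------------------------------------------

def _permute_beta(beta: np.ndarray, perm: tuple[int, ...], K: int) -> np.ndarray:
    """Re-express beta after relabeling states by ``perm`` (new = perm[old]).

    The state effects alpha_k (alpha_K = 0 for the reference) are permuted,
    then re-anchored so the new reference state K has zero effect.
    """
    q = beta.shape[0] - K
    alpha = np.zeros(K)
    alpha[: K - 1] = beta[1:K]
    new_alpha = np.empty(K)
    for old in range(K):
        new_alpha[perm[old]] = alpha[old]
    out = beta.copy()
    out[0] = beta[0] + new_alpha[K - 1]
    out[1:K] = new_alpha[: K - 1] - new_alpha[K - 1]
    return out


def relabel_draws(
    draws_list: list[PosteriorDraws],
    reference: np.ndarray | None = None,
) -> list[PosteriorDraws]:
    """Permute component labels draw-by-draw to match a reference partition.

    The reference defaults to the per-subject modal state of chain 1's raw
    draws. Per draw, the permutation maximizing the number of subjects whose
    label maps onto the reference is applied to (eta, pi, mu, sigma_k) and
    beta is re-expressed against the new reference state.
    """
    if not draws_list:
        return draws_list
    K = draws_list[0].K
    if reference is None:
        ref_alloc = np.stack([
            (draws_list[0].eta == k + 1).mean(axis=0) for k in range(K)
        ], axis=1)
        reference = 1 + ref_alloc.argmax(axis=1)
    reference = np.asarray(reference, dtype=int)
    perms = list(itertools.permutations(range(K)))
    out = []
    for d in draws_list:
        eta = d.eta.copy()
        pi = d.pi.copy()
        mu = d.mu.copy()
        sigma_k = d.sigma_k.copy()
        beta = d.beta.copy()
        for t in range(d.T):
            # contingency[old, new] = #subjects with draw label old+1, ref new+1
            cont = np.zeros((K, K))
            for k_old in range(K):
                mask = d.eta[t] == k_old + 1
                for k_new in range(K):
                    cont[k_old, k_new] = np.sum(mask & (reference == k_new + 1))
            best = max(perms, key=lambda p: sum(cont[o, p[o]] for o in range(K)))
            if best == tuple(range(K)):
                continue
            remap = np.array(best)
            eta[t] = 1 + remap[d.eta[t] - 1]
            pi[t, remap] = d.pi[t]
            mu[t, remap] = d.mu[t]
            sigma_k[t, remap] = d.sigma_k[t]
            beta[t] = _permute_beta(d.beta[t], best, K)
        out.append(PosteriorDraws(
            eta=eta, pi=pi, gamma=d.gamma, mu=mu, sigma_k=sigma_k,
            sigma_0=d.sigma_0, beta=beta, settings=d.settings,
            acceptance_rates=d.acceptance_rates, chain_id=d.chain_id,
        ))
    return out


# ---------------------------------------------------------------------------
# Point summaries
# ---------------------------------------------------------------------------

def _concat(draws: PosteriorDraws | list[PosteriorDraws]) -> list[PosteriorDraws]:
    return draws if isinstance(draws, list) else [draws]


def compute_ppi(draws: PosteriorDraws | list[PosteriorDraws]) -> np.ndarray:
    """Marginal posterior probability of inclusion per region."""
    gam = np.concatenate([d.gamma for d in _concat(draws)], axis=0)
    return gam.mean(axis=0)


def median_model(ppi: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Indices of regions with PPI above the median-model threshold."""
    return np.flatnonzero(np.asarray(ppi) > threshold)


def allocation_probabilities(draws: PosteriorDraws | list[PosteriorDraws]) -> np.ndarray:
    """n x K posterior allocation probabilities (relabel first)."""
    ds = _concat(draws)
    K = ds[0].K
    eta = np.concatenate([d.eta for d in ds], axis=0)
    return np.stack([(eta == k + 1).mean(axis=0) for k in range(K)], axis=1)


def beta_summary(draws: PosteriorDraws | list[PosteriorDraws], level: float = 0.95
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior means, equal-tailed credible intervals and P(beta_j > 0)."""
    beta = np.concatenate([d.beta for d in _concat(draws)], axis=0)
    if beta.shape[0] < 2:
        raise ValueError("need at least 2 draws")
    lo = (1.0 - level) / 2.0
    ci = np.quantile(beta, [lo, 1.0 - lo], axis=0).T
    return beta.mean(axis=0), ci, (beta > 0).mean(axis=0)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def _spectral_var0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via Bartlett-windowed autocovariance."""
    x = np.asarray(x, dtype=float)
    m = len(x)
    x = x - x.mean()
    if np.allclose(x, 0):
        return 0.0
    lag_max = min(m - 1, int(np.floor(10.0 * np.log10(m))))
    acov = np.array([np.dot(x[: m - lag], x[lag:]) / m for lag in range(lag_max + 1)])
    weights = 1.0 - np.arange(1, lag_max + 1) / (lag_max + 1)
    return float(acov[0] + 2.0 * np.sum(weights * acov[1:]))


def geweke_z(chain: np.ndarray, frac_a: float = 0.1, frac_b: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    z = (mean of first frac_a - mean of last frac_b) / sqrt(sum of the
    segments' spectral-density-at-zero variance estimates). A constant chain
    returns 0 by convention.
    """
    chain = np.asarray(chain, dtype=float)
    m = len(chain)
    if m < 100:
        raise ValueError("chain must have length >= 100")
    a = chain[: int(frac_a * m)]
    b = chain[int((1.0 - frac_b) * m):]
    var = _spectral_var0(a) / len(a) + _spectral_var0(b) / len(b)
    if var == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(var))


def gelman_rubin(chains: list[np.ndarray]) -> float:
    """Classic potential scale reduction factor from >= 2 scalar chains."""
    if len(chains) < 2:
        raise ValueError("need at least 2 chains")
    arr = np.asarray(chains, dtype=float)
    m, n = arr.shape
    if n < 100:
        raise ValueError("chains must have length >= 100")
    W = arr.var(axis=1, ddof=1).mean()
    B = n * arr.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0
    v_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(v_hat / W))


def chain_agreement(ppi_per_chain: list[np.ndarray],
                    alloc_per_chain: list[np.ndarray]) -> pd.DataFrame:
    """Pearson correlations of PPIs and state-1 allocation between chain pairs."""
    rows = []
    m = len(ppi_per_chain)
    for a in range(m):
        for b in range(a + 1, m):
            def _corr(x, y):
                if np.std(x) == 0 or np.std(y) == 0:
                    return float("nan")
                return float(np.corrcoef(x, y)[0, 1])
            rows.append({
                "chain_a": a, "chain_b": b,
                "ppi_corr": _corr(ppi_per_chain[a], ppi_per_chain[b]),
                "alloc_corr": _corr(alloc_per_chain[a][:, 0], alloc_per_chain[b][:, 0]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model fit scores
# ---------------------------------------------------------------------------

def observed_data_loglik(
    data: ROIDataset, pi: np.ndarray, mu: np.ndarray, sigma_k: np.ndarray,
    sigma_0: float, gamma: np.ndarray, beta: np.ndarray,
) -> np.ndarray:
    """Per-subject log L_i with the latent state marginalized out.

    L_i = sum_k pi_k N(x_i; mu_k, Sigma_k) p(y_i | eta_i = k, beta).
    """
    K = pi.shape[0]
    var = np.where(gamma == 1, np.asarray(sigma_k)[:, None], sigma_0)
    comp = np.empty((data.n, K))
    base = beta[0] + data.U @ beta[K:]
    for k in range(K):
        resid = data.X - mu[k]
        comp[:, k] = -0.5 * np.sum(_LOG2PI + np.log(var[k]) + resid**2 / var[k], axis=1)
        psi = base + (beta[1 + k] if k < K - 1 else 0.0)
        comp[:, k] += data.Y * psi + log_expit(-psi)
    return logsumexp(comp + np.log(pi), axis=1)


def _per_draw_loglik(draws_list: list[PosteriorDraws], data: ROIDataset) -> np.ndarray:
    lls = []
    for d in draws_list:
        for t in range(d.T):
            lls.append(observed_data_loglik(
                data, d.pi[t], d.mu[t], d.sigma_k[t], float(d.sigma_0[t]),
                d.gamma[t], d.beta[t]).sum())
    return np.asarray(lls)


def dic(draws: PosteriorDraws | list[PosteriorDraws], data: ROIDataset,
        hyper: Hyperparameters) -> float:
    """Deviance information criterion on the state-marginalized deviance.

    DIC = mean posterior deviance + p_eff, with the effective parameter
    count estimated as half the posterior variance of the deviance. The
    plug-in form (deviance at the posterior mean) is deliberately avoided:
    for mixtures with more components than the data support, residual label
    ambiguity blurs the posterior-mean parameters, inflates the plug-in
    deviance, and thereby *lowers* DIC for overfitted models; the
    variance-based penalty is label-invariant and grows with the extra
    wandering components, as an effective parameter count should.
    """
    ds = _concat(draws)
    lls = _per_draw_loglik(ds, data)
    dev = -2.0 * lls
    return float(dev.mean() + 0.5 * dev.var())


def posterior_bayes_factor(
    draws_a: PosteriorDraws | list[PosteriorDraws], data: ROIDataset,
    draws_b: PosteriorDraws | list[PosteriorDraws],
) -> float:
    """Ratio of posterior-averaged likelihoods of two fitted models.

    Computed stably as exp(logmeanexp(ll_a) - logmeanexp(ll_b)) with per-draw
    observed-data log-likelihoods; > 1 favors model A.
    """
    ll_a = _per_draw_loglik(_concat(draws_a), data)
    ll_b = _per_draw_loglik(_concat(draws_b), data)
    lme_a = logsumexp(ll_a) - np.log(len(ll_a))
    lme_b = logsumexp(ll_b) - np.log(len(ll_b))
    return float(np.exp(lme_a - lme_b))


def summarize(
    draws_list: list[PosteriorDraws],
    data: ROIDataset,
    hyper: Hyperparameters,
    ppi_threshold: float = 0.5,
    relabel: bool = True,
) -> PosteriorSummary:
    """Full posterior summary of one or more chains (relabeled by default)."""
    ds = relabel_draws(draws_list) if relabel else draws_list
    ppi = compute_ppi(ds)
    sel = median_model(ppi, ppi_threshold)
    alloc = allocation_probabilities(ds)
    beta_mean, beta_ci, p_pos = beta_summary(ds)
    diag_rows = []
    scalars = {"sigma_0": [d.sigma_0 for d in ds]}
    for p in range(ds[0].beta.shape[1]):
        scalars[f"beta_{p}"] = [d.beta[:, p] for d in ds]
    for name, chains in scalars.items():
        try:
            gz = geweke_z(np.concatenate(chains))
        except ValueError:
            gz = float("nan")
        try:
            psrf = gelman_rubin([np.asarray(c) for c in chains]) if len(chains) > 1 else float("nan")
        except ValueError:
            psrf = float("nan")
        diag_rows.append({"parameter": name, "geweke_z": gz, "psrf": psrf})
    return PosteriorSummary(
        ppi=ppi,
        selected_regions=[data.region_labels[j] for j in sel],
        allocation=alloc,
        modal_state=1 + alloc.argmax(axis=1),
        beta_mean=beta_mean,
        beta_ci=beta_ci,
        prob_or_gt1=p_pos,
        diagnostics=pd.DataFrame(diag_rows),
        dic=dic(ds, data, hyper),
        region_labels=list(data.region_labels),
    )
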