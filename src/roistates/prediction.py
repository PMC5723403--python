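"""Posterior predictive classification and importance-sampling cross-validation.

For a new subject with intensities x_f the predictive event probability
integrates over the posterior draws and the latent state:

    p(y_f = 1 | x_f, X, Y) = (1/T) sum_t sum_k P(eta_f = k | x_f, theta_t)
                              * logistic(xi_f(k)' beta_t),

with P(eta_f = k | x_f) ∝ pi_k N(x_f; mu_k, Sigma_k). The Monte-Carlo
three-step scheme (sample states, then outcomes) and the analytic
Rao-Blackwellized average above are both computed.

Leave-one-out cross-validation reuses the full-data posterior as an
importance-sampling density for the reduced posterior: subject i's weights
are w_t ∝ 1 / p(y_i | eta_i^(t), beta^(t)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit, logsumexp

from .data_model import ROIDataset
from .sampler import PosteriorDraws

__all__ = ["PredictionResult", "predict_new", "loocv_predict", "roc_curve"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class PredictionResult:
    prob_event: np.ndarray
    state_prob: np.ndarray | None
    roc_points: np.ndarray          # (threshold, FPR, TPR) rows
    auc: float
    auc_dense: float
    youden_threshold: float
    confusion_at_threshold: np.ndarray
    ess: np.ndarray | None = None
    ess_flagged: np.ndarray | None = None


def _concat(draws: PosteriorDraws | list[PosteriorDraws]) -> list[PosteriorDraws]:
    return draws if isinstance(draws, list) else [draws]


def _state_psis(beta: np.ndarray, u_f: np.ndarray, K: int) -> np.ndarray:
    """Linear predictor per hypothetical state (state K is reference)."""
    base = beta[0] + float(u_f @ beta[K:]) if beta.shape[0] > K else beta[0]
    psis = np.full(K, base)
    psis[: K - 1] += beta[1:K]
    return psis


def predict_new(
    x_f: np.ndarray,
    u_f: np.ndarray | None,
    draws: PosteriorDraws | list[PosteriorDraws],
    n_eta_samples: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Posterior predictive P(y_f = 1) and state probabilities for one subject.

    Returns ``(prob_event_mc, state_prob, prob_event_rb)``: the Monte-Carlo
    estimate from the three-step sampler with ``n_eta_samples`` state draws
    per posterior draw, the averaged predictive state probabilities, and the
    Rao-Blackwellized estimate.
    """
    ds = _concat(draws)
    K = ds[0].K
    q = ds[0].beta.shape[1] - K
    x_f = np.asarray(x_f, dtype=float)
    if not np.all(np.isfinite(x_f)):
        raise ValueError("x_f must be finite")
    if q > 0 and u_f is None:
        raise ValueError("model was fit with covariates; u_f is required")
    u_f = np.zeros(0) if u_f is None else np.asarray(u_f, dtype=float)
    rng = np.random.default_rng(seed)
    state_prob = np.zeros(K)
    rb = 0.0
    n_event = 0
    n_tot = 0
    T_total = 0
    for d in ds:
        for t in range(d.T):
            var = np.where(d.gamma[t] == 1, d.sigma_k[t][:, None], d.sigma_0[t])
            logp = np.log(d.pi[t]) - 0.5 * np.sum(
                _LOG2PI + np.log(var) + (x_f - d.mu[t]) ** 2 / var, axis=1)
            p_state = np.exp(logp - logsumexp(logp))
            psis = _state_psis(d.beta[t], u_f, K)
            p_event_k = expit(psis)
            state_prob += p_state
            rb += float(p_state @ p_event_k)
            ks = rng.choice(K, size=n_eta_samples, p=p_state)
            ys = rng.random(n_eta_samples) < p_event_k[ks]
            n_event += int(ys.sum())
            n_tot += n_eta_samples
            T_total += 1
    state_prob /= T_total
    return n_event / n_tot, state_prob, rb / T_total


def loocv_predict(
    draws: PosteriorDraws | list[PosteriorDraws],
    data: ROIDataset,
    ess_floor_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Importance-sampling leave-one-out predictive probabilities.

    For each subject i, draws from the full-data posterior are reweighted by
    w_t ∝ 1 / p(y_i | eta_i^(t), beta^(t)) to approximate the posterior
    without subject i's outcome; the estimate is the weighted mean of
    P(Y_i = 1 | eta_i^(t), beta^(t)). Returns ``(probs, ess, flagged)``
    where ``flagged`` marks subjects whose weight effective sample size
    falls below ``ess_floor_frac`` of the draw count.
    """
    ds = _concat(draws)
    K = ds[0].K
    n = data.n
    # stack per-draw quantities
    etas = np.concatenate([d.eta for d in ds], axis=0)        # (T, n)
    betas = np.concatenate([d.beta for d in ds], axis=0)      # (T, p)
    T = etas.shape[0]
    # base: (n, T) linear predictor without the state effect
    if data.q:
        base = betas[:, 0][None, :] + data.U @ betas[:, K:].T
    else:
        base = np.broadcast_to(betas[:, 0][None, :], (n, T)).copy()
    state_eff = np.concatenate([betas.T[1:K], np.zeros((1, T))], axis=0)  # (K, T)
    psi = base + state_eff[etas.T - 1, np.arange(T)[None, :]]             # (n, T)
    log_p1 = log_expit(psi)
    log_py = np.where(data.Y[:, None] == 1, log_p1, log_expit(-psi))
    log_w = -log_py
    log_w -= logsumexp(log_w, axis=1, keepdims=True)
    w = np.exp(log_w)
    probs = np.sum(w * np.exp(log_p1), axis=1)
    ess = 1.0 / np.sum(w**2, axis=1)
    flagged = ess < ess_floor_frac * T
    return probs, ess, flagged


def roc_curve(
    probs: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> PredictionResult:
    """ROC analysis on a threshold grid (default 0, 0.05, ..., 1).

    At each threshold tau the event is predicted iff prob >= tau. ``auc`` is
    the trapezoidal area over the grid's (FPR, TPR) points; ``auc_dense``
    uses every distinct probability as a threshold (equals the pairwise
    concordance statistic with half credit for ties). The Youden threshold
    maximizes TPR - FPR on the grid, ties toward the smaller tau.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    pos = labels == 1
    neg = ~pos
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: labels contain a single class")

    def rates(taus: np.ndarray) -> np.ndarray:
        pts = []
        for tau in taus:
            pred = probs >= tau
            tpr = np.sum(pred & pos) / n_pos
            fpr = np.sum(pred & neg) / n_neg
            pts.append((tau, fpr, tpr))
        return np.asarray(pts)

    def trap_auc(pts: np.ndarray) -> float:
        order = np.lexsort((pts[:, 2], pts[:, 1]))
        fpr = np.concatenate([[0.0], pts[order, 1], [1.0]])
        tpr = np.concatenate([[0.0], pts[order, 2], [1.0]])
        return float(np.trapezoid(tpr, fpr))

    grid_pts = rates(np.asarray(thresholds, dtype=float))
    dense_taus = np.unique(probs)
    dense_pts = rates(np.concatenate([dense_taus, [np.inf]]))
    youden = grid_pts[:, 2] - grid_pts[:, 1]
    best = int(np.flatnonzero(youden == youden.max())[0])
    tau_star = float(grid_pts[best, 0])
    pred = probs >= tau_star
    confusion = np.array([
        [np.sum(~pred & neg), np.sum(pred & neg)],
        [np.sum(~pred & pos), np.sum(pred & pos)],
    ])
    return PredictionResult(
        prob_event=probs,
        state_prob=None,
        roc_points=grid_pts,
        auc=trap_auc(grid_pts),
        auc_dense=trap_auc(dense_pts),
        youden_threshold=tau_star,
        confusion_at_threshold=confusion,
    )
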