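"""Exact sampling from the Polya-Gamma distribution PG(b, c).

A Polya-Gamma variable with parameters b > 0 and c in R is the weighted
infinite sum of gammas

    omega = (1 / (2 pi^2)) * sum_k g_k / ((k - 1/2)^2 + c^2 / (4 pi^2)),

with g_k ~ Gamma(b, 1) independent. Its mean is b/4 at c = 0 and
(b / 2c) tanh(c / 2) otherwise. The logistic-regression augmentation only
requires PG(1, c); draws use the alternating-series rejection sampler of
Devroye for the tilted Jacobi distribution J*(1, z), with
PG(1, c) = J*(1, c/2) / 4. Integer b > 1 is handled by summation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr

__all__ = ["sample_pg", "sample_pg_vector", "pg_mean"]

_TRUNC = 0.64  # series crossover point t of the Jacobi sampler
_HALFPISQ = np.pi**2 / 8.0


def pg_mean(b: float, c: float) -> float:
    """E[PG(b, c)]: b/4 at c = 0, else (b / 2c) tanh(c / 2)."""
    if c == 0.0:
        return b / 4.0
    return (b / (2.0 * c)) * np.tanh(c / 2.0)


def _jacobi_coef(n: int, x: float) -> float:
    """n-th term of the alternating series for the J*(1, 0) density at x."""
    if x <= _TRUNC:
        return (
            np.pi * (n + 0.5) * (2.0 / (np.pi * x)) ** 1.5 * np.exp(-2.0 * (n + 0.5) ** 2 / x)
        )
    return np.pi * (n + 0.5) * np.exp(-((n + 0.5) ** 2) * np.pi**2 * x / 2.0)


def _invgauss_cdf(t: float, z: float) -> float:
    """P(X <= t) for X ~ inverse-Gaussian with mean 1/z, shape 1 (z >= 0)."""
    s = 1.0 / np.sqrt(t)
    if z == 0.0:
        return 2.0 * ndtr(-s)
    b = s * (t * z - 1.0)
    a = -s * (t * z + 1.0)
    return float(ndtr(b) + np.exp(2.0 * z + log_ndtr(a)))


def _sample_truncated_invgauss(z: float, t: float, rng: np.random.Generator) -> float:
    """Draw from inverse-Gaussian(mean 1/z, shape 1) truncated to (0, t]."""
    if z == 0.0 or 1.0 / z > t:
        # mean beyond the truncation point: rejection via the (scaled)
        # one-sided stable proposal of Devroye
        while True:
            while True:
                e1 = rng.exponential()
                e2 = rng.exponential()
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / (1.0 + t * e1) ** 2
            if rng.random() <= np.exp(-0.5 * z * z * x):
                return x
    mu = 1.0 / z
    while True:
        y = rng.standard_normal() ** 2
        x = mu + 0.5 * mu * mu * y - 0.5 * mu * np.sqrt(4.0 * mu * y + (mu * y) ** 2)
        if rng.random() > mu / (mu + x):
            x = mu * mu / x
        if x <= t:
            return x


def _sample_jstar(z: float, rng: np.random.Generator) -> float:
    """Draw from the exponentially tilted Jacobi distribution J*(1, z), z >= 0."""
    z = abs(z)
    t = _TRUNC
    fz = _HALFPISQ + z * z / 2.0
    p = (np.pi / (2.0 * fz)) * np.exp(-fz * t)
    q = 2.0 * np.exp(-z) * _invgauss_cdf(t, z)
    while True:
        if rng.random() < p / (p + q):
            x = t + rng.exponential() / fz
        else:
            x = _sample_truncated_invgauss(z, t, rng)
        # squeeze acceptance via the alternating series
        s = _jacobi_coef(0, x)
        y = rng.random() * s
        n = 0
        accepted = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _jacobi_coef(n, x)
                if y <= s:
                    accepted = True
                    break
            else:
                s += _jacobi_coef(n, x)
                if y > s:
                    break
        if accepted:
            return x


def sample_pg(b: float, c: float, rng: np.random.Generator) -> float:
    """Exact draw from PG(b, c) for positive integer b."""
    if b <= 0:
        raise ValueError(f"b must be positive, got {b}")
    if abs(b - round(b)) > 1e-12:
        raise NotImplementedError("only positive integer b is supported")
    total = 0.0
    for _ in range(int(round(b))):
        total += 0.25 * _sample_jstar(c / 2.0, rng)
    return total


def sample_pg_vector(c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent PG(1, c_i) draws for a vector of tilts."""
    c = np.asarray(c, dtype=float)
    out = np.empty(c.shape)
    flat_c = c.ravel()
    flat_o = out.ravel()
    for i in range(flat_c.size):
        flat_o[i] = 0.25 * _sample_jstar(flat_c[i] / 2.0, rng)
    return out
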