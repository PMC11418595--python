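"""Exact Pólya-Gamma PG(1, c) sampling.

Used for the conjugate data augmentation of logistic Bernoulli nodes:
if y ~ Bernoulli(logistic(psi)) and w ~ PG(1, psi), the conditional of
any parameter entering psi linearly is Gaussian.

The sampler is Devroye's alternating-series rejection method for the
Jacobi J*(1, z) distribution (PG(1, c) = J*(1, c/2) / 4), compiled with
numba.  Expected cost is O(1) draws of uniform/exponential/normal
variates per sample, uniformly in c.

Reference moments used in tests:
    E[PG(1, c)]  = tanh(c/2) / (2 c)        (1/4 at c = 0)
    Var[PG(1,c)] = (sinh(c) - c) / (4 c^3) * sech^2(c/2)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sample_pg", "seed_pg", "pg_mean", "pg_var"]

_TRUNC = 0.64  # crossover point of the two series representations


@njit(cache=True)
def _a_coef(n, x):
    # n-th coefficient of the alternating series for the J*(1, 0) density
    if x > _TRUNC:
        return (
            math.pi
            * (n + 0.5)
            * math.exp(-((n + 0.5) ** 2) * math.pi ** 2 * x / 2.0)
        )
    return (
        math.pi
        * (n + 0.5)
        * (2.0 / (math.pi * x)) ** 1.5
        * math.exp(-2.0 * (n + 0.5) ** 2 / x)
    )


@njit(cache=True)
def _log_norm_cdf(x):
    p = 0.5 * math.erfc(-x / math.sqrt(2.0))
    if p <= 0.0:
        return -1e308
    return math.log(p)


@njit(cache=True)
def _mass_texpon(z):
    # P(proposal falls in the truncated-exponential right tail)
    t = _TRUNC
    k = math.pi ** 2 / 8.0 + z * z / 2.0
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(k) + k * t
    xb = x0 - z + _log_norm_cdf(b)
    xa = x0 + z + _log_norm_cdf(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z):
    # inverse-Gaussian IG(1/z, 1) truncated to (0, _TRUNC)
    t = _TRUNC
    x = t + 1.0
    if z * t < 1.0:  # mean 1/z beyond the truncation point: chi-square trick
        while True:
            while True:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / (1.0 + t * e1) ** 2
            if np.random.random() <= math.exp(-z * z * x / 2.0):
                return x
    mu = 1.0 / z
    while True:
        y = np.random.normal() ** 2
        x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(
            4.0 * mu * y + (mu * y) ** 2
        )
        if np.random.random() > mu / (mu + x):
            x = mu * mu / x
        if x <= t:
            return x


@njit(cache=True)
def _pg1(c):
    # one PG(1, c) draw via J*(1, |c|/2)
    z = abs(c) * 0.5
    k = math.pi ** 2 / 8.0 + z * z / 2.0
    p_right = _mass_texpon(z)
    while True:
        if np.random.random() < p_right:
            x = _TRUNC + np.random.exponential(1.0) / k
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def _sample_pg_array(c, out):
    for i in range(c.shape[0]):
        out[i] = _pg1(c[i])


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


def seed_pg(seed: int) -> None:
    """Seed the (numba-internal) RNG used by :func:`sample_pg`."""
    _seed(int(seed) % (2 ** 31))


def sample_pg(c) -> np.ndarray:
    """Draw one PG(1, c_i) variate per entry of ``c``.

    Seed via :func:`seed_pg` for reproducibility; draws are i.i.d.
    across calls within one seeded stream.
    """
    c = np.ascontiguousarray(np.asarray(c, dtype=np.float64).ravel())
    out = np.empty_like(c)
    _sample_pg_array(c, out)
    return out


def pg_mean(c):
    """E[PG(1, c)], with the c -> 0 limit 1/4."""
    c = np.asarray(c, dtype=float)
    return np.where(np.abs(c) < 1e-8, 0.25, np.tanh(c / 2.0) / (2.0 * np.where(c == 0, 1.0, c)))


def pg_var(c):
    """Var[PG(1, c)], with the c -> 0 limit 1/24."""
    c = np.asarray(c, dtype=float)
    safe = np.where(np.abs(c) < 1e-4, 1.0, c)
    v = (np.sinh(safe) - safe) / (4.0 * safe ** 3) / np.cosh(safe / 2.0) ** 2
    return np.where(np.abs(c) < 1e-4, 1.0 / 24.0, v)
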