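"""Exact Polya-Gamma PG(1, z) sampling.

The logistic likelihood is handled by Polya-Gamma data augmentation: with
omega_i ~ PG(1, psi_i) the Bernoulli-logit likelihood becomes conditionally
Gaussian in the linear predictor psi_i, so all regression coefficients have
normal full conditionals. This module implements the exact alternating-series
rejection sampler of Devroye for PG(1, z), the only case the Bernoulli model
needs.

The density of J*(1, z) (PG(1, z) = J*(1, z)/4 with z halved) is written as an
infinite alternating sum; a two-piece proposal (truncated inverse-Gaussian on
(0, t), exponential tail on (t, inf), t = 0.64) dominates it and the series
partial sums decide acceptance after finitely many terms.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["sample_pg", "pg_mean", "pg_var"]

_TRUNC = 0.64
_SQRT_2 = math.sqrt(2.0)


def _a_coef(n: int, x: float) -> float:
    # n-th coefficient of the alternating series, piecewise in x around _TRUNC
    nph = n + 0.5
    if x > _TRUNC:
        return math.pi * nph * math.exp(-((nph * math.pi) ** 2) * x / 2.0)
    return math.pi * nph * (2.0 / (math.pi * x)) ** 1.5 * math.exp(-2.0 * nph * nph / x)


def _log_ndtr(u: float) -> float:
    v = 0.5 * math.erfc(-u / _SQRT_2)
    if v > 0.0:
        return math.log(v)
    # far left tail: standard asymptotic expansion of the normal cdf
    return -0.5 * u * u - math.log(-u * math.sqrt(2.0 * math.pi))


def _mass_texpon(z: float) -> float:
    """Probability that the proposal draws from the exponential tail piece."""
    t = _TRUNC
    fz = math.pi ** 2 / 8.0 + z * z / 2.0
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _log_ndtr(b)
    xa = x0 + z + _log_ndtr(a)
    if max(xb, xa) > 600.0:  # tail piece has vanishing mass; avoid overflow
        return 0.0
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


def _rtigauss(rng: np.random.Generator, z: float) -> float:
    """Inverse-Gaussian(1/z, 1) truncated to (0, _TRUNC)."""
    t = _TRUNC
    mu = 1.0 / z if z > 0.0 else math.inf
    x = t + 1.0
    if mu > t:
        # rejection from the z = 0 (one-sided stable) case, thinned by exp tilt
        alpha = 0.0
        while rng.random() > alpha:
            e1 = rng.exponential()
            e2 = rng.exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = rng.exponential()
                e2 = rng.exponential()
            x = t / (1.0 + t * e1) ** 2
            alpha = math.exp(-0.5 * z * z * x)
    else:
        # standard IG draw, rejected until it lands below the truncation point
        while x > t:
            y = rng.standard_normal() ** 2
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if rng.random() > mu / (mu + x):
                x = mu * mu / x
    return x


def _draw_pg1(rng: np.random.Generator, psi: float) -> float:
    z = abs(psi) * 0.5
    fz = math.pi ** 2 / 8.0 + z * z / 2.0
    p_tail = _mass_texpon(z)
    while True:
        if rng.random() < p_tail:
            x = _TRUNC + rng.exponential() / fz
        else:
            x = _rtigauss(rng, z)
        s = _a_coef(0, x)
        y = rng.random() * s
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


def sample_pg(rng: np.random.Generator, psi) -> np.ndarray:
    """Draw PG(1, psi) variates, one per element of `psi`.

    Parameters
    ----------
    rng : numpy Generator driving all randomness (determinism contract).
    psi : scalar or array of tilting parameters (the linear predictor).

    Returns
    -------
    Array of draws with the shape of `psi` (0-d input gives a scalar).
    """
    psi = np.asarray(psi, dtype=float)
    if not np.all(np.isfinite(psi)):
        raise ValueError("non-finite tilting parameter in PG sampler")
    flat = psi.ravel()
    out = np.empty(flat.shape)
    for i, p in enumerate(flat):
        out[i] = _draw_pg1(rng, p)
    out = out.reshape(psi.shape)
    return out if out.ndim else float(out)


def pg_mean(z) -> np.ndarray:
    """E[PG(1, z)] = tanh(z/2) / (2 z), with the z -> 0 limit 1/4."""
    z = np.asarray(z, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(z == 0.0, 0.25, np.tanh(z / 2.0) / (2.0 * z))
    return m if m.ndim else float(m)


def pg_var(z) -> np.ndarray:
    """Var[PG(1, z)]; the z -> 0 limit is 1/24."""
    z = np.asarray(z, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        v = np.where(
            z == 0.0,
            1.0 / 24.0,
            (np.sinh(z) - z) / (4.0 * z ** 3 * np.cosh(z / 2.0) ** 2),
        )
    return v if v.ndim else float(v)
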