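"""Pólya–Gamma random variate generation.

The Pólya–Gamma family PG(b, c) is the infinite convolution of gammas

    P = (1 / (2 pi^2)) * sum_{s>=1} g_s / ((s - 1/2)^2 + c^2 / (4 pi^2)),
    g_s ~ Gamma(b, 1),

whose data-augmentation identity turns a logistic likelihood into a
conditionally Gaussian one.  Two samplers are provided:

``exact``
    The Devroye alternating-series rejection sampler for PG(1, c)
    (integer ``b`` is handled by additivity), JIT-compiled with numba.
    This is the device used inside the Gibbs sampler.

``truncated_series``
    Direct truncation of the gamma-convolution representation to
    ``series_terms`` terms plus a moment-matched gamma correction for the
    discarded tail.  Valid for any real ``b > 0``; retained as an
    independent cross-check of the exact device.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sample_pg", "pg_mean", "pg_var"]

_TRUNC = 0.64
_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


@njit(cache=True)
def _log_phi(x: float) -> float:
    # log of the standard normal CDF, with an asymptotic branch for the
    # deep left tail where erfc underflows.
    if x > -8.0:
        return math.log(0.5 * math.erfc(-x * 0.7071067811865476))
    xx = x * x
    return -0.5 * xx - 0.9189385332046727 - math.log(-x) + math.log1p(-1.0 / xx + 3.0 / (xx * xx))


@njit(cache=True)
def _mass_texpon(z: float) -> float:
    # Probability that the dominating mixture proposes from the truncated
    # exponential (right) branch rather than the truncated inverse-Gaussian.
    t = _TRUNC
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    inv_sqrt_t = 1.0 / math.sqrt(t)
    b = inv_sqrt_t * (t * z - 1.0)
    a = -inv_sqrt_t * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _log_phi(b)
    xa = x0 + z + _log_phi(a)
    q_div_p = 4.0 / math.pi * (np.exp(xb) + np.exp(xa))
    return 1.0 / (1.0 + q_div_p)


@njit(cache=True)
def _rtigauss(z: float, rng) -> float:
    # Inverse-Gaussian IG(mu=1/z, lambda=1) truncated to (0, t].
    t = _TRUNC
    x = t + 1.0
    if t * z < 1.0:  # mu > t: rejection from scaled chi^{-2} proposal
        while True:
            while True:
                e1 = rng.standard_exponential()
                e2 = rng.standard_exponential()
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if rng.random() <= np.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while x > t:
            y = rng.standard_normal()
            y = y * y
            mu_y = mu * y
            x = mu + 0.5 * mu * mu_y - 0.5 * mu * math.sqrt(4.0 * mu_y + mu_y * mu_y)
            if rng.random() > mu / (mu + x):
                x = mu * mu / x
        return x


@njit(cache=True)
def _a_coef(n: int, x: float) -> float:
    # n-th coefficient of the alternating series for the J*(1, .) density.
    nph = n + 0.5
    if x > _TRUNC:
        return math.pi * nph * np.exp(-0.5 * nph * nph * math.pi * math.pi * x)
    return math.pi * nph * (2.0 / (math.pi * x)) ** 1.5 * np.exp(-2.0 * nph * nph / x)


@njit(cache=True)
def _pg1_draw(c: float, rng) -> float:
    # One PG(1, c) draw: PG(1, c) = J*(1, c/2) / 4.
    z = 0.5 * abs(c)
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    p_texp = _mass_texpon(z)
    while True:
        if rng.random() < p_texp:
            x = _TRUNC + rng.standard_exponential() / fz
        else:
            x = _rtigauss(z, rng)
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


@njit(cache=True)
def _pg1_vector(c: np.ndarray, rng) -> np.ndarray:
    out = np.empty(c.shape[0])
    for i in range(c.shape[0]):
        out[i] = _pg1_draw(c[i], rng)
    return out


def _exact(b: int, c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = _pg1_vector(c, rng)
    for _ in range(b - 1):
        out = out + _pg1_vector(c, rng)
    return out


def _series(b: float, c: np.ndarray, rng: np.random.Generator, terms: int) -> np.ndarray:
    n = c.shape[0]
    d = (c / (2.0 * math.pi)) ** 2
    s = np.arange(1, terms + 1) - 0.5
    out = np.zeros(n)
    # chunk over s to bound the (terms x n) temporaries
    chunk = max(1, int(2e6) // max(n, 1))
    for lo in range(0, terms, chunk):
        ss = s[lo : lo + chunk, None]
        g = rng.gamma(b, 1.0, size=(ss.shape[0], n))
        out += (g / (ss * ss + d[None, :])).sum(axis=0)
    # moment-matched gamma correction for the truncated tail
    s_tail = (np.arange(terms + 1, terms + 4001) - 0.5) ** 2
    m = np.empty(n)
    v = np.empty(n)
    for lo in range(0, n, max(1, int(2e6) // 4000)):
        sl = slice(lo, lo + max(1, int(2e6) // 4000))
        inv = 1.0 / (s_tail[:, None] + d[None, sl])
        m[sl] = b * inv.sum(axis=0)
        v[sl] = b * (inv * inv).sum(axis=0)
    pos = m > 0
    if np.any(pos):
        shape = np.where(pos, m * m / np.where(pos, v, 1.0), 1.0)
        scale = np.where(pos, v / np.where(pos, m, 1.0), 0.0)
        out[pos] += rng.gamma(shape[pos], scale[pos])
    return out / (2.0 * math.pi * math.pi)


def sample_pg(
    b: float,
    c,
    size: int | None = None,
    *,
    method: str = "exact",
    series_terms: int = 200,
    random_state=None,
) -> np.ndarray:
    """Draw Pólya–Gamma PG(b, c) variates.

    Parameters
    ----------
    b : positive real (integer required for ``method="exact"``)
        Shape parameter.
    c : real scalar or 1-d array
        Tilting parameter.  An array of tiltings yields one draw per entry.
    size : int, optional
        Number of draws when ``c`` is scalar; ignored (must match) when
        ``c`` is an array.
    method : {"exact", "truncated_series"}
    series_terms : int
        Number of gamma terms kept by the series sampler.
    random_state : None, int or numpy Generator
    """
    if not (b > 0):
        raise ValueError(f"b must be positive, got {b}")
    if series_terms < 1:
        raise ValueError("series_terms must be >= 1")
    rng = np.random.default_rng(random_state) if not isinstance(random_state, np.random.Generator) else random_state
    c_arr = np.atleast_1d(np.asarray(c, dtype=float))
    scalar_c = np.ndim(c) == 0
    if scalar_c and size is not None:
        c_arr = np.full(size, float(c))
    elif not scalar_c and size is not None and size != c_arr.shape[0]:
        raise ValueError("size must match len(c) for array-valued c")
    if not np.all(np.isfinite(c_arr)):
        raise ValueError("c must be finite")
    if method == "exact":
        b_int = int(round(b))
        if abs(b - b_int) > 1e-12 or b_int < 1:
            raise ValueError("exact method requires positive integer b; use truncated_series")
        return _exact(b_int, c_arr, rng)
    if method == "truncated_series":
        return _series(float(b), c_arr, rng, series_terms)
    raise ValueError(f"unknown method {method!r}")


def pg_mean(b: float, c: float) -> float:
    """E[PG(b, c)] = (b / 2c) tanh(c / 2), continuously b/4 at c = 0."""
    if c == 0.0:
        return b / 4.0
    return b / (2.0 * c) * math.tanh(c / 2.0)


def pg_var(b: float, c: float) -> float:
    """Var[PG(b, c)] via the exact closed form (series limit at c = 0)."""
    if c == 0.0:
        return b / 24.0
    sech2 = 1.0 / math.cosh(0.5 * c) ** 2
    return b / (4.0 * c**3) * (math.sinh(c) - c) * sech2
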