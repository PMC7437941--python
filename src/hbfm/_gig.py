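"""Vectorized generalized inverse Gaussian (GIG) sampling.

The three-parameter GIG(p, a, b) density is

    f(x) ∝ x^{p-1} exp{-(a x + b / x) / 2},   x > 0,  a > 0,  b > 0.

Sampling is by ratio-of-uniforms with a shift to the mode, applied to the
standardized two-parameter form gig(p, ω) with ω = sqrt(a b); negative
orders use the reciprocal identity 1/gig(p, ω) ~ gig(-p, ω).  The
rejection loop is fully vectorized over heterogeneous parameter arrays;
the rare parameter combinations the envelope handles poorly (all three of
|p| ≤ 1, ω ≤ 0.5 and repeated rejections) fall back to
``scipy.stats.geninvgauss``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["gig_rvs", "gig_logpdf"]

_MAX_ROUNDS = 100


def gig_logpdf(x, p, a, b):
    """Unnormalized log-density of GIG(p, a, b) at ``x`` (elementwise).

    The normalizing constant (a Bessel-K ratio) is omitted: the intended
    use is Metropolis–Hastings ratios with fixed parameters, where it
    cancels.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (p - 1.0) * np.log(x) - 0.5 * (a * x + b / x)
    return np.where(x > 0, out, -np.inf)


def _mode(lam, omega):
    # positive root of the stationarity condition of gig(lam, omega)
    t = lam - 1.0
    return (t + np.sqrt(t * t + omega * omega)) / omega


def _log_g(x, lam, omega, m):
    """log of the density of gig(lam, omega) normalized to 1 at the mode m."""
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (lam - 1.0) * (np.log(x) - np.log(m)) - 0.5 * omega * (
            x + 1.0 / x - m - 1.0 / m
        )
    return np.where(x > 0, val, -np.inf)


def _rou_bounds(lam, omega, m):
    """Bounding rectangle of the mode-shifted ratio-of-uniforms region.

    The two bounding abscissae are the real roots (other than the
    negative spurious one) of x^3 + A x^2 + B x + C = 0; the cubic is
    solved in closed form by the trigonometric method (three real roots
    are guaranteed here: one negative, one in (0, m), one above m).
    """
    A = -(2.0 * (lam + 1.0) / omega + m)
    B = 2.0 * (lam - 1.0) * m / omega - 1.0
    C = m
    # depressed cubic t^3 + pt + q, x = t - A/3
    p = B - A * A / 3.0
    q = 2.0 * A**3 / 27.0 - A * B / 3.0 + C
    with np.errstate(invalid="ignore"):
        arg = 3.0 * q / (2.0 * p) * np.sqrt(-3.0 / p)
    arg = np.clip(arg, -1.0, 1.0)
    theta = np.arccos(arg)
    r = 2.0 * np.sqrt(np.maximum(-p / 3.0, 0.0))
    shift = -A / 3.0
    roots = np.stack(
        [r * np.cos((theta - 2.0 * np.pi * k) / 3.0) + shift for k in range(3)]
    )
    roots = np.sort(roots, axis=0)  # r0 < 0 < r1 < m < r2
    x_lo = np.clip(roots[1], 1e-300, None)
    x_hi = roots[2]
    v_lo = (x_lo - m) * np.exp(0.5 * _log_g(x_lo, lam, omega, m))
    v_hi = (x_hi - m) * np.exp(0.5 * _log_g(x_hi, lam, omega, m))
    return v_lo, v_hi


def _gig_standard(lam, omega, rng):
    """Draws from gig(lam, omega) (two-parameter form), lam >= 0 elementwise."""
    lam = np.asarray(lam, dtype=float)
    omega = np.asarray(omega, dtype=float)
    n = lam.shape[0]
    m = _mode(lam, omega)
    v_lo, v_hi = _rou_bounds(lam, omega, m)

    out = np.empty(n)
    todo = np.ones(n, dtype=bool)
    for _ in range(_MAX_ROUNDS):
        idx = np.flatnonzero(todo)
        if idx.size == 0:
            break
        u = rng.random(idx.size)
        v = v_lo[idx] + (v_hi[idx] - v_lo[idx]) * rng.random(idx.size)
        x = v / u + m[idx]
        ok = x > 0
        with np.errstate(divide="ignore"):
            ok &= 2.0 * np.log(u) <= _log_g(x, lam[idx], omega[idx], m[idx])
        out[idx[ok]] = x[ok]
        todo[idx[ok]] = False
    if todo.any():  # pathological corner: exact but slow scipy path
        idx = np.flatnonzero(todo)
        out[idx] = stats.geninvgauss.rvs(
            lam[idx], omega[idx], random_state=rng
        )
    return out


def gig_rvs(p, a, b, rng):
    """Sample GIG(p, a, b) elementwise for arrays of parameters.

    Parameters
    ----------
    p : array_like
        Order; any real values.
    a, b : array_like
        Positive rate parameters of x and 1/x respectively.
    rng : numpy.random.Generator

    Returns
    -------
    ndarray of draws, one per parameter triple.
    """
    p, a, b = np.broadcast_arrays(
        np.asarray(p, dtype=float), np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    )
    p, a, b = p.ravel(), a.ravel(), b.ravel()
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("GIG requires a > 0 and b > 0; use the Gamma/"
                         "inverse-Gamma limits for boundary cases")
    omega = np.sqrt(a * b)
    scale = np.sqrt(b / a)
    neg = p < 0
    z = _gig_standard(np.abs(p), omega, rng)
    z[neg] = 1.0 / z[neg]
    return z * scale
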