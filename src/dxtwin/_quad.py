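"""Deterministic quadrature helpers for Gaussian latent integrals."""

from __future__ import annotations

import numpy as np
from scipy import special

_TINY = 1e-300
_ONE_MINUS = 1.0 - 1e-16


def gauss_hermite(n: int):
    """Nodes/weights for E[f(Z)], Z ~ N(0,1): returns (z, w), sum(w) = 1."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def midq_nodes(n: int):
    """Mid-quantile probabilities (midpoint rule in probability space)."""
    return (np.arange(n) + 0.5) / n


def trunc_normal_nodes(mu, sigma, lo, hi, n: int):
    """Gauss-Legendre nodes in probability space for a truncated normal.

    Returns ``(z, w)`` with ``z`` the node locations and ``w`` weights
    summing to ``P(lo < Z < hi)`` for ``Z ~ N(mu, sigma^2)``.  Shapes
    broadcast: mu/lo/hi may be arrays, the node axis is appended last.
    """
    mu = np.asarray(mu, dtype=float)
    a = special.ndtr((np.asarray(lo, dtype=float) - mu) / sigma)
    b = special.ndtr((np.asarray(hi, dtype=float) - mu) / sigma)
    x, wl = np.polynomial.legendre.leggauss(n)
    u = a[..., None] + (b - a)[..., None] * (x + 1.0) / 2.0
    u = np.clip(u, _TINY, _ONE_MINUS)
    z = mu[..., None] + sigma * special.ndtri(u)
    w = (b - a)[..., None] * wl / 2.0
    return z, w


def trunc_midq_nodes(mu, sigma, a, b, n: int):
    """Mid-quantile nodes of a normal restricted to CDF interval (a, b).

    ``a``/``b`` are conditional-CDF bounds already on the probability
    scale.  Returns node locations only; each node carries equal
    conditional weight ``1/n``.
    """
    mu = np.asarray(mu, dtype=float)
    q = midq_nodes(n)
    u = np.asarray(a, dtype=float)[..., None] + (
        np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    )[..., None] * q
    u = np.clip(u, _TINY, _ONE_MINUS)
    return mu[..., None] + sigma * special.ndtri(u)
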