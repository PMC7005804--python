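"""Stochastic dependence between methylation density change and expression change.

Rank-based analyses only: Spearman correlation, pseudo-observations, an FGM
copula fit by maximum likelihood on the pseudo-observations, and a 2D
Gaussian kernel density estimate of the joint distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CopulaFit",
    "spearman_rho",
    "pseudo_observations",
    "fgm_fit",
    "fgm_loglik",
    "kde2d",
]


@dataclass(frozen=True)
class CopulaFit:
    """FGM copula dependence parameter with implied rank correlations."""

    theta: float
    loglik: float
    tau_implied: float  # 2*theta/9
    rho_s_implied: float  # theta/3
    n: int
    at_boundary: bool


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    p-value: t approximation for n > 30; permutation for n <= 30 (exhaustive
    for n <= 8, 20000 Monte-Carlo permutations otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("paired vectors of length >= 4 required")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector; Spearman rho undefined")
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > 30:
        p = float(stats.spearmanr(x, y)[1])
        return rho, p
    if n <= 8:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    rng = np.random.default_rng(12345)
    n_perm = 20000
    count = 0
    for _ in range(n_perm):
        r = np.corrcoef(rx, rng.permutation(ry))[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return rho, (count + 1) / (n_perm + 1)


def pseudo_observations(x) -> np.ndarray:
    """u_i = rank(x_i) / (n + 1), average ranks for ties; values in (0, 1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("need n >= 1")
    return stats.rankdata(x) / (x.size + 1)


def fgm_loglik(theta: float, u: np.ndarray, v: np.ndarray) -> float:
    """Log likelihood of the FGM copula density c(u,v) = 1 + theta(1-2u)(1-2v)."""
    core = theta * (1.0 - 2.0 * u) * (1.0 - 2.0 * v)
    if np.any(core <= -1.0):
        return -np.inf
    return float(np.sum(np.log1p(core)))


def fgm_fit(u, v) -> CopulaFit:
    """Maximum-likelihood FGM copula fit, theta constrained to [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size != v.size or u.size < 4:
        raise ValueError("paired pseudo-observations of length >= 4 required")
    if np.any((u <= 0) | (u >= 1) | (v <= 0) | (v >= 1)):
        raise ValueError("pseudo-observations must lie strictly in (0, 1)")
    res = optimize.minimize_scalar(
        lambda t: -fgm_loglik(t, u, v), bounds=(-1.0, 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    theta = float(res.x)
    ll = fgm_loglik(theta, u, v)
    if not np.isfinite(ll):
        raise ValueError("non-finite FGM likelihood")
    # snap near-boundary optima (bounded optimizer cannot reach the bounds exactly)
    at_boundary = abs(abs(theta) - 1.0) < 1e-6
    if at_boundary:
        theta = float(np.sign(theta))
        ll = fgm_loglik(theta, u, v)
        if not np.isfinite(ll):
            theta = float(res.x)
            ll = fgm_loglik(theta, u, v)
        warnings.warn("FGM theta estimate at the boundary of [-1, 1]", stacklevel=2)
    return CopulaFit(theta=theta, loglik=ll, tau_implied=2.0 * theta / 9.0,
                     rho_s_implied=theta / 3.0, n=int(u.size), at_boundary=at_boundary)


def kde2d(x, y, gridsize: int = 100,
          extent: tuple[float, float, float, float] | None = None
          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D Gaussian-product KDE (Scott's rule) evaluated on a regular grid.

    Returns (xs, ys, Z) with Z[i, j] the density at (xs[j], ys[i]).  The grid
    extends 3 marginal standard deviations beyond the data range by default,
    so the surface integrates to ~1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 10:
        raise ValueError("paired vectors of length >= 10 required")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (zero-variance) marginal")
    kde = stats.gaussian_kde(np.vstack([x, y]))  # Scott's rule by default
    if extent is None:
        pad_x, pad_y = 3.0 * x.std(), 3.0 * y.std()
        extent = (x.min() - pad_x, x.max() + pad_x, y.min() - pad_y, y.max() + pad_y)
    xs = np.linspace(extent[0], extent[1], gridsize)
    ys = np.linspace(extent[2], extent[3], gridsize)
    xx, yy = np.meshgrid(xs, ys)
    z = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(gridsize, gridsize)
    return xs, ys, z
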