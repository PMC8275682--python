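"""Stationary density of the cusp diffusion and its numerical machinery.

The diffusion dz = (-z^3 + beta z + alpha) dt + sigma_z dW has stationary
density proportional to exp(2 U(z) / sigma_z^2) with U(z) = alpha z +
beta z^2/2 - z^4/4.  The canonical scaling used throughout the fitting code
absorbs sigma_z (equivalently sigma_z = sqrt(2)), giving

    f(z; alpha, beta) = exp(alpha z + beta z^2 / 2 - z^4 / 4) / C(alpha, beta)

The public functions use adaptive quadrature (normalization exact to ~1e-10).
A vectorized Simpson-grid path (:func:`grid_log_partition_moments`) serves
the likelihood optimizer, where thousands of (alpha_t, beta_t) pairs must be
normalized per evaluation.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

from ..data_model import ValidationError
from .geometry import equilibria


def _exponent(z, alpha, beta):
    return alpha * z + 0.5 * beta * z * z - 0.25 * z**4


def integration_radius(alpha: float, beta: float) -> float:
    """Half-width of a window outside which the density is negligible
    (quartic decay dominates; tail exponent < -60 at the returned radius)."""
    r = 3.5 + 1.5 * max(1.0, np.sqrt(max(beta, 0.0)), abs(alpha) ** (1.0 / 3.0))
    gmax = max(_exponent(z, alpha, beta) for z, _ in equilibria(alpha, beta))
    while max(_exponent(r, alpha, beta), _exponent(-r, alpha, beta)) - gmax > -60:
        r *= 1.4
    return r


def log_partition(alpha: float, beta: float) -> float:
    """log of C(alpha, beta) = integral exp(alpha z + beta z^2/2 - z^4/4) dz."""
    eq = equilibria(alpha, beta)
    peaks = [z for z, _ in eq] or [0.0]
    gmax = max(_exponent(np.asarray(z), alpha, beta) for z in peaks)
    r = integration_radius(alpha, beta)
    val, err = integrate.quad(
        lambda z: np.exp(_exponent(z, alpha, beta) - gmax),
        -r,
        r,
        points=sorted(peaks),
        limit=200,
        epsabs=1e-12,
        epsrel=1e-11,
    )
    if not np.isfinite(val) or val <= 0 or err > 1e-8 * val:
        raise ValidationError(
            f"quadrature failed for alpha={alpha}, beta={beta}: value={val}, err={err}")
    return float(gmax + np.log(val))


def stationary_density(z, alpha: float, beta: float):
    """Normalized stationary density f(z; alpha, beta); integrates to 1."""
    z = np.asarray(z, dtype=float)
    logc = log_partition(alpha, beta)
    out = np.exp(_exponent(z, alpha, beta) - logc)
    return float(out) if out.ndim == 0 else out


def stationary_moments(alpha: float, beta: float) -> tuple[float, float]:
    """(E[z], E[z^2]) of the stationary density, by adaptive quadrature."""
    logc = log_partition(alpha, beta)
    peaks = sorted(z for z, _ in equilibria(alpha, beta)) or [0.0]
    r = integration_radius(alpha, beta)

    def moment(k):
        val, _ = integrate.quad(
            lambda z: z**k * np.exp(_exponent(z, alpha, beta) - logc),
            -r, r, points=peaks, limit=200,
        )
        return float(val)

    return moment(1), moment(2)


def stationary_modes(alpha: float, beta: float) -> list[float]:
    """Modes of the stationary density = stable equilibria of the drift."""
    return [z for z, label in equilibria(alpha, beta) if label == "stable"]


def _grid(alphas: np.ndarray, betas: np.ndarray, n_grid: int) -> np.ndarray:
    """Shared z-grid wide enough that every row's density has negligible tails."""
    amax = float(np.max(np.abs(alphas))) if len(alphas) else 1.0
    bmax = float(np.max(betas)) if len(betas) else 0.0
    r = 3.5 + 1.5 * max(1.0, np.sqrt(max(bmax, 0.0)), abs(amax) ** (1.0 / 3.0))
    return np.linspace(-r, r, n_grid)


def grid_log_partition_moments(
    alphas, betas, n_grid: int = 513
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (logC, E[z], E[z^2]) for paired (alpha_t, beta_t) arrays.

    Composite-Simpson on a common grid; the grid is widened until the tail
    contribution is negligible for every row.  Returns (grid, logC, Ez, Ez2).
    """
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    if n_grid % 2 == 0:
        n_grid += 1
    r = float(_grid(alphas, betas, 3)[-1])
    for _ in range(8):
        zg = np.linspace(-r, r, n_grid)
        g = (
            alphas[:, None] * zg[None, :]
            + 0.5 * betas[:, None] * zg[None, :] ** 2
            - 0.25 * zg[None, :] ** 4
        )
        gmax = g.max(axis=1, keepdims=True)
        tail = max(float((g[:, 0] - gmax[:, 0]).max()),
                   float((g[:, -1] - gmax[:, 0]).max()))
        if tail < -30.0:
            break
        r *= 1.4
    w = np.ones(n_grid)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    h = (zg[-1] - zg[0]) / (n_grid - 1)
    w *= h / 3.0
    e = np.exp(g - gmax)
    c0 = e @ w
    c1 = e @ (w * zg)
    c2 = e @ (w * zg * zg)
    logc = gmax[:, 0] + np.log(c0)
    return zg, logc, c1 / c0, c2 / c0
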