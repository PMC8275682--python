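"""Deterministic geometry of the cusp catastrophe.

Potential (sign convention: minima of V are stable equilibria):

    V(z; alpha, beta) = z^4/4 - beta z^2/2 - alpha z

Equilibria solve V'(z) = 0, i.e. the cubic  z^3 - beta z - alpha = 0, whose
real-root count is governed by Cardan's discriminant

    delta = 27 alpha^2 - 4 beta^3

with one real root for delta > 0 and three for delta < 0.  The zero set
delta = 0, i.e. alpha = +/- sqrt(4 beta^3 / 27) for beta >= 0, bounds the
bistable "cusp area" in the (alpha, beta) control plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..data_model import ValidationError

#: relative half-width of the |delta| ~ 0 band labelled "boundary"
BOUNDARY_RTOL = 1e-9


@dataclass(frozen=True)
class CuspSurfacePoint:
    """One observation located on the cusp control/state surface."""

    alpha: float
    beta: float
    z: float
    delta: float
    state_class: str  # stable | bistable | boundary
    year: int | None = None

    def to_dict(self) -> dict:
        return {
            "year": self.year,
            "alpha": self.alpha,
            "beta": self.beta,
            "z": self.z,
            "delta": self.delta,
            "state_class": self.state_class,
        }


def potential(z, alpha, beta):
    """Cusp potential V(z) = z^4/4 - beta z^2/2 - alpha z (vectorized)."""
    z = np.asarray(z, dtype=float)
    return 0.25 * z**4 - 0.5 * beta * z**2 - alpha * z


def cardan_discriminant(alpha, beta):
    """delta = 27 alpha^2 - 4 beta^3; positive iff a single real equilibrium."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    out = 27.0 * alpha**2 - 4.0 * beta**3
    return float(out) if out.ndim == 0 else out


def classify_state(alpha: float, beta: float) -> str:
    """Classify a control point: 'bistable' (delta<0), 'stable' (delta>0) or
    'boundary' within a small relative band around delta = 0."""
    delta = cardan_discriminant(alpha, beta)
    band = BOUNDARY_RTOL * max(1.0, abs(27.0 * alpha**2), abs(4.0 * beta**3))
    if abs(delta) < band:
        return "boundary"
    return "bistable" if delta < 0 else "stable"


def equilibria(alpha: float, beta: float) -> list[tuple[float, str]]:
    """Real roots of z^3 - beta z - alpha = 0 with stability labels.

    Labels from the curvature V''(z) = 3 z^2 - beta: 'stable' (V''>0),
    'unstable' (V''<0), 'degenerate' at a fold (double root, V''~0).
    Returned sorted by z.
    """
    if not (np.isfinite(alpha) and np.isfinite(beta)):
        raise ValidationError("alpha and beta must be finite")
    roots = np.roots([1.0, 0.0, -beta, -alpha])
    scale = max(1.0, abs(alpha) ** (1 / 3), abs(beta) ** 0.5)
    real = sorted(r.real for r in roots if abs(r.imag) < 1e-8 * scale)
    # merge numerically coincident roots (fold points)
    merged: list[float] = []
    for r in real:
        if merged and abs(r - merged[-1]) < 1e-7 * scale:
            merged[-1] = 0.5 * (merged[-1] + r)
        else:
            merged.append(r)
    out = []
    for z in merged:
        curv = 3.0 * z * z - beta
        if curv > 1e-7 * scale**2:
            label = "stable"
        elif curv < -1e-7 * scale**2:
            label = "unstable"
        else:
            label = "degenerate"
        out.append((float(z), label))
    return out


def bifurcation_set(beta_grid) -> pd.DataFrame:
    """Bifurcation boundary alpha = +/- sqrt(4 beta^3 / 27) on a beta >= 0 grid.

    The closed region between ``alpha_low`` and ``alpha_high`` is the
    bistable cusp area (the shaded polygon in control-plane plots).
    """
    beta = np.asarray(beta_grid, dtype=float)
    if np.any(beta < 0):
        raise ValidationError("bifurcation set requires beta >= 0 "
                              "(no bistable region exists for beta < 0)")
    half = np.sqrt(4.0 * beta**3 / 27.0)
    return pd.DataFrame({"beta": beta, "alpha_low": -half, "alpha_high": half})
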