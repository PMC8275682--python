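"""Maximum-likelihood fit of the stochastic cusp model to an annual table.

Canonical variables are linear in one observed variable each:

    z_t     = omega0 + omega1 * state_t        (state; default SSB)
    alpha_t = a0 + a1 * asym_t                 (asymmetry; default F/R)
    beta_t  = b0 + b1 * bifur_t                (bifurcation; default SST)

and the likelihood of the observed state y_t is the stationary density of
the cusp diffusion evaluated at z_t, times the Jacobian |omega1| of the
linear state map:

    log L = sum_t [ alpha_t z_t + beta_t z_t^2/2 - z_t^4/4 - log C(alpha_t, beta_t) ]
            + n log |omega1|.

The six coefficients are estimated by quasi-Newton ascent with analytic
gradients (the derivatives of log C are stationary moments, computed on the
same Simpson grid as the normalization) from 8 deterministic starts covering
the sign patterns of the control slopes.  Variables are standardized to zero
mean / unit sd internally and the coefficients mapped back afterwards; the
canonical coefficients are affine-equivariant, so reported per-year
(alpha_t, beta_t, z_t) and all classifications are unchanged by this.

The fitted sign indeterminacy (z, alpha) -> (-z, -alpha) leaves the
likelihood invariant; fits are canonicalized to omega1 > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ..data_model import StockSeriesTable, ValidationError, resolve_variable
from .density import grid_log_partition_moments, stationary_moments, stationary_modes
from .geometry import CuspSurfacePoint, cardan_discriminant, classify_state

_N_GRID = 513


@dataclass(frozen=True)
class CuspFit:
    """Fitted canonical coefficients, per-year surface points and diagnostics."""

    state_var: str
    asym_var: str
    bifur_var: str
    omega0: float
    omega1: float
    a0: float
    a1: float
    b0: float
    b1: float
    loglik: float
    converged: bool
    per_year: tuple[CuspSurfacePoint, ...]
    n_bistable: int
    aic: float
    se_omega1_std: float
    p_omega1: float
    n_params: int = 6
    # internals needed for prediction / validation
    _std: dict = field(default_factory=dict, repr=False)
    _arrays: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return len(self.per_year)

    @property
    def pct_in_cusp(self) -> float:
        return 100.0 * self.n_bistable / self.n

    def to_dict(self) -> dict:
        return {
            "state_var": self.state_var,
            "asym_var": self.asym_var,
            "bifur_var": self.bifur_var,
            "coefficients": {
                "omega0": self.omega0,
                "omega1": self.omega1,
                "a0": self.a0,
                "a1": self.a1,
                "b0": self.b0,
                "b1": self.b1,
            },
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "n_bistable": self.n_bistable,
            "pct_in_cusp": self.pct_in_cusp,
            "p_omega1": self.p_omega1,
            "per_year": [p.to_dict() for p in self.per_year],
        }


def _standardize(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu, sd = float(np.mean(v)), float(np.std(v, ddof=0))
    if sd <= 0:
        raise ValidationError("constant variable cannot enter the cusp fit")
    return (v - mu) / sd, mu, sd


def _nll_and_grad(theta: np.ndarray, ys: np.ndarray, x1: np.ndarray,
                  x2: np.ndarray) -> tuple[float, np.ndarray]:
    w0, w1, a0, a1, b0, b1 = theta
    n = len(ys)
    z = w0 + w1 * ys
    al = a0 + a1 * x1
    be = b0 + b1 * x2
    _, logc, ez, ez2 = grid_log_partition_moments(al, be, _N_GRID)
    expo = al * z + 0.5 * be * z * z - 0.25 * z**4
    nll = -(np.sum(expo - logc) + n * np.log(abs(w1)))
    u = al + be * z - z**3  # d exponent / dz
    g = np.empty(6)
    g[0] = -np.sum(u)
    g[1] = -np.sum(u * ys) - n / w1
    g[2] = -np.sum(z - ez)
    g[3] = -np.sum(x1 * (z - ez))
    g[4] = -0.5 * np.sum(z * z - ez2)
    g[5] = -0.5 * np.sum(x2 * (z * z - ez2))
    return float(nll), g


def _starts() -> list[np.ndarray]:
    """8 deterministic multi-starts: identity state map, sign grid over the
    control slopes, two bifurcation intercept levels."""
    starts = []
    for sa in (1.0, -1.0):
        for sb in (1.0, -1.0):
            for b0 in (0.5, 1.5):
                starts.append(np.array([0.0, 1.0, 0.0, sa, b0, sb]))
    return starts


def _hessian(fun_grad, theta: np.ndarray, *args, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from the analytic gradient."""
    k = len(theta)
    H = np.zeros((k, k))
    for i in range(k):
        step = eps * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += step
        tm[i] -= step
        _, gp = fun_grad(tp, *args)
        _, gm = fun_grad(tm, *args)
        H[i] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


def fit_cusp(
    table: StockSeriesTable,
    state_var: str = "ssb",
    asym_var: str = "scaled_pressure",
    bifur_var: str = "sst",
    min_observations: int = 20,
) -> CuspFit:
    """Fit the stochastic cusp model to three columns of an annual table."""
    state_var = resolve_variable(state_var)
    asym_var = resolve_variable(asym_var)
    bifur_var = resolve_variable(bifur_var)
    if table.n < min_observations:
        raise ValidationError(
            f"cusp fit needs >= {min_observations} observations, got {table.n}")
    y = table.column(state_var)
    x1r = table.column(asym_var)
    x2r = table.column(bifur_var)
    return fit_cusp_arrays(y, x1r, x2r, years=table.years,
                           state_var=state_var, asym_var=asym_var,
                           bifur_var=bifur_var)


def fit_cusp_arrays(
    y, x1r, x2r, years=None,
    state_var: str = "state", asym_var: str = "asymmetry",
    bifur_var: str = "bifurcation",
) -> CuspFit:
    """Array-level cusp fit (used by the table front-end and the simulation
    harnesses)."""
    y = np.asarray(y, dtype=float)
    x1r = np.asarray(x1r, dtype=float)
    x2r = np.asarray(x2r, dtype=float)
    n = len(y)
    if years is None:
        years = np.arange(n)
    ys, my, sy = _standardize(y)
    x1, m1, s1 = _standardize(x1r)
    x2, m2, s2 = _standardize(x2r)

    best = None
    n_ok = 0
    # standardized canonical coefficients are O(1); the box keeps the
    # optimizer off the degenerate |beta| -> inf Gaussian ridge, where the
    # density collapses below grid resolution
    bounds = [(-15.0, 15.0)] * 6
    for theta0 in _starts():
        res = optimize.minimize(
            _nll_and_grad, theta0, args=(ys, x1, x2), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 400, "ftol": 1e-12, "gtol": 1e-8},
        )
        if np.isfinite(res.fun):
            n_ok += int(res.success)
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise ValidationError("cusp fit failed from every start")
    converged = bool(n_ok > 0 and np.isfinite(best.fun))
    theta = best.x.copy()
    if theta[1] < 0:  # canonicalize the (z, alpha) -> (-z, -alpha) symmetry
        theta[[0, 1, 2, 3]] *= -1.0
    w0, w1, a0s, a1s, b0s, b1s = theta
    if abs(w1) < 1e-3:
        warnings.warn("state coefficient omega1 ~ 0: state not identified",
                      stacklevel=2)

    # Wald SE for the standardized state slope
    se_w1 = np.nan
    p_w1 = np.nan
    try:
        H = _hessian(_nll_and_grad, theta, ys, x1, x2)
        cov = np.linalg.inv(H)
        v = cov[1, 1]
        if v > 0:
            se_w1 = float(np.sqrt(v))
            from scipy import stats

            p_w1 = float(2.0 * stats.norm.sf(abs(w1) / se_w1))
    except np.linalg.LinAlgError:
        pass

    # map coefficients back to raw-variable scale
    omega1 = w1 / sy
    omega0 = w0 - w1 * my / sy
    a1 = a1s / s1
    a0 = a0s - a1s * m1 / s1
    b1 = b1s / s2
    b0 = b0s - b1s * m2 / s2

    z = w0 + w1 * ys
    al = a0s + a1s * x1
    be = b0s + b1s * x2
    per_year = []
    for t in range(n):
        delta = cardan_discriminant(al[t], be[t])
        per_year.append(
            CuspSurfacePoint(
                alpha=float(al[t]), beta=float(be[t]), z=float(z[t]),
                delta=float(delta), state_class=classify_state(al[t], be[t]),
                year=int(years[t]),
            )
        )
    n_bistable = sum(p.state_class == "bistable" for p in per_year)
    # log-likelihood on the raw state scale (subtract the standardization Jacobian)
    loglik = -float(best.fun) - n * np.log(sy)
    return CuspFit(
        state_var=state_var, asym_var=asym_var, bifur_var=bifur_var,
        omega0=float(omega0), omega1=float(omega1),
        a0=float(a0), a1=float(a1), b0=float(b0), b1=float(b1),
        loglik=loglik, converged=converged, per_year=tuple(per_year),
        n_bistable=int(n_bistable), aic=float(-2.0 * loglik + 2 * 6),
        se_omega1_std=float(se_w1), p_omega1=float(p_w1),
        _std={"my": my, "sy": sy, "m1": m1, "s1": s1, "m2": m2, "s2": s2,
              "theta_std": tuple(float(v) for v in theta)},
        _arrays={"y": y, "x1": x1r, "x2": x2r, "z": z, "alpha": al, "beta": be,
                 "years": np.asarray(years)},
    )


def predict_states(fit: CuspFit, convention: str = "nearest_mode") -> np.ndarray:
    """Per-year predicted state in observed units.

    ``nearest_mode`` (delay convention): the mode of the stationary density
    closest to the observed canonical state — the branch the system actually
    tracks under hysteresis.  ``expected_value``: the stationary mean.
    """
    if convention not in ("nearest_mode", "expected_value"):
        raise ValidationError(f"unknown prediction convention {convention!r}")
    if not fit.converged:
        raise ValidationError("cannot predict from a non-converged fit")
    z_pred = predict_canonical(fit, convention)
    w0, w1 = fit._std["theta_std"][:2]
    sy, my = fit._std["sy"], fit._std["my"]
    ys_pred = (z_pred - w0) / w1
    return ys_pred * sy + my


def predict_canonical(fit: CuspFit, convention: str = "nearest_mode") -> np.ndarray:
    al, be, z = fit._arrays["alpha"], fit._arrays["beta"], fit._arrays["z"]
    out = np.empty(len(z))
    for t in range(len(z)):
        if convention == "expected_value":
            out[t] = stationary_moments(float(al[t]), float(be[t]))[0]
        else:
            modes = stationary_modes(float(al[t]), float(be[t]))
            if not modes:  # degenerate flat top: fall back to the mean
                out[t] = stationary_moments(float(al[t]), float(be[t]))[0]
            else:
                out[t] = min(modes, key=lambda m: abs(m - z[t]))
    return out


def pseudo_r2(fit: CuspFit, convention: str = "nearest_mode") -> float:
    """Cobb-style pseudo-R^2: 1 - Var(z_obs - z_pred) / Var(z_obs)."""
    z = fit._arrays["z"]
    if float(np.var(z)) <= 0:
        raise ValidationError("zero variance in the canonical state")
    z_pred = predict_canonical(fit, convention)
    return float(1.0 - np.var(z - z_pred) / np.var(z))
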