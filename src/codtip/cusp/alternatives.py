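"""Alternative linear and logistic models for comparison with the cusp fit.

Both alternatives model the raw state directly from the two control
covariates with additive Gaussian error, so their AICs are on the same
(observed-state density) scale as the cusp likelihood:

    linear:    y = c0 + c1 x1 + c2 x2 + e,                  k = 4 (3 coef + sigma)
    logistic:  y = L / (1 + exp(-(c0 + c1 x1 + c2 x2))) + e, k = 5

AIC = -2 log L + 2k with the Gaussian log-likelihood at the variance MLE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize

from ..data_model import StockSeriesTable, resolve_variable


def gaussian_loglik(rss: float, n: int) -> float:
    """Gaussian log-likelihood at the variance MLE sigma^2 = RSS/n."""
    s2 = max(rss / n, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)


@dataclass(frozen=True)
class AlternativeFits:
    """Linear and logistic comparison fits with comparable AICs."""

    linear_params: tuple[float, float, float]
    linear_rss: float
    aic_linear: float
    logistic_params: tuple[float, float, float, float] | None
    logistic_rss: float | None
    aic_logistic: float | None
    logistic_converged: bool
    n: int

    def to_dict(self) -> dict:
        return {
            "linear": {"params": list(self.linear_params), "rss": self.linear_rss,
                       "aic": self.aic_linear},
            "logistic": {
                "params": None if self.logistic_params is None
                else list(self.logistic_params),
                "rss": self.logistic_rss,
                "aic": self.aic_logistic,
                "converged": self.logistic_converged,
            },
        }


def _fit_logistic(y: np.ndarray, x1: np.ndarray, x2: np.ndarray):
    """Nonlinear least squares for the scaled-logistic response surface.

    The saturation level L is bounded to the scale of the observed response
    range: without this the model is unidentified on near-linear data
    (L -> inf with c -> 0 reproduces any straight line), which makes L and
    the slopes meaningless as a sigmoid description.
    """
    span = float(np.max(y) - np.min(y))
    lo = float(np.min(y))
    span = max(span, 1e-9)

    def model(p, x1, x2):
        L, c0, c1, c2 = p
        return lo + L / (1.0 + np.exp(-np.clip(c0 + c1 * x1 + c2 * x2, -40, 40)))

    def resid(p):
        return model(p, x1, x2) - y

    bounds = ([0.1 * span, -np.inf, -np.inf, -np.inf],
              [2.0 * span, np.inf, np.inf, np.inf])
    best = None
    for c1_sign in (1.0, -1.0):
        p0 = np.array([span, 0.0, c1_sign, 0.0])
        try:
            res = optimize.least_squares(resid, p0, method="trf", bounds=bounds,
                                         max_nfev=2000)
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        return None
    rss = float(2.0 * best.cost)
    return tuple(float(v) for v in best.x), rss, bool(best.status > 0)


def fit_alternatives(
    table: StockSeriesTable,
    state_var: str = "ssb",
    asym_var: str = "scaled_pressure",
    bifur_var: str = "sst",
) -> AlternativeFits:
    """Fit the linear and logistic comparison models to three table columns."""
    y = table.column(resolve_variable(state_var))
    x1 = table.column(resolve_variable(asym_var))
    x2 = table.column(resolve_variable(bifur_var))
    return fit_alternatives_arrays(y, x1, x2)


def fit_alternatives_arrays(y, x1, x2) -> AlternativeFits:
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = len(y)

    X = sm.add_constant(np.column_stack([x1, x2]))
    ols = sm.OLS(y, X).fit()
    rss_lin = float(ols.ssr)
    aic_lin = -2.0 * gaussian_loglik(rss_lin, n) + 2 * 4

    logi = _fit_logistic(y, x1, x2)
    if logi is None:
        warnings.warn("logistic comparison model did not converge", stacklevel=2)
        params_log, rss_log, aic_log, conv = None, None, None, False
    else:
        params_log, rss_log, conv = logi
        aic_log = -2.0 * gaussian_loglik(rss_log, n) + 2 * 5
        if not conv:
            warnings.warn("logistic comparison model did not converge",
                          stacklevel=2)
    return AlternativeFits(
        linear_params=tuple(float(v) for v in ols.params),
        linear_rss=rss_lin,
        aic_linear=float(aic_lin),
        logistic_params=params_log,
        logistic_rss=rss_log,
        aic_logistic=None if aic_log is None else float(aic_log),
        logistic_converged=conv,
        n=n,
    )
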