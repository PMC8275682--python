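"""Multiple structural breaks in a bivariate linear relationship.

For a response ``y`` regressed on a covariate ``x`` (intercept + slope, both
shifting at each break), the optimal break positions for each break count
``m`` minimize the total residual sum of squares (RSS) over all admissible
partitions of the TIME-ordered observations.  The search is the classical
dynamic program over a triangular matrix of segment RSS values, computed
once from cumulative sums and shared across all ``m``.

The number of breaks is selected by BIC:

    BIC(m) = n * log(RSS_m / n) + (p*(m+1) + m) * log(n),      p = 2,

counting two regression coefficients per regime plus one parameter per break
position; ties go to the smaller ``m``.  As the evidence summary for the
selected model the fit reports delta-BIC against the no-break model (the
break test statistic used in the original analyses is not printed anywhere,
so no sup-F test is attempted).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .data_model import AnalysisConfig, StockSeriesTable, ValidationError, resolve_variable


@dataclass(frozen=True)
class RegimeFit:
    """OLS fit of one regime (rows between consecutive breaks)."""

    first_year: int
    last_year: int
    intercept: float
    slope: float
    rss: float


@dataclass(frozen=True)
class BreakpointFit:
    """Selected break positions and regime-wise coefficients for one pair."""

    response_name: str
    covariate_name: str
    break_years: tuple[int, ...]
    m: int
    regimes: tuple[RegimeFit, ...]
    rss: float
    ic_table: dict[int, float]
    min_segment: int
    delta_bic: float  # BIC(0) - BIC(chosen): evidence for the break structure

    @property
    def coefficients(self) -> tuple[tuple[float, float], ...]:
        return tuple((r.intercept, r.slope) for r in self.regimes)

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "covariate": self.covariate_name,
            "break_years": list(self.break_years),
            "m": self.m,
            "regimes": [
                {
                    "first_year": r.first_year,
                    "last_year": r.last_year,
                    "intercept": r.intercept,
                    "slope": r.slope,
                    "rss": r.rss,
                }
                for r in self.regimes
            ],
            "rss": self.rss,
            "bic_by_m": {str(k): v for k, v in sorted(self.ic_table.items())},
            "delta_bic": self.delta_bic,
            "min_segment": self.min_segment,
        }


def _segment_rss_matrix(y: np.ndarray, x: np.ndarray, min_segment: int) -> np.ndarray:
    """RSS of the OLS line fitted to rows [i, j) for every admissible segment.

    Entry [i, j] is +inf for inadmissible (too short) segments.  Constant
    covariate within a segment degrades to an intercept-only fit.
    """
    n = len(y)
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cyy = np.concatenate(([0.0], np.cumsum(y * y)))
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))
    rss = np.full((n + 1, n + 1), np.inf)
    scale_x = float(np.var(x)) if np.var(x) > 0 else 1.0
    degraded = False
    for i in range(n):
        for j in range(i + min_segment, n + 1):
            k = j - i
            sx = cx[j] - cx[i]
            sy = cy[j] - cy[i]
            sxx_c = (cxx[j] - cxx[i]) - sx * sx / k
            syy_c = (cyy[j] - cyy[i]) - sy * sy / k
            sxy_c = (cxy[j] - cxy[i]) - sx * sy / k
            if sxx_c <= 1e-12 * k * scale_x:
                degraded = True
                val = syy_c
            else:
                val = syy_c - sxy_c * sxy_c / sxx_c
            rss[i, j] = max(0.0, val)
    if degraded:
        warnings.warn(
            "constant covariate within a candidate regime: intercept-only fit used",
            stacklevel=3,
        )
    return rss


def dp_breakpoints(
    response: Sequence[float],
    covariate: Sequence[float],
    max_breaks: int,
    min_segment: int,
) -> dict[int, tuple[tuple[int, ...], float]]:
    """Optimal break sets for every m = 0..max_breaks.

    Returns ``{m: (break_indices, rss)}`` where break indices are 0-based
    positions of the first observation of each NEW regime (so a break at
    index ``b`` separates rows ``[.., b-1]`` from ``[b, ..]``).
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("response and covariate must be aligned 1-d series")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(x)):
        raise ValidationError("non-finite values in regression series")
    n = len(y)
    if min_segment < 2:
        raise ValidationError("min_segment must be >= 2 (OLS needs 2 points)")
    if max_breaks < 0 or (max_breaks + 1) * min_segment > n:
        raise ValidationError(
            f"infeasible: {max_breaks} breaks with min_segment={min_segment} on n={n}")

    seg = _segment_rss_matrix(y, x, min_segment)

    # best[k][j]: min RSS of partitioning rows [0, j) into k segments
    kmax = max_breaks + 1
    best = np.full((kmax + 1, n + 1), np.inf)
    arg = np.full((kmax + 1, n + 1), -1, dtype=int)
    best[1] = seg[0]
    for k in range(2, kmax + 1):
        for j in range(k * min_segment, n + 1):
            lo, hi = (k - 1) * min_segment, j - min_segment
            vals = best[k - 1, lo: hi + 1] + seg[lo: hi + 1, j]
            s = int(np.argmin(vals))  # first minimizer -> earliest positions
            best[k, j] = vals[s]
            arg[k, j] = lo + s

    out: dict[int, tuple[tuple[int, ...], float]] = {}
    for m in range(0, max_breaks + 1):
        k = m + 1
        if not np.isfinite(best[k, n]):
            continue
        breaks = []
        j, kk = n, k
        while kk > 1:
            s = arg[kk, j]
            breaks.append(int(s))
            j, kk = s, kk - 1
        out[m] = (tuple(sorted(breaks)), float(best[k, n]))
    return out


def exhaustive_breakpoints(
    response: Sequence[float],
    covariate: Sequence[float],
    max_breaks: int,
    min_segment: int,
) -> dict[int, tuple[tuple[int, ...], float]]:
    """Enumeration oracle: every admissible break set for each m (tests only)."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(covariate, dtype=float)
    n = len(y)
    if n > 60 or max_breaks > 3:
        raise ValidationError("enumeration oracle refused: n <= 60 and m <= 3 only")
    seg = _segment_rss_matrix(y, x, min_segment)
    out: dict[int, tuple[tuple[int, ...], float]] = {}
    positions = range(min_segment, n - min_segment + 1)
    for m in range(0, max_breaks + 1):
        best_rss, best_breaks = np.inf, None
        for combo in combinations(positions, m):
            bounds = (0,) + combo + (n,)
            if any(b - a < min_segment for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            total = sum(seg[a, b] for a, b in zip(bounds[:-1], bounds[1:]))
            if best_breaks is None or total < best_rss - 1e-12 * max(1.0, best_rss):
                best_rss, best_breaks = total, combo
        if best_breaks is not None:
            out[m] = (best_breaks, float(best_rss))
    return out


def bic_for_breaks(rss: float, m: int, n: int, p: int = 2) -> float:
    """BIC(m) = n log(RSS/n) + (p(m+1) + m) log n, with an RSS floor for
    numerically perfect fits."""
    floor = 1e-12 * n
    return n * math.log(max(rss, floor) / n) + (p * (m + 1) + m) * math.log(n)


def select_num_breaks(
    per_m_results: dict[int, tuple[tuple[int, ...], float]], n: int, p: int = 2
) -> tuple[int, dict[int, float]]:
    """Choose m minimizing BIC; ties resolved toward smaller m."""
    if not per_m_results:
        raise ValidationError("no candidate break fits")
    ic = {m: bic_for_breaks(rss, m, n, p) for m, (_, rss) in per_m_results.items()}
    best_m = min(sorted(ic), key=lambda m: (round(ic[m], 9), m))
    return best_m, ic


def _regime_fits(
    y: np.ndarray, x: np.ndarray, years: np.ndarray, breaks: tuple[int, ...]
) -> tuple[RegimeFit, ...]:
    bounds = (0,) + breaks + (len(y),)
    regimes = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        xs, ys = x[a:b], y[a:b]
        if np.var(xs) <= 1e-12 * max(1.0, float(np.var(x))):
            intercept, slope = float(np.mean(ys)), 0.0
            rss = float(np.sum((ys - intercept) ** 2))
        else:
            res = sm.OLS(ys, sm.add_constant(xs)).fit()
            intercept, slope = float(res.params[0]), float(res.params[1])
            rss = float(res.ssr)
        regimes.append(
            RegimeFit(
                first_year=int(years[a]),
                last_year=int(years[b - 1]),
                intercept=intercept,
                slope=slope,
                rss=rss,
            )
        )
    return tuple(regimes)


def fit_breakpoints(
    response: Sequence[float],
    covariate: Sequence[float],
    years: Sequence[int] | None = None,
    max_breaks: int = 5,
    min_segment: int | None = None,
    response_name: str = "y",
    covariate_name: str = "x",
) -> BreakpointFit:
    """Full break analysis of one response~covariate pair."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(covariate, dtype=float)
    n = len(y)
    years_arr = np.arange(n) if years is None else np.asarray(years)
    if min_segment is None:
        min_segment = max(2, math.ceil(0.15 * n))
    max_breaks = min(max_breaks, n // min_segment - 1)
    per_m = dp_breakpoints(y, x, max_breaks, min_segment)
    chosen, ic = select_num_breaks(per_m, n)
    breaks, rss = per_m[chosen]
    regimes = _regime_fits(y, x, years_arr, breaks)
    return BreakpointFit(
        response_name=response_name,
        covariate_name=covariate_name,
        break_years=tuple(int(years_arr[b - 1]) for b in breaks),
        m=chosen,
        regimes=regimes,
        rss=float(rss),
        ic_table=ic,
        min_segment=min_segment,
        delta_bic=float(ic[0] - ic[chosen]),
    )


def fit_relationships(
    table: StockSeriesTable, config: AnalysisConfig | None = None
) -> list[BreakpointFit]:
    """Break analysis of every configured response~covariate relationship.

    Defaults to the six pairs SSB~F, SSB~F/R, R~SSB, R~SST, R/SSB~SSB and
    R/SSB~SST.
    """
    config = config or AnalysisConfig()
    fits = []
    for resp, cov in config.relationships:
        resp_c, cov_c = resolve_variable(resp), resolve_variable(cov)
        fits.append(
            fit_breakpoints(
                table.column(resp_c),
                table.column(cov_c),
                years=table.years,
                max_breaks=config.max_breaks,
                min_segment=config.breakpoint_min_segment(table.n),
                response_name=resp_c,
                covariate_name=cov_c,
            )
        )
    return fits
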