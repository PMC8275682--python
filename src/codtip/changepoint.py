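"""Multiple mean-changepoints in a single series by penalized exact search.

The detector is PELT (Pruned Exact Linear Time): a dynamic program over
segmentation end points that returns the exact global minimizer of

    sum over segments of C(segment)  +  m * penalty,

where ``m`` is the number of changepoints and the segment cost ``C`` is the
Gaussian twice-negative-log-likelihood of the segment under its own mean and
a common variance:

    C(x[i:j]) = sum (x_t - mean(x[i:j]))^2 / sigma2.

The common variance ``sigma2`` is estimated from first differences of the
whole series (half the variance of the differences), which is robust to mean
shifts; holding it common across segments prevents variance changes from
masquerading as mean changes.

An exhaustive enumeration oracle (:func:`exhaustive_segmentation`) is
provided for testing: it searches every admissible segmentation and must
agree with PELT exactly.

Position convention: a changepoint is reported as the calendar year of the
LAST observation of the closing segment.  Ties in penalized cost are broken
toward fewer changepoints, then lexicographically earliest positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data_model import ValidationError

#: relative tolerance used when comparing penalized costs for tie-breaking
_COST_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class Segmentation:
    """Optimal segmentation of one series into constant-mean regimes."""

    series_name: str
    changepoint_years: tuple[int, ...]
    m: int
    segment_means: tuple[float, ...]
    total_cost: float
    penalty: float
    min_segment_length: int
    #: internal 0-based end indices of each segment except the last (= changepoints)
    changepoint_indices: tuple[int, ...] = field(default=(), repr=False)

    def to_dict(self) -> dict:
        return {
            "series_name": self.series_name,
            "penalty": self.penalty,
            "changepoint_years": list(self.changepoint_years),
            "m": self.m,
            "segment_means": list(self.segment_means),
            "cost": self.total_cost,
            "min_segment_length": self.min_segment_length,
        }


def diff_variance(series: Sequence[float]) -> float:
    """Common-variance estimate: var of first differences / 2 (shift-robust)."""
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise ValidationError("need at least 3 observations to estimate variance")
    v = float(np.var(np.diff(x), ddof=1)) / 2.0
    if v <= 0.0:
        # constant series: any positive value gives zero cost everywhere
        return 1.0
    return v


def aic_penalty(series: Sequence[float] | None = None, k: int = 2) -> float:
    """AIC penalty per changepoint: 2*k.

    Each changepoint introduces ``k`` parameters — one segment mean plus the
    changepoint position itself — so the default is ``2 * 2 = 4``.  The
    penalty does not depend on the data values.
    """
    if series is not None and len(series) < 3:
        raise ValidationError("series too short for a penalty estimate")
    return 2.0 * float(k)


def _validate_series(series: Sequence[float], min_segment_length: int) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("series must be one-dimensional")
    if np.any(~np.isfinite(x)):
        raise ValidationError("series contains non-finite values")
    if min_segment_length < 1:
        raise ValidationError("min_segment_length must be >= 1")
    if len(x) < min_segment_length:
        raise ValidationError("no admissible segmentation: series shorter than "
                              f"min_segment_length={min_segment_length}")
    return x


def _cost_fn(x: np.ndarray, variance: float) -> Callable[[int, int], float]:
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def cost(i: int, j: int) -> float:
        n = j - i
        return max(0.0, (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / n) / variance

    return cost

def _better(cand: tuple[float, int, tuple[int, ...]],
            best: tuple[float, int, tuple[int, ...]] | None) -> bool:
    """Tie-aware comparison: lower cost, then fewer changepoints, then
    lexicographically earliest positions."""
    if best is None:
        return True
    tol = _COST_TIE_RTOL * max(1.0, abs(best[0]), abs(cand[0]))
    if cand[0] < best[0] - tol:
        return True
    if cand[0] > best[0] + tol:
        return False
    return (cand[1], cand[2]) < (best[1], best[2])


def _finalize(x: np.ndarray, cps: tuple[int, ...], cost, penalty: float,
              min_segment_length: int, series_name: str,
              years: Sequence[int] | None) -> Segmentation:
    bounds = (0,) + cps + (len(x),)
    means = tuple(float(np.mean(x[a:b])) for a, b in zip(bounds[:-1], bounds[1:]))
    total = sum(cost(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
    total += penalty * len(cps)
    if years is None:
        years_arr = np.arange(len(x))
    else:
        years_arr = np.asarray(years)
    cp_years = tuple(int(years_arr[c - 1]) for c in cps)
    return Segmentation(
        series_name=series_name,
        changepoint_years=cp_years,
        m=len(cps),
        segment_means=means,
        total_cost=float(total),
        penalty=float(penalty),
        min_segment_length=min_segment_length,
        changepoint_indices=cps,
    )


def pelt_mean(
    series: Sequence[float],
    penalty: float | None = None,
    min_segment_length: int = 10,
    years: Sequence[int] | None = None,
    variance: float | None = None,
    series_name: str = "series",
) -> Segmentation:
    """Exact penalized changepoint detection in the mean by PELT.

    Parameters
    ----------
    series
        Ordered observations (one per year).
    penalty
        Cost added per changepoint; default :func:`aic_penalty` (= 4).
    min_segment_length
        Shortest admissible regime, in observations (default 10 years).
    years
        Calendar-year labels; defaults to 0-based positions.
    variance
        Common variance of the Gaussian cost; default
        :func:`diff_variance` of the series.
    """
    x = _validate_series(series, min_segment_length)
    n = len(x)
    if penalty is None:
        penalty = aic_penalty(x)
    if penalty < 0:
        raise ValidationError("penalty must be nonnegative")
    if variance is None:
        variance = diff_variance(x) if n >= 3 else 1.0
    cost = _cost_fn(x, variance)
    L = min_segment_length

    # F[t]: best penalized cost of x[0:t]; state carries (cost, m, cps)
    state: list[tuple[float, int, tuple[int, ...]] | None] = [None] * (n + 1)
    state[0] = (-penalty, 0, ())
    candidates = [0]
    # PELT pruning with K = 0: once F[s] + C(s, t) > F[t], point t dominates
    # s — but only from t + L onward, because t itself is inadmissible as a
    # segment start until the minimum segment length has elapsed.
    pruned_at: dict[int, int] = {}
    for t in range(L, n + 1):
        best: tuple[float, int, tuple[int, ...]] | None = None
        active = []
        for s in candidates:
            pa = pruned_at.get(s)
            if pa is not None and t >= pa + L:
                continue  # dominated and the dominator is now admissible
            active.append(s)
            if t - s < L:
                continue
            fs = state[s]
            assert fs is not None
            cand = (fs[0] + cost(s, t) + penalty,
                    fs[1] + (1 if s > 0 else 0),
                    fs[2] + ((s,) if s > 0 else ()))
            if _better(cand, best):
                best = cand
        assert best is not None
        state[t] = best
        candidates = active
        for s in candidates:
            if s not in pruned_at and state[s][0] + cost(s, t) > best[0]:
                pruned_at[s] = t
        candidates.append(t)

    final = state[n]
    assert final is not None
    return _finalize(x, final[2], cost, penalty, L, series_name, years)


def exhaustive_segmentation(
    series: Sequence[float],
    penalty: float | None = None,
    min_segment_length: int = 10,
    max_m: int | None = None,
    years: Sequence[int] | None = None,
    variance: float | None = None,
    series_name: str = "series",
    max_enumerations: int = 5_000_000,
) -> Segmentation:
    """Exact global minimizer by enumeration of every admissible segmentation.

    Test oracle only: refuses instances that are too large to enumerate
    (guard: n <= 60 or max_m <= 3, and an explicit count bound).
    """
    x = _validate_series(series, min_segment_length)
    n = len(x)
    if not (n <= 60 or (max_m is not None and max_m <= 3)):
        raise ValidationError(
            "exhaustive_segmentation refused: require n <= 60 or max_m <= 3")
    if penalty is None:
        penalty = aic_penalty(x)
    if variance is None:
        variance = diff_variance(x) if n >= 3 else 1.0
    cost = _cost_fn(x, variance)
    L = min_segment_length

    # count admissible segmentations before enumerating
    counts = np.zeros(n + 1, dtype=float)
    counts[0] = 1.0
    for t in range(L, n + 1):
        counts[t] = counts[0 : t - L + 1].sum()
    if counts[n] > max_enumerations:
        raise ValidationError(
            f"exhaustive_segmentation refused: ~{counts[n]:.3g} segmentations")

    best: tuple[float, int, tuple[int, ...]] | None = None

    def search(start: int, cps: tuple[int, ...], acc: float) -> None:
        nonlocal best
        if n - start >= L:
            cand = (acc + cost(start, n), len(cps), cps)
            if _better(cand, best):
                best = cand
        if max_m is not None and len(cps) >= max_m:
            return
        for end in range(start + L, n - L + 1):
            search(end, cps + (end,), acc + cost(start, end) + penalty)

    search(0, (), 0.0)
    if best is None:
        raise ValidationError("no admissible segmentation")
    return _finalize(x, best[2], cost, penalty, L, series_name, years)
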