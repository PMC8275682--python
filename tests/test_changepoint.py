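import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codtip.changepoint import (
    aic_penalty,
    diff_variance,
    exhaustive_segmentation,
    pelt_mean,
)
from codtip.data_model import ValidationError


def test_constant_series_has_no_changepoint():
    seg = pelt_mean(np.ones(30), penalty=1.0, min_segment_length=2)
    assert seg.m == 0
    assert seg.changepoint_years == ()


def test_single_planted_shift_found_at_tenth_position():
    # frozen from the exhaustive oracle on this 20-point instance
    x = np.r_[np.zeros(10), np.full(10, 8.0)]
    seg = pelt_mean(x, penalty=2.0, min_segment_length=2, variance=1.0)
    assert seg.changepoint_indices == (10,)
    assert seg.segment_means == (0.0, 8.0)
    oracle = exhaustive_segmentation(x, penalty=2.0, min_segment_length=2,
                                     variance=1.0)
    assert oracle.changepoint_indices == (10,)


def test_huge_penalty_forces_single_segment():
    rng = np.random.default_rng(0)
    x = np.r_[rng.normal(0, 1, 15), rng.normal(9, 1, 15)]
    unsegmented_cost = np.sum((x - x.mean()) ** 2) / diff_variance(x)
    seg = pelt_mean(x, penalty=unsegmented_cost + 1.0, min_segment_length=2)
    assert seg.m == 0


def test_changepoint_year_is_last_year_of_closing_segment():
    x = np.r_[np.zeros(12), np.full(12, 5.0)]
    years = np.arange(1990, 1990 + 24)
    seg = pelt_mean(x, penalty=4.0, min_segment_length=10, years=years,
                    variance=1.0)
    assert seg.changepoint_years == (2001,)


def test_total_cost_is_segment_costs_plus_penalty():
    rng = np.random.default_rng(3)
    x = np.r_[rng.normal(0, 1, 12), rng.normal(6, 1, 12)]
    seg = pelt_mean(x, penalty=4.0, min_segment_length=5)
    var = diff_variance(x)
    bounds = (0,) + seg.changepoint_indices + (len(x),)
    cost = sum(np.sum((x[a:b] - x[a:b].mean()) ** 2) / var
               for a, b in zip(bounds[:-1], bounds[1:]))
    assert seg.total_cost == pytest.approx(cost + 4.0 * seg.m)
    assert all(b - a >= 5 for a, b in zip(bounds[:-1], bounds[1:]))


def test_aic_penalty_convention():
    assert aic_penalty(np.arange(10.0)) == 4.0
    assert aic_penalty(np.arange(10.0) * 100) == 4.0  # data-independent
    assert aic_penalty(k=3) == 6.0
    with pytest.raises(ValidationError):
        aic_penalty([1.0, 2.0])


def test_short_series_and_nonfinite_rejected():
    with pytest.raises(ValidationError, match="no admissible"):
        pelt_mean(np.ones(5), penalty=1.0, min_segment_length=10)
    with pytest.raises(ValidationError, match="non-finite"):
        pelt_mean(np.array([1.0, np.nan, 2.0, 3.0]), penalty=1.0,
                  min_segment_length=2)


def test_exhaustive_guard_refuses_large_unbounded_instances():
    with pytest.raises(ValidationError, match="refused"):
        exhaustive_segmentation(np.random.default_rng(0).normal(size=80),
                                penalty=1.0, min_segment_length=3)


def test_exhaustive_minimal_instance_combinatorics():
    # n=4, L=2: only {no split, split at 2} are admissible
    x = np.array([0.0, 0.0, 4.0, 4.0])
    seg = exhaustive_segmentation(x, penalty=0.5, min_segment_length=2,
                                  variance=1.0)
    assert seg.changepoint_indices == (2,)
    seg2 = exhaustive_segmentation(x, penalty=1e6, min_segment_length=2,
                                   variance=1.0)
    assert seg2.changepoint_indices == ()


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_pelt_equals_exhaustive_on_random_instances(seed):
    """Exact-oracle equivalence on random planted-shift series."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 41))
    L = int(rng.integers(5, 9))
    x = rng.normal(size=n)
    if rng.uniform() < 0.7:
        p = int(rng.integers(L, n - L + 1))
        x[p:] += rng.uniform(1.0, 6.0)
    pen = float(rng.uniform(1.0, 8.0))
    a = pelt_mean(x, penalty=pen, min_segment_length=L)
    b = exhaustive_segmentation(x, penalty=pen, min_segment_length=L)
    assert a.changepoint_indices == b.changepoint_indices
    assert a.total_cost == pytest.approx(b.total_cost, rel=1e-9)


def test_number_of_changepoints_nonincreasing_in_penalty():
    rng = np.random.default_rng(11)
    x = np.concatenate([rng.normal(m, 1.0, 12) for m in (0, 5, -3, 4)])
    ms = [pelt_mean(x, penalty=p, min_segment_length=5).m
          for p in (0.5, 1, 2, 4, 8, 16, 32, 64, 128)]
    assert all(b <= a for a, b in zip(ms[:-1], ms[1:]))
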