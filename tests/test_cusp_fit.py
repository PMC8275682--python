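import numpy as np
import pytest

from codtip.cusp import (
    fit_alternatives,
    fit_cusp,
    predict_states,
    pseudo_r2,
    validate_cusp,
)
from codtip.cusp.alternatives import fit_alternatives_arrays, gaussian_loglik
from codtip.cusp.fitting import fit_cusp_arrays, predict_canonical
from codtip.data_model import StockSeriesTable, ValidationError
from codtip.synthetic_data import CuspSimSpec, sample_cusp_series


@pytest.fixture(scope="module")
def bistable_sim():
    """One simulated dataset from the cusp model spanning both regions."""
    rng = np.random.default_rng(5)
    n = 400
    x1 = rng.uniform(-1.5, 1.5, n)
    x2 = rng.uniform(-1.0, 2.0, n)
    spec = CuspSimSpec(omega0=0.2, omega1=1.1, a0=0.4, a1=1.2, b0=0.6, b1=1.5,
                       asym_series=tuple(x1), bifur_series=tuple(x2), n=n,
                       seed=42)
    return sample_cusp_series(spec)


@pytest.fixture(scope="module")
def bistable_fit(bistable_sim):
    return fit_cusp_arrays(bistable_sim["state"], bistable_sim["asym"],
                           bistable_sim["bifur"])


def test_fit_recovers_generating_coefficients(bistable_sim, bistable_fit):
    fit = bistable_fit
    assert fit.converged
    truth = {"omega0": 0.2, "omega1": 1.1, "a0": 0.4, "a1": 1.2,
             "b0": 0.6, "b1": 1.5}
    for k, v in truth.items():
        assert getattr(fit, k) == pytest.approx(v, abs=0.35)
    # state coefficient clearly significant on model data
    assert fit.p_omega1 < 0.01


def test_per_year_surface_is_consistent(bistable_fit):
    fit = bistable_fit
    assert len(fit.per_year) == 400
    assert fit.n_bistable == sum(
        p.state_class == "bistable" for p in fit.per_year)
    for p in fit.per_year[::37]:
        assert p.delta == pytest.approx(27 * p.alpha**2 - 4 * p.beta**3,
                                        rel=1e-9, abs=1e-12)


def test_row_permutation_leaves_fit_unchanged(bistable_sim):
    y, x1, x2 = (bistable_sim["state"], bistable_sim["asym"],
                 bistable_sim["bifur"])
    fit = fit_cusp_arrays(y[:60], x1[:60], x2[:60])
    perm = np.random.default_rng(0).permutation(60)
    fit_p = fit_cusp_arrays(y[:60][perm], x1[:60][perm], x2[:60][perm])
    assert fit_p.loglik == pytest.approx(fit.loglik, rel=1e-6)
    assert fit_p.omega1 == pytest.approx(fit.omega1, rel=1e-3)


def test_affine_covariate_rescaling_leaves_classification_unchanged(bistable_sim):
    y, x1, x2 = (bistable_sim["state"], bistable_sim["asym"],
                 bistable_sim["bifur"])
    a = fit_cusp_arrays(y, x1, x2)
    b = fit_cusp_arrays(y, 10.0 * x1 - 3.0, 0.2 * x2 + 5.0)
    cls_a = [p.state_class for p in a.per_year]
    cls_b = [p.state_class for p in b.per_year]
    assert np.mean([u == v for u, v in zip(cls_a, cls_b)]) > 0.99
    assert b.pct_in_cusp == pytest.approx(a.pct_in_cusp, abs=1.0)


def test_too_few_observations_rejected(tipping_table):
    import pandas as pd

    small = StockSeriesTable(tipping_table.data.iloc[:10][
        ["year", "ssb", "recruitment", "f", "sst"]].copy())
    with pytest.raises(ValidationError, match="observations"):
        fit_cusp(small)


def test_prediction_conventions(bistable_fit):
    near = predict_canonical(bistable_fit, "nearest_mode")
    expv = predict_canonical(bistable_fit, "expected_value")
    mono = [p.state_class == "stable" for p in bistable_fit.per_year]
    # in clearly monostable years both conventions approximately agree
    deltas = np.array([p.delta for p in bistable_fit.per_year])
    strong = list(np.argsort(deltas)[-20:])  # deepest single-well years
    assert deltas[strong].min() > 0
    assert np.allclose(near[strong], expv[strong], atol=0.4)
    with pytest.raises(ValidationError, match="convention"):
        predict_states(bistable_fit, "mode_of_the_mean")
    # observed-units prediction inverts the state map
    pred = predict_states(bistable_fit, "nearest_mode")
    assert pred.shape == (bistable_fit.n,)
    assert mono  # used above


def test_pseudo_r2_limits(bistable_fit):
    r2 = pseudo_r2(bistable_fit, "nearest_mode")
    assert 0.0 < r2 <= 1.0
    # nearest-mode prediction on model data explains most variance
    assert r2 > 0.5


def test_near_linear_stable_region_matches_ols():
    """Deep in the stable region the cusp response is continuous and close
    to linear; its predictions should track the OLS line."""
    rng = np.random.default_rng(8)
    n = 300
    x1 = rng.uniform(-1.0, 1.0, n)
    x2 = rng.uniform(-1.6, -1.4, n)  # beta ~ -1.5: single well everywhere
    spec = CuspSimSpec(omega0=0.0, omega1=1.0, a0=0.0, a1=1.5, b0=0.0, b1=1.0,
                       asym_series=tuple(x1), bifur_series=tuple(x2), n=n,
                       seed=3)
    sim = sample_cusp_series(spec)
    fit = fit_cusp_arrays(sim["state"], sim["asym"], sim["bifur"])
    pred = predict_states(fit, "expected_value")
    X = np.column_stack([np.ones(n), x1])
    coef, *_ = np.linalg.lstsq(X, sim["state"], rcond=None)
    ols_pred = X @ coef
    # cusp prediction correlates almost perfectly with the OLS line
    assert np.corrcoef(pred, ols_pred)[0, 1] > 0.98
    rms = np.sqrt(np.mean((pred - ols_pred) ** 2))
    assert rms < 0.5 * np.std(sim["state"])


def test_linear_aic_matches_closed_form():
    rng = np.random.default_rng(1)
    n = 80
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    y = 1.0 + 0.5 * x1 - 0.2 * x2 + rng.normal(0, 0.3, n)
    alts = fit_alternatives_arrays(y, x1, x2)
    assert alts.aic_linear == pytest.approx(
        -2.0 * gaussian_loglik(alts.linear_rss, n) + 8.0)
    # logistic with a flat surface reduces to an intercept-like fit
    flat = fit_alternatives_arrays(np.full(n, 2.0) + rng.normal(0, .01, n), x1, x2)
    assert flat.aic_logistic is not None


def test_validation_report_on_model_data(bistable_fit, bistable_sim):
    alts = fit_alternatives_arrays(bistable_sim["state"], bistable_sim["asym"],
                                   bistable_sim["bifur"])
    rep = validate_cusp(bistable_fit, alts, seed=0)
    assert rep.verdict == "valid"
    assert rep.omega1_significant
    assert 0 < rep.pct_in_cusp <= 100
    assert rep.aic_cusp < rep.aic_linear
    assert rep.bimodality_assessable  # plenty of bistable years at n=400
    d = rep.to_dict()
    assert d["verdict"] == "valid"


def test_all_years_stable_gives_not_valid_verdict():
    rng = np.random.default_rng(10)
    n = 120
    x1 = rng.uniform(-0.5, 0.5, n)
    x2 = rng.uniform(-2.2, -1.8, n)
    spec = CuspSimSpec(a1=1.0, b1=1.0, asym_series=tuple(x1),
                       bifur_series=tuple(x2), n=n, seed=4)
    sim = sample_cusp_series(spec)
    fit = fit_cusp_arrays(sim["state"], sim["asym"], sim["bifur"])
    if fit.n_bistable == 0:  # the designed outcome for beta = -2 everywhere
        alts = fit_alternatives_arrays(sim["state"], sim["asym"], sim["bifur"])
        rep = validate_cusp(fit, alts, seed=0)
        assert rep.pct_in_cusp == 0.0
        assert rep.verdict == "not valid"
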