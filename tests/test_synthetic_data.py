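import numpy as np
import pytest
from scipy import stats

from codtip.changepoint import aic_penalty, pelt_mean
from codtip.cusp.density import integration_radius, stationary_density
from codtip.data_model import ValidationError
from codtip.synthetic_data import (
    CuspSimSpec,
    RegimeSpec,
    make_tipping_fixture,
    sample_cusp_series,
    sample_cusp_stationary,
    simulate_cusp_sde,
    simulate_regime_series,
)


def test_zero_noise_series_equals_regime_means():
    spec = RegimeSpec(noise_sd_per_variable={"ssb": 0, "recruitment": 0, "f": 0},
                      sst_noise_sd=0.0)
    t = simulate_regime_series(spec)
    idx = spec.regime_index()
    for var in ("ssb", "recruitment", "f"):
        expect = np.asarray(spec.means_per_variable[var])[idx]
        assert np.allclose(t.column(var), expect)


def test_same_seed_same_table():
    a = simulate_regime_series(RegimeSpec(seed=11))
    b = simulate_regime_series(RegimeSpec(seed=11))
    assert a.data.equals(b.data)
    assert not a.data.equals(simulate_regime_series(RegimeSpec(seed=12)).data)


def test_short_regime_rejected():
    with pytest.raises(ValidationError, match="minimum segment"):
        RegimeSpec(boundaries=(1970, 1975, 1995, 2008))


def test_pelt_recovers_default_regime_boundaries():
    hits = 0
    planted = [1982, 1994, 2007]  # last year of each closing regime
    for s in range(40):
        t = simulate_regime_series(RegimeSpec(seed=s))
        seg = pelt_mean(t.ssb, penalty=aic_penalty(t.ssb),
                        min_segment_length=10, years=t.years)
        found = seg.changepoint_years
        hits += int(len(found) == 3 and all(
            min(abs(f - p) for f in found) <= 1 for p in planted))
    assert hits >= 38  # >= 95%


def test_stationary_sampler_symmetry_and_single_well():
    s = sample_cusp_stationary(0.0, 3.0, n=100_000, seed=1)
    assert abs(s.mean()) < 3 * s.std() / np.sqrt(len(s))
    s5 = sample_cusp_stationary(5.0, 0.0, n=50_000, seed=2)
    # single equilibrium at the real root of z^3 = 5 (bisection oracle)
    lo, hi = 0.0, 3.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if mid**3 < 5 else (lo, mid)
    hist, edges = np.histogram(s5, bins=120)
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    assert abs(mode - lo) < 0.1


def test_stationary_sampler_matches_quadrature_density():
    alpha, beta = 0.0, 3.0
    s = sample_cusp_stationary(alpha, beta, n=100_000, seed=3)
    r = integration_radius(alpha, beta)
    zg = np.linspace(-r, r, 4001)
    pdf = stationary_density(zg, alpha, beta)
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(zg))))
    cdf /= cdf[-1]
    res = stats.ks_1samp(s, lambda v: np.interp(v, zg, cdf))
    assert res.pvalue > 0.01


def test_sde_deterministic_limit_decays_to_zero():
    traj = simulate_cusp_sde(0.0, -2.0, sigma_z=1e-12, dt=1e-3,
                             n_steps=20_000, z0=1.0, seed=0)[:, 0]
    assert np.all(np.diff(traj) <= 1e-12)  # monotone decay
    assert abs(traj[-1]) < 1e-3


def test_sde_symmetric_double_well_occupancy():
    traj = simulate_cusp_sde(0.0, 3.0, sigma_z=np.sqrt(2.0), dt=1e-3,
                             n_steps=60_000, z0=0.0, seed=5, n_chains=64)
    frac = (traj[10_000:] > 0).mean()
    assert 0.4 < frac < 0.6


def test_sde_diverges_with_large_step():
    with pytest.raises(ValidationError, match="dt"):
        simulate_cusp_sde(0.0, 0.0, sigma_z=1.0, dt=5.0, n_steps=200,
                          z0=3.0, seed=0)


def test_sde_and_stationary_sampler_agree_in_distribution():
    alpha, beta = 0.4, 1.2
    traj = simulate_cusp_sde(alpha, beta, sigma_z=np.sqrt(2.0), dt=1e-3,
                             n_steps=40_000, z0=0.0, seed=6, n_chains=256)
    sde_draws = traj[-1]
    iid = sample_cusp_stationary(alpha, beta, n=10_000, seed=7)
    res = stats.ks_2samp(sde_draws, iid)
    assert res.pvalue > 0.01


def test_cusp_sim_spec_validation():
    with pytest.raises(ValidationError):
        CuspSimSpec(n=0)
    with pytest.raises(ValidationError):
        CuspSimSpec(sigma_z=0.0)
    with pytest.raises(ValidationError):
        CuspSimSpec(dt=-1.0)
    with pytest.raises(ValidationError, match="length n"):
        sample_cusp_series(CuspSimSpec(n=3, asym_series=(0.0,),
                                       bifur_series=(0.0, 0.0, 0.0)))


def test_tipping_fixture_determinism_and_f_regime(tipping_table, tmp_path):
    again = make_tipping_fixture(seed=7)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    tipping_table.to_csv(p1)
    again.to_csv(p2)
    assert p1.read_bytes() == p2.read_bytes()
    # collapse-regime F mostly above 1/yr
    sub = tipping_table.data.query("1986 <= year <= 1995")
    assert (sub["f"] > 1.0).mean() >= 0.8
    # SST trends upward
    sst = tipping_table.sst
    assert np.polyfit(np.arange(len(sst)), sst, 1)[0] > 0
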