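import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize

from codtip.cusp import (
    bifurcation_set,
    cardan_discriminant,
    classify_state,
    dip_pvalue,
    dip_statistic,
    equilibria,
    log_partition,
    potential,
    stationary_density,
    stationary_modes,
    stationary_moments,
)
from codtip.cusp.density import integration_radius
from codtip.data_model import ValidationError


# ---------------------------------------------------------------- geometry

def test_potential_analytic_cases():
    assert potential(0.0, 1.7, -2.3) == 0.0
    z = np.linspace(-2, 2, 401)
    assert np.argmin(potential(z, 0.0, 0.0)) == 200  # single well at 0
    v = potential(z, 0.0, 3.0)
    # minima at +/- sqrt(3), local max at 0
    assert potential(np.sqrt(3), 0.0, 3.0) == pytest.approx(-9 / 4)
    assert v[200] > potential(np.sqrt(3), 0.0, 3.0)


def test_equilibria_analytic_cases():
    eq = equilibria(0.0, 3.0)
    zs = [z for z, _ in eq]
    labels = [l for _, l in eq]
    assert zs == pytest.approx([-np.sqrt(3), 0.0, np.sqrt(3)], abs=1e-9)
    assert labels == ["stable", "unstable", "stable"]

    eq = equilibria(2.0, 3.0)  # (z - 2)(z + 1)^2
    assert len(eq) == 2
    assert eq[0][0] == pytest.approx(-1.0, abs=1e-6)
    assert eq[0][1] == "degenerate"
    assert eq[1][0] == pytest.approx(2.0, abs=1e-9)
    assert eq[1][1] == "stable"

    eq = equilibria(1.0, 0.0)
    assert len(eq) == 1
    assert eq[0] == (pytest.approx(1.0), "stable")


def test_discriminant_and_classification():
    assert cardan_discriminant(0.0, 0.0) == 0.0
    assert cardan_discriminant(0.0, 3.0) == -108.0
    assert len(equilibria(0.0, 3.0)) == 3
    assert classify_state(0.0, 3.0) == "bistable"
    assert classify_state(2.0, -1.0) == "stable"
    assert classify_state(0.0, 0.0) == "boundary"


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.floats(-3, 3), st.floats(-3, 3))
def test_discriminant_sign_matches_root_count(alpha, beta):
    d = cardan_discriminant(alpha, beta)
    if abs(d) < 1e-6 * max(1.0, abs(27 * alpha**2), abs(4 * beta**3)):
        return  # on the fold curve the count is ambiguous numerically
    roots = np.roots([1.0, 0.0, -beta, -alpha])
    n_real = int(np.sum(np.abs(roots.imag) < 1e-7 * np.maximum(1.0, np.abs(roots.real))))
    assert (n_real == 3) == (d < 0)


def test_bifurcation_set_geometry():
    bs = bifurcation_set([0.0, 3.0])
    assert bs["alpha_high"].iloc[0] == 0.0  # cusp point
    assert bs["alpha_high"].iloc[1] == pytest.approx(2.0)
    assert bs["alpha_low"].iloc[1] == pytest.approx(-2.0)
    grid = np.linspace(0, 4, 50)
    bs = bifurcation_set(grid)
    for _, row in bs.iterrows():
        assert abs(cardan_discriminant(row["alpha_high"], row["beta"])) < 1e-9
    with pytest.raises(ValidationError):
        bifurcation_set([-0.5, 1.0])


# ------------------------------------------------------------------ density

@pytest.mark.parametrize("alpha,beta", [(0.0, 0.0), (-2.0, 2.0), (1.5, -1.0),
                                        (0.0, 3.0), (2.0, 1.0)])
def test_density_normalizes_to_one(alpha, beta):
    r = integration_radius(alpha, beta)
    val, _ = integrate.quad(lambda z: stationary_density(z, alpha, beta),
                            -r, r, points=[z for z, _ in equilibria(alpha, beta)],
                            limit=200)
    assert val == pytest.approx(1.0, abs=1e-8)


def test_density_symmetry_at_zero_asymmetry():
    z = np.linspace(0.1, 3, 17)
    assert np.allclose(stationary_density(z, 0.0, 2.0),
                       stationary_density(-z, 0.0, 2.0))


def test_density_modes_are_stable_equilibria():
    modes = sorted(stationary_modes(0.0, 3.0))
    assert modes == pytest.approx([-np.sqrt(3), np.sqrt(3)], abs=1e-9)
    # numeric maximum of f coincides with the analytic mode
    res = optimize.minimize_scalar(
        lambda z: -stationary_density(z, 0.0, 3.0), bounds=(0.5, 3.0),
        method="bounded")
    assert res.x == pytest.approx(np.sqrt(3), abs=1e-5)


def test_moments_match_direct_quadrature():
    ez, ez2 = stationary_moments(1.0, 0.5)
    logc = log_partition(1.0, 0.5)
    num, _ = integrate.quad(
        lambda z: z * np.exp(1.0 * z + 0.25 * z**2 - 0.25 * z**4 - logc),
        -8, 8)
    assert ez == pytest.approx(num, abs=1e-9)
    assert ez2 > 0


# ---------------------------------------------------------------------- dip

def _dip_lp_oracle(x):
    """Exact unimodal sup-distance by linear programming over mode points."""
    from scipy.optimize import linprog

    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    h = (np.arange(1, n + 1) - 0.5) / n
    best = np.inf
    for k in range(n):
        # variables: g_1..g_n, t
        c = np.zeros(n + 1)
        c[-1] = 1.0
        A, b = [], []
        for i in range(n):  # |g_i - h_i| <= t
            row = np.zeros(n + 1); row[i] = 1.0; row[-1] = -1.0
            A.append(row); b.append(h[i])
            row = np.zeros(n + 1); row[i] = -1.0; row[-1] = -1.0
            A.append(row); b.append(-h[i])
        for i in range(n - 1):  # monotone
            row = np.zeros(n + 1); row[i] = 1.0; row[i + 1] = -1.0
            A.append(row); b.append(0.0)
        dx = np.diff(x)
        for i in range(n - 2):  # chord slopes: convex before k, concave after
            if dx[i] <= 0 or dx[i + 1] <= 0:
                continue
            row = np.zeros(n + 1)
            # slope_i - slope_{i+1} with slope_i = (g_{i+1}-g_i)/dx_i
            row[i] = -1.0 / dx[i]
            row[i + 1] = 1.0 / dx[i] + 1.0 / dx[i + 1]
            row[i + 2] = -1.0 / dx[i + 1]
            if i + 2 <= k:      # fully left of the mode: convex
                A.append(row); b.append(0.0)
            elif i >= k:        # fully right: concave
                A.append(-row); b.append(0.0)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0, 1)] * n + [(0, 1)], method="highs")
        if res.success:
            best = min(best, res.fun)
    return 1.0 / (2.0 * n) + best


def test_dip_matches_lp_oracle_on_random_samples():
    rng = np.random.default_rng(4)
    for _ in range(25):
        n = int(rng.integers(5, 14))
        x = rng.choice([0.0, 3.0], size=n) + rng.normal(0, 1.0, size=n)
        fast = dip_statistic(x)
        exact = _dip_lp_oracle(x)
        assert fast <= exact + 1e-9          # fast relaxes the mode junction
        assert exact - fast <= 1.0 / n + 1e-9  # and is close to the LP value


def test_dip_separates_bimodal_from_unimodal():
    rng = np.random.default_rng(1)
    uni = rng.normal(size=60)
    bim = np.r_[rng.normal(-2, 0.3, 30), rng.normal(2, 0.3, 30)]
    assert dip_statistic(bim) > 3 * dip_statistic(uni)
    assert dip_pvalue(bim, seed=9)[1] < 0.05
    assert dip_pvalue(uni, seed=9)[1] > 0.05


def test_dip_test_level_is_honest_under_unimodal_null():
    rej = sum(
        dip_pvalue(np.random.default_rng(i).normal(size=30), n_boot=200)[1] < 0.05
        for i in range(100))
    assert rej <= 10  # at most ~5% nominal + margin
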