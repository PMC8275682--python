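"""Synthetic stock series and cusp-process simulators.

The study's assessment tables are not publicly deposited, so every stage of
the pipeline is exercised on generated data with the same statistical
structure: a ~49-year annual series with piecewise-constant regime means in
SSB, recruitment and fishing mortality, an upward SST trend, exploitation
mostly above F = 1 in the collapse regime, and a state trajectory that
migrates from the bistable cusp region into the stable region at low
biomass.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import StockSeriesTable, ValidationError
from .cusp.density import grid_log_partition_moments
from .cusp.geometry import equilibria

#: default four-regime structure: first years of each regime, 1970-2018
DEFAULT_BOUNDARIES = (1970, 1983, 1995, 2008)
#: per-regime means: high / collapsed / recovered / collapsed-for-good
DEFAULT_MEANS: Mapping[str, tuple[float, ...]] = {
    "ssb": (37000.0, 9000.0, 30000.0, 11000.0),       # tonnes
    "recruitment": (60.0, 8.0, 35.0, 5.0),            # millions of age-1 fish
    "f": (1.1, 1.3, 1.0, 0.9),                        # per year; > 1 in regime 2
}
#: observation noise, ~5% of the grand mean of each variable
DEFAULT_NOISE_SD: Mapping[str, float] = {"ssb": 1100.0, "recruitment": 1.4, "f": 0.055}


@dataclass(frozen=True)
class RegimeSpec:
    """Piecewise-constant-mean specification of a multi-regime stock series."""

    boundaries: tuple[int, ...] = DEFAULT_BOUNDARIES
    n_years: int = 49
    means_per_variable: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MEANS))
    noise_sd_per_variable: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD))
    sst_start: float = 7.2     # deg C
    sst_trend: float = 0.03    # deg C per year
    sst_noise_sd: float = 0.12
    min_segment_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        b = tuple(int(x) for x in self.boundaries)
        if list(b) != sorted(set(b)):
            raise ValidationError("regime boundaries must be strictly increasing")
        ends = b[1:] + (b[0] + self.n_years,)
        lengths = [e - s for s, e in zip(b, ends)]
        if any(l < self.min_segment_length for l in lengths):
            raise ValidationError(
                f"regime lengths {lengths} below minimum segment length "
                f"{self.min_segment_length}")
        for var, means in self.means_per_variable.items():
            if len(means) != len(b):
                raise ValidationError(f"{var}: need one mean per regime")
            if any(m <= 0 for m in means):
                raise ValidationError(f"{var}: regime means must be positive")
        if any(sd < 0 for sd in self.noise_sd_per_variable.values()):
            raise ValidationError("noise sds must be nonnegative")
        object.__setattr__(self, "boundaries", b)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.boundaries[0], self.boundaries[0] + self.n_years)

    def regime_index(self) -> np.ndarray:
        """0-based regime label of every year."""
        return np.searchsorted(np.asarray(self.boundaries), self.years, "right") - 1


def simulate_regime_series(spec: RegimeSpec) -> StockSeriesTable:
    """Gaussian series with piecewise-constant regime means + trending SST."""
    rng = np.random.default_rng(spec.seed)
    years = spec.years
    idx = spec.regime_index()
    cols = {"year": years}
    for var in ("ssb", "recruitment", "f"):
        means = np.asarray(spec.means_per_variable[var])[idx]
        sd = spec.noise_sd_per_variable.get(var, 0.0)
        vals = means + rng.normal(0.0, sd, size=len(years)) if sd > 0 else means.copy()
        # positivity guard for extreme draws; never triggered at default noise
        cols[var] = np.maximum(vals, 1e-6 * np.asarray(spec.means_per_variable[var]).min())
    t = years - years[0]
    sst = spec.sst_start + spec.sst_trend * t
    if spec.sst_noise_sd > 0:
        sst = sst + rng.normal(0.0, spec.sst_noise_sd, size=len(years))
    cols["sst"] = sst
    return StockSeriesTable(pd.DataFrame(cols))


def sample_cusp_stationary(
    alpha: float, beta: float, n: int, seed: int, n_grid: int = 2**14
) -> np.ndarray:
    """I.i.d. draws from f(z) ~ exp(alpha z + beta z^2/2 - z^4/4).

    Inverse-CDF on a fine grid (2^14 points spanning the quartic well);
    rejection sampling is avoided because its acceptance rate collapses for
    large beta.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    zg, logc, _, _ = grid_log_partition_moments([alpha], [beta], n_grid + 1)
    pdf = np.exp(alpha * zg + 0.5 * beta * zg**2 - 0.25 * zg**4 - logc[0])
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(zg))))
    cdf /= cdf[-1]
    u = rng.uniform(size=n)
    return np.interp(u, cdf, zg)


@dataclass(frozen=True)
class CuspSimSpec:
    """Specification of a canonical cusp SDE simulation with per-step controls."""

    omega0: float = 0.0
    omega1: float = 1.0
    a0: float = 0.0
    a1: float = 1.0
    b0: float = 0.0
    b1: float = 1.0
    asym_series: tuple[float, ...] = (0.0,)
    bifur_series: tuple[float, ...] = (0.0,)
    n: int = 1
    sigma_z: float = np.sqrt(2.0)
    dt: float = 1e-3
    burn_in: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if not self.sigma_z > 0:
            raise ValidationError("sigma_z must be > 0")
        if not self.dt > 0:
            raise ValidationError("dt must be > 0")


def simulate_cusp_sde(
    alpha: float,
    beta: float,
    sigma_z: float = np.sqrt(2.0),
    dt: float = 1e-3,
    n_steps: int = 100_000,
    z0: float = 0.0,
    seed: int = 0,
    n_chains: int = 1,
) -> np.ndarray:
    """Euler-Maruyama trajectories of dz = (-z^3 + beta z + alpha) dt + sigma dW.

    Returns an array of shape (n_steps + 1, n_chains).  With sigma_z =
    sqrt(2) the stationary law is exactly the canonical density used by the
    fitting code; for general sigma_z it is exp(2 U(z) / sigma_z^2)-shaped.
    """
    if not dt > 0:
        raise ValidationError("dt must be > 0")
    rng = np.random.default_rng(seed)
    z = np.full(n_chains, float(z0))
    out = np.empty((n_steps + 1, n_chains))
    out[0] = z
    sq = sigma_z * np.sqrt(dt)
    for i in range(1, n_steps + 1):
        drift = -z**3 + beta * z + alpha
        z = z + drift * dt + sq * rng.standard_normal(n_chains)
        if not np.all(np.isfinite(z)) or np.any(np.abs(z) > 1e6):
            raise ValidationError(
                "trajectory diverged: the Euler-Maruyama step dt is too large "
                "for this drift; reduce dt")
        out[i] = z
    return out


def sample_cusp_series(spec: CuspSimSpec) -> dict[str, np.ndarray]:
    """Draw one stationary cusp observation per year of a CuspSimSpec.

    Controls follow alpha_t = a0 + a1 * asym_t, beta_t = b0 + b1 * bifur_t;
    each state draw comes from the stationary density at its year's
    controls (the sigma_z = sqrt(2) canonical scaling) and is mapped to
    observed units through the inverse state map y = (z - omega0) / omega1.

    Returns arrays ``state``, ``asym``, ``bifur``, ``z``, ``alpha``,
    ``beta``.
    """
    asym = np.asarray(spec.asym_series, dtype=float)
    bifur = np.asarray(spec.bifur_series, dtype=float)
    if len(asym) != spec.n or len(bifur) != spec.n:
        raise ValidationError("covariate series must have length n")
    alpha = spec.a0 + spec.a1 * asym
    beta = spec.b0 + spec.b1 * bifur
    rng = np.random.default_rng(spec.seed)
    zg, logc, _, _ = grid_log_partition_moments(alpha, beta, 4097)
    g = (alpha[:, None] * zg[None, :] + 0.5 * beta[:, None] * zg[None, :] ** 2
         - 0.25 * zg[None, :] ** 4)
    pdf = np.exp(g - logc[:, None])
    dz = np.diff(zg)
    cdf = np.concatenate(
        (np.zeros((spec.n, 1)),
         np.cumsum(0.5 * (pdf[:, 1:] + pdf[:, :-1]) * dz[None, :], axis=1)),
        axis=1)
    cdf /= cdf[:, -1:]
    u = rng.uniform(size=spec.n)
    z = np.array([np.interp(u[t], cdf[t], zg) for t in range(spec.n)])
    state = (z - spec.omega0) / spec.omega1
    return {"state": state, "asym": asym, "bifur": bifur,
            "z": z, "alpha": alpha, "beta": beta}


# ---------------------------------------------------------------------------
# packaged tipping fixture
# ---------------------------------------------------------------------------

#: true canonical coefficients of the packaged fixture (state = SSB in
#: tonnes, asymmetry = F/R, bifurcation = SST in deg C)
FIXTURE_COEFFS = {
    "omega0": -2.5, "omega1": 1.0e-4,
    "a0": 0.234, "a1": -7.45,
    "b0": 17.9, "b1": -2.0,
}


def _fixture_paths(years: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic F/R, SST-trend and basin-choice paths of the fixture.

    Early decades sit deep inside the bistable cusp region (cool SST, low
    F/R); from 2008 on the system sits outside it at low state values
    (record-high F/R, warm SST).  Basin flips at 1986 (collapse), 1996
    (recovery) and 2008 (final collapse) give SSB its four regimes; the
    recruitment collapses are planted two years earlier so that
    productivity (R/SSB) shifts lead the SSB shifts.
    """
    n = len(years)
    fr = np.empty(n)
    basin = np.empty(n)  # +1 upper branch, -1 lower branch
    for i, y in enumerate(years):
        if y < 1986:
            fr[i] = 0.018
            basin[i] = +1
        elif y < 1996:
            fr[i] = 0.218
            basin[i] = -1
        elif y < 2008:
            fr[i] = 0.029
            basin[i] = +1
        else:
            fr[i] = 0.27 + 0.013 * (y - 2008)  # record-high scaled pressure
            basin[i] = -1
    # SST: slow warming to ~2005, then rapid warming
    sst = np.where(years <= 2005,
                   7.2 + 0.022 * (years - 1970),
                   7.2 + 0.022 * 35 + 0.105 * (years - 2005))
    return fr, sst, basin


def make_tipping_fixture(seed: int = 7) -> StockSeriesTable:
    """Packaged 49-year demo table with the full tipping-point geometry.

    Generated exactly from the cusp model with the coefficients in
    :data:`FIXTURE_COEFFS`: per-year controls follow
    :func:`_fixture_paths`, the canonical state sits near the equilibrium of
    the scripted basin with small Gaussian scatter, and recruitment follows
    a four-regime step pattern whose collapses lead the SSB collapses by two
    years.  Reproducible: the same seed yields a byte-identical CSV.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(1970, 2019)
    n = len(years)
    c = FIXTURE_COEFFS
    fr, sst_trend, basin = _fixture_paths(years)
    fr = fr * np.exp(rng.normal(0.0, 0.04, size=n))
    sst = sst_trend + rng.normal(0.0, 0.08, size=n)
    alpha = c["a0"] + c["a1"] * fr
    beta = c["b0"] + c["b1"] * sst

    z = np.empty(n)
    for t in range(n):
        eq = [r for r, lab in equilibria(float(alpha[t]), float(beta[t]))
              if lab == "stable"]
        if len(eq) == 1:
            target = eq[0]
        else:
            target = max(eq) if basin[t] > 0 else min(eq)
        z[t] = target + rng.normal(0.0, 0.10)
    ssb = (z - c["omega0"]) / c["omega1"]

    # recruitment (millions): the collapses lead the SSB flips by two years,
    # the recovery arrives with the SSB recovery
    r_means = np.where(years < 1984, 60.0,
                       np.where(years < 1996, 5.5,
                                np.where(years < 2006, 35.0, 3.0)))
    recruitment = r_means * np.exp(rng.normal(0.0, 0.06, size=n))
    f = fr * recruitment  # keeps scaled_pressure = F/R exactly on its path

    return StockSeriesTable(
        pd.DataFrame({
            "year": years,
            "ssb": ssb,
            "recruitment": recruitment,
            "f": f,
            "sst": sst,
        })
    )
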