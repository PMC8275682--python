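# Methods

`codtip` assembles three statistical lines of evidence that an exploited
fish stock has crossed a tipping point into an alternative, hard-to-reverse
state: abrupt changes in single time series, structural breaks in the
relationships between series, and an explicit bistable/stable state
classification from a stochastic cusp-catastrophe model.  The package works
on one annual table — year, spawning stock biomass (SSB, tonnes),
recruitment at age 1 (R), fishing mortality (F, 1/yr) and mean sea surface
temperature (SST, °C) — plus the two derived indices R/SSB (stock
productivity) and F/R (exploitation pressure per unit of year-class
strength).

## Changepoints in the mean (PELT)

For a series x_1..x_n the detector minimizes

    sum_segments  C(seg)  +  m · penalty,          C(seg) = Σ (x_t − μ_seg)² / σ̂²,

over all segmentations with segments of at least `min_segment_length` years
(default 10, a deliberately conservative "reasonable regime length").  The
search is PELT — an exact dynamic program with cost-based pruning; with a
minimum segment length the usual pruning rule must be *delayed*: a point
dominated at time t only becomes removable once the dominating candidate is
itself an admissible segment start (t + L).  Correctness is guaranteed by
test, not by assumption: the suite checks exact agreement with full
enumeration on hundreds of random instances.

Numerical choices:

* **Common variance** σ̂² = var(diff(x))/2, estimated from first differences
  so that mean shifts do not inflate it.  Holding the variance common
  across segments prevents variance changes from masquerading as mean
  changes.  A constant series degrades to σ̂² = 1 (all costs zero, no
  changepoints).
* **Penalty**: "AIC" convention, 2·k with k = 2 parameters per changepoint
  (one new segment mean plus the changepoint position), i.e. 4 by default;
  k is configurable.
* **Ties** are broken toward fewer changepoints, then earliest positions.
* A changepoint is reported as the calendar year of the **last**
  observation of the closing segment.

## Structural breaks in bivariate relationships

For each response~covariate pair (defaults: SSB~F, SSB~F/R, R~SSB, R~SST,
R/SSB~SSB, R/SSB~SST) the package finds, for every break count m, the break
positions minimizing the total OLS residual sum of squares over the
time-ordered rows, by dynamic programming over a triangular matrix of
segment RSS values computed once from cumulative sums.  Both intercept and
slope shift at each break.  The break count is selected by

    BIC(m) = n log(RSS_m / n) + (2(m+1) + m) log n,

ties toward smaller m.  The minimum regime length defaults to
ceil(0.15·n).  As evidence for the selected break structure the fit reports
ΔBIC against the no-break model; no sup-F-type significance test is
attempted because no target value for one exists, and ΔBIC is an honest,
reproducible summary.  Regimes with a (numerically) constant covariate
degrade to intercept-only fits with a warning.

## The stochastic cusp model

The canonical state z follows the overdamped diffusion

    dz = (−z³ + β z + α) dt + σ_z dW,

whose stationary density is ∝ exp(2U(z)/σ_z²), U(z) = αz + βz²/2 − z⁴/4.
The fitting code uses the canonical scaling in which σ_z is absorbed
(equivalently σ_z = √2), giving

    f(z; α, β) = exp(αz + βz²/2 − z⁴/4) / C(α, β).

Deterministic equilibria solve z³ − βz − α = 0; Cardan's discriminant
δ = 27α² − 4β³ is positive in the monostable (stable) region and negative
in the bistable cusp region, whose boundary is α = ±√(4β³/27), β ≥ 0.
Observations with |δ| inside a tiny relative band (10⁻⁹) are labelled
"boundary".

State, asymmetry and bifurcation are linear in one observed variable each
(state = SSB, asymmetry = F/R, bifurcation = SST by default):

    z_t = ω₀ + ω₁·SSB_t,    α_t = a₀ + a₁·(F/R)_t,    β_t = b₀ + b₁·SST_t.

The six coefficients maximize Σ_t log f(z_t; α_t, β_t) + n log|ω₁| (the
Jacobian of the linear state map, without which ω₁ → 0 degenerates the
likelihood).  Implementation details:

* Variables are standardized internally (zero mean, unit sd) and the
  coefficients mapped back; canonical coefficients are affine-equivariant,
  so per-year (α_t, β_t, z_t), classifications and the likelihood are
  unaffected by the units of the inputs (including the recruitment unit,
  which the literature leaves ambiguous).
* C(α, β) and the moments E[z], E[z²] (which are exactly the derivatives of
  log C needed for the analytic gradient) are evaluated by composite
  Simpson on a shared 513-point grid that widens until every row's tail
  exponent is below −30.  Public density functions instead use adaptive
  quadrature (normalization error < 10⁻⁸ by test).
* Quasi-Newton (L-BFGS-B) with analytic gradients from 8 deterministic
  starts: OLS-seeded state map and a sign/level grid over (a₁, b₁, b₀),
  since the likelihood is multimodal.  Standardized coefficients are
  box-bounded to [−15, 15]: beyond that the β → −∞ Gaussian ridge makes the
  model an exact duplicate of the linear one while the density narrows
  below grid resolution.  The reported maximum is the best over starts and
  `converged` is honest.
* The exact symmetry (z, α) → (−z, −α) is resolved by canonicalizing to
  ω₁ > 0.  The Wald p-value for ω₁ uses a central-difference Hessian of the
  negative log-likelihood at the optimum.

**Prediction** is per year from the fitted per-year density: the default
`nearest_mode` (delay convention) takes the density mode closest to the
observed canonical state — the branch a hysteretic system actually tracks —
and `expected_value` takes the stationary mean.  Predictions are mapped
back to observed units through the inverse state map.  Cobb-type pseudo-R²
is 1 − Var(z_obs − z_pred)/Var(z_obs).

**Alternative models** for comparison are fit to the same three columns:
linear (y ~ x₁ + x₂, OLS) and a scaled logistic
y = min(y) + L/(1 + e^−(c₀+c₁x₁+c₂x₂)) + ε by nonlinear least squares.  AIC
uses the Gaussian likelihood at the variance MLE with k = 4 (linear),
k = 5 (logistic) and k = 6 (cusp).  The logistic saturation L is bounded to
[0.1, 2]× the observed response range: unbounded, L → ∞ with c → 0
reproduces any straight line and L is unidentified.  Because both
alternatives can locally mimic a linear response, AIC comparisons between
these families are indicative rather than decisive; the validation report
carries this caveat explicitly, and under a genuinely linear truth the
linear model wins the AIC race in roughly three quarters of simulated
datasets rather than always (the flexible families' overfit gain
occasionally exceeds AIC's fixed penalty difference — an inherent property
of AIC with quasi-nested rivals, not an estimation failure).

**Validation protocol** (four criteria): (i) Wald test of ω₁ at 5%;
(ii) bimodality of the canonical states of bistable-classified years,
assessed with a dip-type statistic when at least 10 such years exist;
(iii) the percentage of observations inside the cusp region; (iv) pseudo-R²
plus the AIC comparison.  The verdict is "valid" iff (i) passes, the cusp
AIC is lowest, and the cusp share is nonzero.

The dip statistic is the sup-norm distance from the empirical CDF to the
closest unimodal CDF, computed via greatest-convex-minorant /
least-concave-majorant constructions over candidate mode points; the test
suite validates it against an exact linear-programming formulation of the
same problem.  P-values come from Monte-Carlo simulation of the uniform
null (cached per sample size), which makes the test exact for the
implemented statistic by construction.

## Synthetic data

The assessment tables behind the original analyses are not publicly
deposited, so the package generates series with the same statistical
structure:

* `simulate_regime_series`: piecewise-constant regime means with Gaussian
  noise and a trending SST.  Defaults emulate a 49-year series (1970–2018)
  with four regimes (boundaries 1983/1995/2008, each ≥ 10 years), a
  collapse regime with F > 1/yr, and noise sd ≈ 5% of each variable's
  level — shifts of ≥ 4 sd, the regime detectability the original design
  targets.
* `sample_cusp_stationary`: inverse-CDF sampling of f(z; α, β) on a 2¹⁴
  point grid (rejection sampling has unbounded cost for large β).
* `simulate_cusp_sde`: fixed-step Euler–Maruyama; with σ_z = √2 its
  stationary law is exactly the canonical density, which the tests verify
  by KS comparison against quadrature.  Non-finite excursions raise an
  error advising a smaller dt.
* `make_tipping_fixture`: the packaged 49-year demo table, generated
  exactly from the cusp model with known coefficients.  Early decades sit
  deep inside the bistable region (the scripted basin flips in 1986, 1996
  and 2008 produce the SSB regimes); from 2008 on, record-high F/R and warm
  SST put the system outside the cusp at low state values.  Recruitment
  collapses lead the SSB collapses by two years, so productivity
  changepoints precede SSB changepoints by construction.

What passing tests on these generators do **not** show about real data:
the generators have no autocorrelation within regimes, no assessment-error
structure, exact linearity of the canonical maps, and observation scatter
placed tightly around the scripted equilibrium branch.  Real stock series
violate all four, so real-data verdicts lean on the validation protocol,
not on the recovery rates demonstrated here.

## Verification studies and problem sizes

The harness (shared by the test suite and `scripts/acceptance.py`) runs:
PELT vs enumeration on 500 random instances (n ≤ 40); boundary recovery on
200 simulated 49-year series; break DP vs enumeration on 300 instances
(n ≤ 40, m ≤ 2); the discriminant against a numeric root-count oracle on a
101×101 control grid; density normalization, mode placement and an SDE
endpoint KS test (384 chains, 40 time units); cusp coefficient recovery and
classification accuracy on 50 datasets of n = 500 (median absolute errors
pre-registered at 0.25–0.6 per coefficient from a pilot oracle run); and
model-family selection under bistable truth (50 seeds) and linear truth
(100 seeds of n = 100).  These sizes keep every oracle enumerable and the
whole battery reproducible on one CPU.

## Known limitations

* The likelihood treats years as independent draws of the stationary
  density; autocorrelation in real stock series is not corrected for.
* AIC comparability across the cusp and least-squares families is
  conventional (see above).
* σ_z is not estimated separately; it is absorbed by the canonical scaling.
* Breaks and changepoints come without confidence intervals; ΔBIC is the
  only evidence summary for break structure.
* Only the cusp geometry is implemented (no fold or higher catastrophes),
  and the state/asymmetry/bifurcation maps are strictly linear in one
  variable each.
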