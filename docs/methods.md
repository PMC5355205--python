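# Methods

This note documents the models, numerical choices and validation design
behind `tallgrass`, and what the synthetic experiments do and do not show.

## 1. The movement model

A step is a displacement between consecutive 4-h GPS fixes inside the
1 April – 30 September season. The model factorizes each step into a
habitat-independent redistribution kernel and a habitat weight:

    f(b | a, X) = φ(a, b; θ) · exp(X_b β) / ∫_D φ(a, c; θ) exp(X_c β) dc

- φ is an isotropic bivariate normal with per-axis SD θ (m). Under φ alone,
  step lengths are Rayleigh(θ) with mean θ√(π/2).
- ω = exp(Xβ) carries no intercept: a constant multiplies numerator and
  denominator identically and cancels, so none is estimable or needed.
- X holds elevation (m), slope (°), cos(aspect), crude protein (%CP),
  herbaceous biomass (g/m²) and protein × biomass. Aspect is measured in
  radians clockwise from north (0 = north, π = south), so *southerly*
  preference appears as a negative coefficient on cos(aspect). Flat cells
  get cos(aspect) = 0, a neutral value.
- The domain D is the fenced enclosure: the simulator renormalizes over
  in-mask cells, and the fitted likelihood models the same boundary through
  its denominator. A practical consequence worth knowing: near a fence the
  realized steps are shorter than Rayleigh(θ), so the mean observed
  displacement falls below θ√(π/2) even when θ is recovered correctly.

### Simulation

The forward simulator discretizes the landscape to raster cells and samples
endpoints exactly from the normalized cell-weight distribution — it is an
exact generative oracle for the fitted model up to cell size. The kernel is
truncated at 6θ (omitted mass < 1e-7). Covariates for a step come from the
biweekly forage layer containing the step's *end* timestamp.

### Estimation

Each observed step is paired with 100 control endpoints. Controls are drawn
from an isotropic normal centred on the step's start with pilot SD θ₀ (the
Rayleigh-moment estimate from the observed step lengths), rejected onto the
mask; each control carries its proposal log-density. A uniform-on-disk
proposal with R = 3 × the maximum observed step length is also shipped and
serves as the R-sensitivity diagnostic. The kernel proposal is the default
because, at 100 controls, the uniform proposal's importance weights span
many orders of magnitude over a study-scale enclosure and the resulting
Monte-Carlo variance in the log-denominator visibly biases θ̂; the kernel
proposal keeps that variance small.

Two objectives are provided:

- `negative_log_likelihood` — the Monte-Carlo approximation of the integral
  itself, `(p̂/m) Σ φ ω / q` in the denominator (for the uniform proposal
  this is the classical effective-area form). The in-mask area of the
  uniform disk is computed exactly by cell counting rather than estimated
  from the acceptance rate; the acceptance-rate estimate is a per-step
  constant with ≈1% relative noise that would otherwise dominate the
  denominator's error budget.
- `choice_set_negative_log_likelihood` — the sampled-alternatives
  conditional-logit form: the observed endpoint competes inside its own
  control set, every alternative corrected by −log q. By the standard
  sampled-alternatives argument this estimator is consistent at a *fixed*
  number of controls, whereas the integral form is consistent only as the
  number of controls grows. It is therefore the default fitting objective.

Optimization is L-BFGS over (log θ, β) — log θ enforces positivity — with
covariates z-standardized for conditioning and coefficients (and the
covariance) back-transformed to the original scale afterwards. The
covariance is the inverse of a central-difference numerical Hessian at the
optimum; CIs are estimate ± 1.96 SE (θ's SE by the delta method). Fits are
flagged unconverged on optimizer failure or a non-positive-definite
Hessian, and no CIs are reported in that case. Steps whose endpoint lands
on nodata are dropped and counted; a run fails if more than 10% drop.
Zero-length steps are legal and need no special casing.

### Estimator validation

Three layers of validation back the estimator:

1. **Denominator oracle.** On a 40×40-cell landscape the uniform-disk
   Monte-Carlo denominator at 5,000 controls matches exact summation over
   all cells within 1% (run at moderate selection strength so Monte-Carlo
   noise sits well under the tolerance; the weights being checked do not
   depend on the parameter values).
2. **Exact-likelihood equivalence.** On a fixed ~970-ha landscape the
   default fit was compared against a fully exact denominator (summation
   over all ~97k cells with analytic gradients): the two agree in
   distribution, including a small positive finite-sample offset on the
   protein axis that is a property of the exact MLE at 1,000 steps on that
   landscape realization — i.e. of the likelihood itself, not of the
   Monte-Carlo machinery.
3. **Parameter recovery.** Twenty replicates of 1,000 steps at θ = 546 m
   and β = (0.05, −0.1, −0.2, 0.4, −0.005, 0), each replicate regenerating
   landscape, weather and trajectory independently (the standard design for
   measuring an estimator's marginal bias): per-parameter |bias| stays
   under 0.5 mean SE and 95% CI coverage at or above 85%.

The kernel-only limit (β = 0) is checked on a 7×7-km domain at θ = 100 m:
the fence must be far relative to θ for the pure Rayleigh distribution to
be observable (see the boundary remark above), and 10-m cells keep the
lattice granularity of step lengths below the KS tolerance.

## 2. Forage surfaces

Crude protein is %N × 6.25. Disk-meter heights are calibrated to dry
biomass by OLS (per field season; the 2011 season reuses the 2013
calibration via a configurable year → calibration lookup). The forage
models are random forests — 1,000 trees, terminal node size 5 — over
elevation, slope, sin/cos aspect, days since burn, cumulative precipitation
since 1 March, burns since 1980, burn-interval class (encoded as the
interval integer ∈ {1,2,4,20}), burned-this-year, and sin/cos of Julian day
rescaled by day/365 × 2π.

Validation is repeated random holdout: train on 33% of sites, evaluate RMSE
of the log-transformed response on the 67% holdout, 10 repeats. Two
conventions the protocol leaves open are fixed as: log(y + 1), which admits
zero biomass; and out-of-bag pseudo-R² = 1 − MSE_oob/Var(y). The sample
table is canonicalized by lexicographic sort before splitting so the report
is invariant to row order at a fixed seed.

Projection writes one protein and one biomass grid per biweekly period —
strict 14-day blocks anchored at 1 April, giving 14 periods to 1 October,
the last truncated — with shrub-masked cells set to nodata at projection
time only (training plots are not masked). Rasters are exchanged as ESRI
ASCII grids (plain text, nodata −9999), a deliberate text-only format
choice; georeferencing is planar metres with a lower-left origin and
half-open cell bounds [x, x + cellsize).

## 3. The synthetic landscape

The generator produces the statistical structure the analysis assumes,
nothing more:

- **Terrain**: Gaussian-filtered white noise rescaled to a configured
  relief amplitude (default 50 m over a ~380–430 m base, a tallgrass-hill
  scale); slope/aspect by Horn's 3×3 method with odd-reflection padding
  (exact for affine surfaces, including edges).
- **Watersheds**: axis-aligned column strips, one burn interval each from
  {1, 2, 4, 20} years; burn dates uniform in a 15 March – 5 May spring
  window; schedules extend back to 1980 so days-since-burn and
  burns-since-1980 are always defined. Geometric realism is a non-goal.
- **Weather**: wet-day/gamma daily precipitation whose expected annual
  total is 835 mm with 75% in April–September; sinusoidal temperature
  (annual mean 12.8 °C, amplitude 14 °C) peaking mid-July. Drought years
  scale precipitation by 0.6 and add 2 °C. The ANPP proxy (0.1 g/m² units)
  is an increasing linear function of growing-season precipitation.
- **Forage truth**: smooth parametric response curves, deliberately not a
  hidden ensemble model, so ground truth is analytically evaluable —
  protein falls with time since burn (logistic post-fire flush plus a slow
  linear decay), rises on uplands and falls with biomass; biomass rises
  with cumulative precipitation (saturating), with time since burn
  (saturating regrowth), peaks mid-summer, and is lower on uplands.
  Monotonicities are property-tested on a covariate grid sweep within the
  seasonal covariate ranges; outside them (e.g. decades-unburned
  watersheds) protein is floored at 1 %CP, where strictness gives way to
  a plateau.
- **Plot campaigns**: uniform-random cells and uniform-random in-season
  dates (the real campaigns were opportunistic; the design is unstated, so
  a uniform design is the recorded assumption). Disk heights are generated
  by *inverting* the configured calibration plus optional noise, so at zero
  noise the calibration regression is exactly recoverable — a deliberate
  closed loop for testing.

All randomness flows from one run-level seed through named substreams
(terrain, burns, weather, plots, one per trajectory and fit), so any stage
can be re-run in isolation and whole runs are bit-reproducible.

What the generator does *not* emulate: spatial autocorrelation of plot
residuals, observation error in GPS fixes, herd cohesion (each trajectory
is independent), fire spread, hydrology, or shrub dynamics. Passing tests
therefore demonstrate correctness of the estimation machinery under the
stated model, not robustness to these real-data complications.

## 4. Interannual analyses

Per-individual-year coefficient tables are analyzed with linear mixed
models with a random intercept per animal (the same individuals recur
across 2–7 years): a categorical-year fixed effect with a Wald F-test,
Tukey-style all-pairs year contrasts, single-covariate regressions on
previous-year ANPP (0.1 g/m²) or April–October mean temperature (°C), and
lactation-status contrasts with optional status × climate interactions.
The protein-vs-biomass selection relationship is the same machinery with
one coefficient regressed on another.

Degrees-of-freedom choices: denominator df use a containment-style
approximation, n − rank(X) − (g − 1); the Tukey adjustment is Tukey–Kramer
via the studentized-range distribution on the mixed-model contrasts. These
are approximations — the type-I error of the year F-test is therefore
verified by simulation (200 null tables of 20 animals × 7 years: empirical
rejection ≈5–7% at α = .05) rather than assumed. Degenerate inputs
(constant response, zero residual variance) are mapped to F = 0 / p = 1
instead of NaN. With a single individual the random intercept is
inestimable and the correlation analysis reduces to OLS, which is flagged
in the docstring rather than hidden. All analyses are deterministic given
the input table.

## 5. Selection-strategy classification

A converged fit is classified by its 95% CIs: protein CI spanning zero →
`none`; protein CI > 0 with significantly positive interaction or biomass
→ `form1` (biomass selected when coupled with protein); protein CI > 0
with biomass CI < 0 and no positive interaction → `form2` (high protein,
low biomass); protein CI > 0 with biomass CI spanning zero → `form3`
(protein only). The precedence (interaction/positive-biomass before
negative-biomass) resolves the one ambiguous overlap in the rule table.

## 6. Problem sizes and defaults

- Demo pipeline: 160×160 cells at 20 m (~1,020 ha, the study's enclosure
  scale; 20-m demo cells are a runtime choice — analyses use the 10-m
  grid), 6 individual-years × 500 steps, full 1,000-tree forests.
- Recovery experiments: 311×311 cells at 10 m (~970 ha), 1,000 steps per
  individual-year (a full season at 4-h fixes holds at most ~1,100 steps),
  100 controls per step, 20 replicates.
- Movement truth for validation: θ = 546 m (the study-scale kernel SD);
  β = (0.05, −0.1, −0.2, 0.4, −0.005, 0) in per-unit-covariate units,
  chosen to produce clear but not caricatural selection on the synthetic
  surfaces.

## 7. Known limitations

- The kernel has no directional persistence; correlated-random-walk
  alternatives are out of scope.
- The protein–biomass axis is strongly collinear by construction (as in
  the real system), so per-fit protein SEs are wide and the finite-sample
  ML offset along that axis, while small relative to SE, is measurable on
  any fixed landscape realization.
- Mixed-model df are approximate (see §4); exact small-sample F statistics
  are not reproduced, only calibrated error rates.
- The likelihood treats steps as conditionally independent given the
  landscape; trajectories are Markovian by construction, matching that
  assumption exactly — real fixes need not.
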