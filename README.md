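# tallgrass

Mechanistic step-selection analysis of large-grazer movement on dynamic
tallgrass-prairie forage landscapes — with a fully synthetic, ground-truthed
data pipeline for validating every stage of the analysis.

## The scientific problem

Grazers such as plains bison face a quality–quantity tradeoff: foliar crude
protein is highest in recently burned, low-biomass grassland, while standing
biomass accumulates with time since fire. Quantifying how individuals weigh
these resources requires (i) spatiotemporal surfaces of forage quality and
quantity and (ii) a movement model that separates where an animal *can* go
in one fix interval from what it *prefers* once there.

The core model is a redistribution-kernel step-selection function. The
probability that an animal steps from location *a* to location *b* in one
4-h fix interval is

```
f(b | a, X) = φ(a, b; θ) · ω(X_b; β) / ∫_D φ(a, c; θ) · ω(X_c; β) dc
```

where φ is an isotropic bivariate normal density with per-axis standard
deviation θ (the habitat-independent movement kernel, metres per 4 h) and
ω(X; β) = exp(Xβ) is the habitat weight over six covariates: elevation (m),
slope (°), cos(aspect), crude protein (%CP), herbaceous biomass (g/m²) and
the protein × biomass interaction. θ and β are estimated *simultaneously*
per individual-year by maximum likelihood, with the normalizing integral
approximated case–control style: each observed step is paired with 100
random control endpoints (drawn from a pilot movement kernel, with
importance corrections) and the fit uses the sampled-alternatives
conditional-logit objective. Confidence intervals are ±1.96 SE from the
inverse numerical Hessian.

Around that core the package provides:

- **`tallgrass.landscape`** — synthetic terrain (Horn slope/aspect), strip
  watersheds on 1/2/4/20-year spring-burn rotations, daily weather with
  drought years, an analytically evaluable forage-truth surface, and plot
  campaigns (foliar protein plots; disk-pasture-meter height plots).
- **`tallgrass.forage`** — crude protein = %N × 6.25; OLS disk-meter
  calibration (e.g. BIOMASS = 2.40·HEIGHT + 3.70); random-forest forage
  models (1,000 trees, terminal node size 5) with repeated 33/67 holdout
  validation; biweekly 10-m raster projection from 1 April to 1 October.
- **`tallgrass.movement`** — an exact forward simulator of f(b | a, X) on
  the raster grid, used as the generative oracle for estimator validation.
- **`tallgrass.ssf`** — step construction, control sampling, the likelihood
  and its fitting machinery, and a rule-based classifier of forage
  selection strategies.
- **`tallgrass.analysis`** — linear mixed models (random intercept per
  animal) for year effects with Tukey-style contrasts, regressions of
  selection coefficients on previous-year ANPP and growing-season
  temperature, and lactation-status contrasts.
- **`tallgrass.pipeline` / `tallgrass` CLI** — end-to-end orchestration
  with per-stage seeded substreams and bit-reproducible outputs.

## Worked example

Run the demo pipeline — 6 individual-years (3 animals × 2 seasons, the
second a drought year) of 500 steps each, simulated at θ = 546 m and known
β on a ~1,020-ha enclosure, then re-estimated from the simulated fixes:

```python
from tallgrass.config import default_config
from tallgrass.pipeline import run_pipeline

art = run_pipeline(default_config(seed=3), "runs/demo")
print(art.coefficient_table[["eartag", "year", "theta_hat",
                             "beta_protein", "strategy"]])
```

Output (printed by the run above):

```
  eartag  year  theta_hat  beta_protein strategy
0   W601  2011   561.5968        0.4538    form3
1   W602  2011   576.9520        0.3096    form3
2   W603  2011   578.2377        0.5098    form3
3   W601  2012   508.1678        0.1887     none
4   W602  2012   536.8324        0.4092     none
5   W603  2012   532.7342        0.2090     none
```

Each row is one animal-season. `theta_hat` is the recovered movement-kernel
SD (truth: 546 m — the estimates straddle it), `beta_protein` the recovered
protein selection (truth: 0.4 per %CP on the projected surfaces), and
`strategy` the rule-based classification: `form3` = selection for high
protein with indifference to biomass; `none` = protein CI spans zero (the
drought season carries weaker forage contrast, so per-fit uncertainty is
larger). The run directory also holds the projected forage rasters
(`rasters/*.asc`), per-fit JSON with full provenance, the Tukey year
contrasts and a `manifest.json`; rerunning with the same config reproduces
every payload bit for bit.

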