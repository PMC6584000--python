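# Methods

## Scope and data model

The package analyses gradient ("distance-decay") monitoring designs around
a dredging source. Four tables drive everything:

- **water quality** — one row per site-day: turbidity (NTU), daily light
  integral (DLI, mol photons m⁻² d⁻¹) and raw deposition-sensor output
  (instrument units). Day 0 is the start of dredging; baseline days are
  negative.
- **colonies** — one row per tagged colony per ~14-day survey: morphology
  (encrusting, foliose, corymbose, branching, massive), sediment-cover and
  (massive *Porites* only) mucous-sheet categories on the 1–7 scale,
  surface state, a dislodged flag, and a study-level non-zero-mortality
  flag supplied as an external binary input.
- **psd** — per site and survey phase, the seabed composition as percent
  gravel (>2 mm), sand (2000–62.5 µm), silt (62.5–4 µm), clay (<4 µm).
- **sites** — site id and distance from the source (km).

## Preprocessing

Turbidity is converted to suspended sediment concentration with a fixed
factor of 1.8 mg L⁻¹ per NTU. The deposition signal is averaged per day,
then min–max normalised per site to a unit-less 0–1 deposition index
(absolute accumulation rates are not recoverable from the optical
backscatter signal, so only relative levels are meaningful; the index is
invariant to affine rescaling of the instrument units). The three pressure
metrics consumed by the fits are the fortnightly maximum of a 14 d running
mean SSC, a 14 d running mean DLI and a 60 d running mean deposition index.

Numerical choices:

- Running means are **trailing** (right-aligned): the exposure experienced
  up to each day, never using future data.
- A window is emitted only when ≥ 50% of its days have data
  (`min_window_coverage`), guarding against fouled or serviced loggers.
- The fortnightly summary applies the **maximum** to all three metrics,
  including DLI. A maximum of light is arguably a best-case rather than a
  pressure reading, so `PreprocessConfig(dli_summary_stat="min")` switches
  DLI to the fortnightly minimum; the default keeps all metrics symmetric.
- Fortnight = floor(day/14): the bins partition the day axis with no gaps.
- DLI integration fills missing within-day samples with the day's mean
  available flux, i.e. the integral scales mean flux to the full day; an
  empty day is a missing value.

## Colony scoring

Cover categories use half-open bands (previous upper, upper]: 1 = exactly
0%, 2 = (0,5], 3 = (5,33], 4 = (33,65], 5 = (65,95], 6 = (95,99],
7 = (99,100]. The printed integer band edges leave gaps (e.g. 5.5%);
closing each band downward assigns such values to the higher category.

Tissue fate follows the photographic-sequence rule: within each maximal
covered episode, tissue is *live* throughout if the episode ends with a
clear, live surface; it is *dead* from the episode's first covered day if
the cover persists to the end of the record or its removal reveals dead
tissue. Dead is absorbing over the record. The same rule serves
mucous-sheet episodes.

Colonies ever flagged dislodged are excluded whole — including their
pre-flag observations — since a moved colony's series is unusable.

Site-level exceedance is the proportion of observations (colony × survey)
with score ≥ 3 (>5% cover); a per-colony-ever-exceeded denominator is
available by flag. The pipeline computes the exceedance metrics on massive
*Porites* only, the morphology on which smothering and mucous sheets are
scored and interpreted; branching and corymbose colonies never smother.

## The decay model

Each metric is transformed (log10 SSC, √DLI, logit for the deposition
index and all proportions) and fitted with

y_ij = β0 + β1·log10(d_i) + u_site(i) + v_fortnight(j) + ε_ij,

u ~ N(0, σ_u²), v ~ N(0, σ_v²), ε ~ N(0, σ_ε²). Proportions at exactly 0
or 1 are shrunk by the empirical-logit correction (p·n + c)/(n + 2c) with
c = 0.5 and n the underlying count; continuous indices without a count use
n = 1 on boundary values only, with a warning.

"Uninformative" priors are Normal(0, 100²) on β and
InverseGamma(0.001, 0.001) on each variance. Sampling is by Gibbs over the
conjugate full conditionals. Because distance is constant within a site,
β0 and β1 are partially confounded with the site intercepts; the sweep
therefore includes translation-group moves that shift mass along
(β0, u − δ) and (β1, u − δ·x_s) from their exact conditional densities.
These moves leave the target distribution invariant and restore fast
mixing of the regression coefficients — without them the desk-scale
profile would not converge.

Defaults are 5 chains × 10,000 burn-in × 20,000 retained draws; the
desk-scale test profile (3 × 500/1,500) is used throughout the test suite
and the bundled analysis scripts, which is sufficient for the effectively
independent draws this sampler produces on well-specified data. Chains
start overdispersed around a least-squares anchor. Classic split-R̂ is
computed per scalar parameter; values above 1.05 raise a warning.

Site-level pooled responses (coral exceedance, mortality, silt+clay) have
one value per site, so both random effects are disabled and the model
degenerates to a Bayesian simple regression — random intercepts would be
unidentifiable there. Random effects are intercepts only. Baseline
(pre-dredging) fortnights are excluded from the fits; the baseline phase
has no distance gradient by design.

Degenerate inputs: a single distinct distance raises a collinearity error;
site/fortnight effects require ≥3 sites and ≥2 fortnights respectively.

## Effect distances

ED_q solves f(ED_q) = f(d_far) + q·(f(d_near) − f(d_far)) with
f(d) = g⁻¹(β0 + β1·log10 d), random effects at zero. ED is defined on the
**back-transformed (natural) scale**: under the identity transform the
geometry forces ED_q to depend only on the endpoints
(log10 ED_q = log10 d_far + q·(log10 d_near − log10 d_far), so
ED10 = 20.67 km and ED50 = 2.571 km for 0.19–34.8 km regardless of the
coefficients), while curved transforms give metric-specific EDs. A
transformed-scale definition would collapse every metric onto the identity
values, contradicting the heterogeneous EDs that motivate the statistic.

`ed_point` uses the identity closed form where it applies and monotone
bisection (tolerance 1e-9 on log10 d) otherwise. Posterior EDs
(`ed_posterior`) use the equivalent vectorised solve through the forward
transform, cross-checked against bisection to 1e-6 relative in the test
suite. The defining equation is direction-symmetric, so light-like metrics
with β1 > 0 work unchanged. Draws whose slope has the wrong sign for the
metric, or is numerically zero (|β1| < 1e-8, where the solution approaches
the identity geometry as a removable limit), describe a gradient that
never dissipates within the monitored range; they are censored at d_far
and counted (`n_clipped`). More than 50% such draws aborts: the posterior
carries no usable gradient. The point estimate is the posterior median
(robust to censoring); the mean is available by flag. The square-root
back-transform is clamped at zero (a negative √DLI prediction means zero
light) before inversion.

## Particle sizes

Binned grain-size distributions are reduced to the four classes with
straddling bins split pro-rata on log grain size, matching log-spaced
laser-diffraction output. The gravel class is treated as open-ended above
2 mm; only the 2 mm sand boundary matters downstream. Enrichment is the
after/before ratio of the combined silt+clay proportion per site,
undefined (NaN) at a zero baseline.

## Synthetic campaigns

The generator is the fitted model run forward, not a hydrodynamic
simulation — deliberately, so parameter recovery is a well-posed check.
Defaults emulate a 530-day campaign at 17 log-spaced sites from 0.19 to
34.8 km with a 180-day baseline:

- Transformed-scale slopes/intercepts per metric: log10 NTU 1.0 − 0.4·L,
  √DLI 1.7 + 0.95·L, logit deposition −0.36 − 1.68·L (L = log10 km),
  chosen so near-source conditions (≈19 NTU, ≈1 mol m⁻² d⁻¹ light,
  deposition index ≈0.6) relax to far-field values (≈2.4 NTU, ≈10 mol
  light) across the array. During the baseline the mean is flat at the
  far-field level (zero distance gradient).
- Random variation: σ_site = 0.3, σ_fortnight = 0.2, σ_resid = 0.2 on the
  transformed scale; the fortnight shock is shared across sites within a
  fortnight (campaign-intensity fluctuations).
- Colonies: 50 per site plus a top-up to ≥20 massive *Porites*; morphology
  mix 15/15/10/30/30% encrusting/foliose/corymbose/branching/massive;
  P(score ≥ 3) = logistic(−1.4 − 3.6·L) for susceptible morphologies
  (≈20% at 1 km falling to ≈2% at 5 km) and identically zero for
  branching/corymbose; 5% of colonies dislodged at a random survey
  (missing-at-random, to exercise the exclusion filter).
- PSD: baseline composition 10/82/5/3% with silt+clay enrichment declining
  linearly on log10 distance from 5× at the nearest site to 1× at the
  farthest, halving in each subsequent post-dredging survey; Dirichlet
  noise with total concentration 300; a noise-free mode returns the
  expectations exactly.

What the generator does **not** emulate: spatially correlated plumes,
tidal and weather signals, sensor fouling artefacts beyond daily
averaging, non-stationary dredging intensity, and any coupling between
water-quality noise and colony scores beyond the shared distance gradient.
Passing recovery tests therefore show the estimator is correct under the
model's own assumptions, not that real campaigns satisfy them.

## Problem sizes used in tests and scripts

The bundled analyses use the desk-scale MCMC profile (3 × 500/1,500), the
default 17-site/530-day synthetic campaign for end-to-end runs, 20
replicates of 17 sites × 38 fortnights for the recovery experiment, and an
800 × 600 panel for the variance-decomposition check. These sizes give
Monte-Carlo error comfortably inside the tolerances asserted alongside
them.

## Known limitations

- Site random effects are only weakly identified against the smooth
  distance trend (one distance per site); the proper prior keeps them
  well-posed, and the translation moves keep the confounding from harming
  mixing, but σ_site is informed mainly by the 15–17 site contrasts.
- The deposition index's min–max normalisation ties the fitted logit curve
  to each site's observed range, so its generator slope is not recovered
  exactly (the index is a relative, not absolute, pressure measure).
- EDs are interval-censored at the monitored range [d_near, d_far]; the
  method deliberately does not extrapolate beyond the array.
- The mucous/sediment exceedance fits pool all dredge-phase surveys into
  one proportion per site; a fortnightly-resolution variant is possible
  via `site_exceedance` per fortnight but is not the default.
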