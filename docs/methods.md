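# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Gloss parameterization (`matodd.reflectance`)

The Ward model is used with three parameters: diffuse reflectance ρd,
specular energy ρs (ρd + ρs ≤ 1), and lobe spread α ∈ (0, 1].  The
perceptual coordinates are contrast gloss c = (ρs + ρd/2)^⅓ − (ρd/2)^⅓ and
DOI gloss d = 1 − α.  The inverse is closed-form
(ρs = (c + (ρd/2)^⅓)³ − ρd/2, α = 1 − d) and round-trips to < 1e−8 over the
valid domain.

Two conventions worth stating:

- δ in the specular lobe is the angle between the half vector of the
  incoming/outgoing directions and the surface normal — the standard Ward
  (1992) convention.  The normalization is
  ρs·exp(−tan²δ/α²)/(4πα²√(cosθᵢcosθₒ)); a cosine-weighted hemispherical
  quadrature in the tests confirms energy stays below ρd + ρs.
- Published gloss parameter lists truncate toward zero at three decimals
  (e.g. c = 0.06797 appears as 0.067).  `printed_gloss_value` implements
  that display convention; all internal computation is full precision.

## Oddity sensitivity (`matodd.psychophysics`)

Equal-variance Gaussian model: non-targets ~ N(0,1), target ~ N(d′,1).  The
decision rule is the differencing ("most distant from the others") rule,
equivalent to picking the sample farthest from the grand mean.  This is a
modeling choice — the underlying task analysis could also use other
unbiased-observer rules — and it is verified against an independent
quadrature oracle in the tests (agreement ≤ 0.005 at d′ ∈ {0.5, 1, 2, 4}
for both m = 3 and m = 4).

- Chance is 1/m: 0.25 for the four-alternative design (one illumination,
  four poses) and 1/3 for the three-alternative designs (three
  illuminations, one pose).
- `simulate_oddity_pc` uses 10⁶ Monte-Carlo trials by default with a fixed
  seed; the Monte-Carlo standard error at chance is ≈ 0.0005.
- Perfect scores are capped at 1 − 1/(2N) before inversion so d′ stays
  finite.
- The inverse interpolates a monotone (PCHIP) fit of the simulated
  psychometric function on a d′ grid dense below 2.0 (grid spacing 0.1)
  and coarser up to 8.0, inverted by bisection.  Proportions at or below
  chance floor at d′ = 0; sensitivity is never negative.
- Lab-style aggregation estimates d′ per observer then averages (SEM =
  sample SD / √n); crowd-style aggregation pools all one-trial responses
  into a single proportion.  Unequal trial counts per observer are
  accepted.
- The cross-environment comparison is OLS of crowd d′ on lab d′ with an
  intercept.  Note that estimation noise in the lab d′ (the regressor)
  attenuates the fitted slope below the generating attenuation — the
  classical errors-in-variables effect — which the recovery test accounts
  for in its tolerance.

## Synthetic stimuli (`matodd.stimuli`)

The generator replaces a physically based global-illumination renderer with
a procedural proxy.  The analysis pipeline consumes only images and
responses, so fidelity requirements are: correct design structure, correct
parameter grids, and monotone image change along each dimension.

- **Geometry**: five bumpy spheres, each a unit-sphere height field plus
  one noise type (low-frequency noise with crater-like depressions,
  bandpass noise, sine modulation, and two power-law noises of different
  spectral slope), sampled on the sphere's (latitude, longitude) chart so
  that a pose change is a pure longitude shift.  Presets are reproducible
  bit-exactly from their seeds.
- **Illumination**: six parametric proxies (directional lights + ambient).
  Proxies 1–3 are mutually similar (overcast family; illumination
  condition 2), proxies 4–6 mutually dissimilar (tunnel / tungsten / cool
  interior; condition 3).  Condition 1 uses proxy 1 with four of the five
  36°-step poses.
- **Shading**: Lambertian diffuse plus the Ward lobe per light.  The lobe
  is evaluated at a resolvable angular spread (α clamped to ≥ 0.05 for the
  shape term only) so sharp highlights cannot fall between pixels; DOI is
  then realized as a Gaussian blur of the specular layer with σ = 0.5·α·size
  pixels, monotone in α.  Specular energy stays proportional to ρs.
- **Task grids** (target parameter; anchor in parentheses): GC ρs
  0.00–0.12 step 0.02 (0.06); GD d 0.88–1.00 step 0.02 (0.94); OT density
  scale {0.0039, 0.0156, 0.0625, 0.25, 1.00} (1.00); MP and MG blend
  weight 0.00–0.80 step 0.20 (0.00); GP d 0.88–1.00 step 0.04 with a
  consistent/inconsistent highlight flag (non-targets inconsistent at the
  same d).  Off-grid values raise an error listing the valid grid.
- **Translucency proxy**: optical depth τ = 6·scale·thickness with the
  chord length from the height field; the body term fades and a backlight
  term grows as the medium thins.  Monotone in the scale parameter.
- **Material blends**: per-pixel linear combinations of two endpoint
  shading models (gold/plastic-yellow; silver/glass), weight 0 giving the
  pure metal endpoint.
- **Inconsistent highlights**: the specular layer of a consistent render is
  re-applied by spherical mapping with a seeded random longitude/latitude
  offset and 2× tiling (the repeat count is a config value), then the
  result is histogram-matched per channel to the consistent render.
  Matching is exact rank-based assignment: the output's pixel multiset
  equals the reference's exactly, which a generic quantile-mapping matcher
  does not guarantee on 8-bit images with large tied regions.  The
  consistency index used in tests is the masked Pearson correlation between
  highlight and shading intensities; a gradient-orientation measure was
  tried first but does not separate the classes on this proxy renderer,
  whose orientation fields are dominated by the silhouette.
- **Synthetic observers**: a link function maps stimulus parameter distance
  to d′ (linear in anchor-normalized distance; log-scale for the geometric
  OT grid; a constant for the GP flag), with a lapse probability of a
  uniform random response (default 0.02).  Responses are generated by the
  same differencing rule the estimator assumes, so parameter-recovery tests
  probe the estimator, not model mismatch.
- Determinism: per-artifact seeds are SHA-256 hashes of the master seed and
  the artifact's identifying tuple; identical configs give bit-identical
  corpora.

What passing tests do **not** show about real data: the proxies contain no
global illumination, no cast shadows, no physically correct subsurface
scattering or refraction, and the observer model has no bias, learning, or
attention effects.  Quantities estimated on this corpus (e.g. regression
MSEs) are not comparable to values measured on photorealistic stimuli with
human observers; only the pipeline's statistical machinery is validated.

## Texture features (`matodd.features`)

- CIELAB conversion decodes the display gamma of 2.2, maps linear RGB
  through the sRGB primaries to XYZ, and normalizes by a scene white — the
  mean XYZ of a matte white sphere rendered under the same illumination
  proxies (averaged over a condition's proxies).
- The complex steerable pyramid (4 scales, 4 orientations) is built in the
  frequency domain with log-raised-cosine radial masks and cos³ angular
  masks, without subsampling.  Boundary handling is circular, so statistics
  are exactly invariant to circular shifts; object crops are not truly
  stationary, which is accepted and shared by all images equally.
- The 32-feature per-channel reduction is an explicit registry: 4 pixel
  marginals (mean, SD, skew, kurtosis), 2 lowpass marginals (skew,
  kurtosis), 3 lowpass autocorrelations (lags 1–3), and per scale: mean
  subband magnitude (4), orientation anisotropy (4), mean within-scale
  cross-orientation magnitude correlation (4), adjacent-scale magnitude
  correlation (3), band autocorrelation at a scale-matched lag (4), and
  band skewness (4).  The registry is isolated so an alternative reduction
  table can be swapped in.
- Variants: 3 color means, 12 color moments, 32 grayscale, 96 color.  The
  combined grayscale+color condition is assembled as the union of the
  grayscale set and the color pixel moments (40 features after removing the
  duplicated L\* marginals); its size is logged, not asserted, because the
  composition of that condition is ambiguous (a printed count of 48 is not
  reproducible as 32 + 12).
- Constant planes yield zeros for all variance-normalized statistics, so
  vectors stay finite.
- Distances: features are z-scored per feature across the full corpus
  (constant features dropped with a warning); the scalar condition distance
  is the mean pairwise Euclidean distance, and the regression predictors
  are per-feature mean pairwise absolute differences.  Standardization
  matters because raw pixel means would otherwise dominate every distance.

## Sensitivity regression (`matodd.regression`)

- One row per task condition: X = per-feature distances, y = d′.
- Stratified 4:1 split by task with a largest-remainder rule for fractional
  test counts; every stratum keeps at least one row on each side; strata
  under 5 rows are pooled with a warning.
- Pixel conditions (3, 12 features) use OLS; texture conditions use lasso
  with the penalty tuned to exactly 18 nonzero coefficients.  The
  regularization path is scanned and bisected for penalties achieving
  support 18; if the path jumps past 18, the largest support below is used
  and logged.  Among candidate penalties, 5-fold CV inside the training
  split picks the MSE minimizer (`lambda_mode="cv_min"`); the
  least-penalized candidate is available behind `lambda_mode="first"`
  because the original analysis does not state which control was used.
- Predictors are standardized on the training split only; y is left
  unstandardized.  Test R² = 1 − SSres/SStot about the test mean and may be
  negative.
- Resampling defaults to 10,000 splits; the pipeline and tests use a few
  hundred, which already stabilizes the medians, to keep runtimes at desk
  scale.  Per-task MSEs carry percentile bootstrap 95% intervals over the
  resamples.

## Pipeline (`matodd.pipeline`, `matodd.cli`)

Stages (stimuli → observers → d′ → features → regression) communicate
through files only; a manifest records the resolved config and SHA-256 of
every artifact, and identical configs produce identical manifests.  The
default demo config uses 128-px renders, 100 crowd / 20 lab observers, a
ground-truth link gain of 3.0, crowd attenuation 0.8, and 200 regression
resamples.  The `matodd` CLI exposes each stage and `run-all`.

## Known limitations

- The proxy renderer is not photometric; absolute feature values and
  regression errors are corpus-specific.
- The 32-feature reduction is a documented stand-in for a published
  reduction table that is not reproducible from its description alone.
- The oddity decision rule and simulation trial count are config-exposed
  assumptions; other observer models (e.g. bias, criterion shifts) are out
  of scope.
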