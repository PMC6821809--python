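# Methods

This note documents the models, numerical choices, and limitations of the
package; it is the design record a maintainer or reviewer should read
next to the code.

## Historical defaunation index

The index D(r, f) = Σω(N_r − N_f) / Σω(N_r + N_f) is a weighted, signed
dissimilarity between a focal and a reference assemblage, bounded in
[−1, 1], antisymmetric (D(r, f) = −D(f, r)), zero on identical
assemblages, and invariant to rescaling all weights. Removing a unit
present in both assemblages from the focal one can never decrease D.
These invariants are enforced by property tests.

Weight schemes: `equal` (1 per unit); `conservation` (IUCN threat rank
LC=1, NT=2, VU=3, EN=4, CR=5, Data Deficient units at the 2.5 midpoint of
the scale rather than a guess at either extreme); `size` (body mass in
grams to the 3/4 power — the metabolic scaling exponent — so weight
tracks approximate contribution to ecosystem function); `rank`
(ascending body-mass rank with averaged ties). The rank scheme is named
but not defined in the literature that motivates it; ascending rank with
averaged ties is this package's definition, exposed as an option and kept
out of headline outputs.

Functional extinction: a unit recorded at strictly fewer than 2.5% of a
site's stations is scored absent. The inequality is deliberately strict
on the station *fraction* — a unit at exactly 2.5% survives — rather than
on a rounded integer station count; the boundary behavior is pinned by a
test. The threshold treats very sparse records as evidence of an
ecologically non-functional population, not of absence.

## Community occupancy model

The model is the Royle–Dorazio hierarchical multispecies occupancy
formulation with a species-and-site random intercept on occupancy, two
station covariates (canopy closure, village density) on occupancy, and
effort as the only detection covariate:

    z_ij ~ Bern(ψ_ij),  logit ψ_ij = α_{i,site[j]} + β1_i x1_j + β2_i x2_j
    y_ijk ~ Bern(z_ij p_ijk),  logit p_ijk = α.p_i + β.e_i effort_jk

Detection is conditioned on the latent state (the z factor): a species
absent from a station cannot be detected there. Species-level parameters
are community draws, α_{i,s} ~ N(μ_α[s], σ_α[s]) per site and similarly
for β1, β2, α.p, β.e.

One model is fitted per landscape, with site-indexed intercepts inside
it; a per-site fit is a one-line restriction of the inputs. Units with
zero detections anywhere are excluded from fitting (with a warning) — the
community model describes the recorded community; never-detected units
enter the historical index instead.

**Priors.** Community means ~ N(0, sd 2.25) on the logit scale (near-flat
on the probability scale), community sds ~ Uniform(0, 5). With a single
species and `hierarchical=False`, species parameters take the N(0, 2.25)
prior directly.

**Sampler.** Metropolis-within-Gibbs:

* z from its exact full conditional (certain presence at stations with a
  detection; otherwise Bernoulli on the posterior odds of presence given
  no detection across the station's active occasions);
* species-level parameters by adaptive random-walk Metropolis — because
  species are conditionally independent given the hyperparameters, the
  whole community is proposed and accepted per species in one vectorized
  step; (α.p, β.e) move as a joint block, α per (species, site) block,
  β1 and β2 per species. Proposal scales adapt during burn-in toward
  ~35% acceptance and are frozen afterwards;
* community means by conjugate normal full conditionals; community sds by
  shrinkage slice sampling on (0, 5).

The detection layer's per-cell Bernoulli terms are evaluated in a fused
scan (numba-compiled when numba is available, vectorized numpy
otherwise); the scan is refreshed only for species whose detection
parameters moved. The occupancy linear predictor is maintained
incrementally and recomputed from scratch every 500 sweeps to bound
floating-point drift. Any sampler targeting the same posterior is
interchangeable; correctness is pinned by an oracle test comparing
posterior means against dense-grid integration of a 3-parameter
single-species model (agreement within 0.02) and by parameter-recovery
and interval-calibration tests on synthetic communities.

**Chain settings.** Full-scale: 3 chains × 250,000 iterations, 20,000
burn-in, thinned by 20 (`MCMCConfig.full()`). Routine work and the test
suite use `MCMCConfig.desk()` — 3 × 4,000 / 1,000 / thin 2 — which the
recovery tests show is calibrated for communities of ~30 units at ~240
stations. Convergence is assessed with the classic Gelman-Rubin potential
scale reduction factor (not the rank-normalized split variant, whose
values differ; the classic form is what the summary contracts pin down),
computed per scalar parameter across chains; R̂ ≥ 1.1 on any
hyperparameter triggers a warning and marks the result non-converged,
never a silent pass. R̂ is defined as 1 for zero-variance draws.

**Summaries.** Posterior mean, sd, and percentile credible intervals —
95% from the (2.5, 97.5) and 75% from the (12.5, 87.5) percentiles of
the pooled draws, linear-interpolation convention. Effect-size tables
flag whether each interval excludes zero, per species and for the
community means. Site-level occupancy of a unit is the mean of its
station-level ψ over the site's stations, per posterior draw —
station-averaged rather than ψ at mean covariates, so it answers "what
fraction of the site's sampled stations are occupied".

**Effort covariate.** Effort (active days per occasion) is z-scored over
active cells before entering the detection predictor, like the occupancy
covariates; its scaling is otherwise arbitrary and absorbed by α.p.
Zero-effort cells are structural zeros contributing nothing to the
likelihood.

## Covariates

Canopy closure is the vegetation-pixel fraction of binarized upward
photographs (dark = vegetation by convention, polarity flag available),
averaged over a station's five photos (center + four grid corners; fewer
accepted with a warning). Images with more than two distinct values are
rejected — thresholding is a judgment made during photo processing, not
silently applied here.

Village density is Σ_v (1 − (d_v/r)²)² over villages within r = 15 km of
a station — the unnormalized quartic (biweight) kernel. GIS packages
apply various normalization constants; all of them cancel under the
per-landscape z-scoring, so only the relative spatial pattern enters the
model. Distances are Euclidean on projected planar coordinates;
geographic-looking coordinate tables are rejected rather than silently
projected.

Normalization is a per-landscape z-score (sample sd), erroring on
constant columns (the coefficient would be unidentifiable). The
distribution-matching subsetter (for re-running a fit on stations of one
landscape whose canopy distribution matches the other's) is a greedy
in/out swap search minimizing |Δmean|/sd_target + |Δsd|/sd_target from a
seeded random start; the device it supports names no algorithm, and any
subset achieving the target moments serves.

## Occupancy-based defaunation

ψ replaces N in the index; 30,000 Monte-Carlo repetitions each draw one
posterior ψ value per (unit, site) — independently across units and
sites by default, matching a workflow that samples each posterior
separately; `joint=True` reuses one MCMC iteration per repetition,
preserving posterior correlations. The reference site's D is identically
zero by construction (under independent resampling, comparing the
reference against an independent redraw of itself would otherwise yield
spurious spread). Confidence limits are the 2.5/97.5 percentiles of the
D distribution. With degenerate (point-mass) posteriors every repetition
equals the closed-form index exactly. The comparison is defined over the
units recorded in every landscape (species or cross-landscape species
pairs); the pipeline intersects the fitted unit sets.

## Synthetic data

The generator emulates the survey design: per site, stations on a
jittered grid (2.5 km target spacing, ±8% jitter, mean nearest-neighbor
distance within 10% of target), 60-day deployments plus a uniform 0–10
day collection overrun (giving up to seven 10-day occasions and a
variable-effort trailing occasion), site-staggered start dates. Canopy
comes from Gaussian-smoothed spatial noise rescaled to per-landscape
moments (0.77 ± 0.12 degraded, 0.83 ± 0.05 hunted — the contrast of a
structurally varied logged forest against intact hunted forest) and
clipped to [0, 1]; villages are uniform points in a 10 km buffer (8 in
the degraded landscape, 40 in the hunted one), and their kernel density
is computed by the same covariates code the analysis uses. Communities
default to 30 units with occupancy intercepts N(0, 1) (ψ centered at
0.5), detection intercepts N(−1, 0.5) (p ≈ 0.27 per occasion, typical
for camera traps), a positive effort effect N(0.5, 0.25), and the
qualitative driver contrast the analysis is designed to detect:
canopy-driven occupancy in the degraded landscape (μ_β1 = 1, μ_β2 = 0)
and village-suppressed occupancy in the hunted one (μ_β1 = 0,
μ_β2 = −1), with σ = 0.5 on the driving effect and 0.25 on the null one.

Detections are drawn from exactly the process the model assumes, and
records are emitted at occasion granularity (dated to the occasion's
first active day) since nothing downstream uses finer timing. All
randomness flows from one master seed through named per-stage
sub-streams, so stages are independently reproducible.

What the generator does **not** emulate — and hence what passing tests do
not show about field data: temporal clustering of detections within
occasions, behavioral non-independence between neighboring stations,
spatial autocorrelation in occupancy beyond what the smooth canopy field
induces, unmodeled detection heterogeneity (microhabitat, camera
failures), misidentification, and any mechanistic link between village
density and snaring intensity. Recovery results on synthetic surveys
demonstrate the estimator is correct under its own assumptions, not that
those assumptions hold in any particular forest.

## Numerical choices and degenerate inputs

* Occasions are anchored per station at its own deployment start;
  trailing partial occasions are retained with their true effort rather
  than dropped (the model carries effort on detection, so partial
  occasions are information, not bias). Deployment length counts both end
  dates.
* A record dated outside its station's deployment window, an unknown
  station, or a species missing from the trait table is an error naming
  the offender — never silently dropped.
* The index is undefined (error) when no unit is present in either
  assemblage under the given weights; weights must be finite,
  nonnegative, and not all zero.
* Single-value canopy rasters resolve by comparing the value to zero
  under the declared polarity.
* Degenerate ψ posteriors (a single retained draw) are valid inputs to
  the Monte-Carlo propagation and reproduce the closed form exactly.
* Fixed seeds make every stage bit-reproducible; the station-permutation
  test checks posterior invariance distributionally (vectorized samplers
  consume randomness in station order, so bitwise equality across a
  permutation is not expected).

## Problem sizes used in the checks

The recovery and calibration checks run 20 independent synthetic surveys
of 30 units × 240 stations (one landscape, three sites) at desk-scale
MCMC, and the driver-contrast check runs the two-landscape, 480-station
survey at the same settings; the oracle-equivalence check integrates a
3-parameter model on a 121³ grid against 3 × 200,000-iteration chains.
These sizes were chosen so the full battery runs on a single CPU in
minutes while keeping posterior Monte-Carlo error well below the
tolerances being asserted.

## Known limitations

* No spatial autocorrelation terms, no abundance (N-mixture) models, no
  model selection machinery.
* No temporal-independence filtering of records (none is applied to
  occupancy input; the index uses station-level presence only).
* Historical reference assemblages are an input (compiled upstream from
  range maps and expert judgment), not computed.
* Village points arrive as CSV in projected meters; shapefile conversion
  and reprojection are upstream GIS work.
* The adaptive random-walk sampler is adequate for the survey sizes
  above; much larger communities or very sparse detections would warrant
  longer chains (use `MCMCConfig.full()`) and inspection of the R̂
  report.
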