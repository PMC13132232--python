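# Methods

This note documents the statistical models implemented in `surveygam`, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Data model and estimand

Surveys record observations of single males and male-female pairs along
strip transects (two 200 m half-strips, 0.4 km combined width) in a planar
equal-area projection with km units.  Each single male or pair counts as
one **indicated pair** (a lone drake is taken to indicate a nesting
female); lone females and off-transect sightings are excluded, and an
"open" group of size 1 is recoded as a single male (larger open groups are
rejected rather than guessed at).  The population estimand is **indicated
breeding birds** = 2 × indicated pairs, corrected for detection.

Observations are attached to transect segments by nearest perpendicular
distance within their own survey-year, with ties broken to the smaller
segment id and a 1 km gate beyond which a sighting is treated as an orphan
and logged.  The assignment rule is a package decision: recorded
coordinates do not identify the segment directly, and nearest-segment is
the least-assumption choice.  Totals are insensitive to it whenever
segments of one transect are contiguous.

## Design-based estimator

The strip-adapted R3 estimator treats transects (not segments) as the
sampling units, matching the design that randomized/systematized transect
placement:

    N̂ = A Σnᵢ / Σaᵢ,
    var(N̂) = (A/a)² · a/(k−1) · Σ aᵢ (nᵢ/aᵢ − n/a)².

No finite-population correction (counts are not repeatable under animal
movement and imperfect detection) and no detection correction.  95% CIs
are normal-theory and truncated at zero.  A classical ratio estimator is
available behind a flag for comparison only; it degrades when count and
strip area are negatively correlated, as with short coastal transects
holding most birds.  With all-zero counts both N̂ and var(N̂) are exactly
zero — the known failure mode that motivates the model-based estimator.

## Density GAM

Segment counts are modelled as

    countᵢ ~ NB(μᵢ, θ),  var = μ + μ²/θ,
    log μᵢ = xᵢ′β + log(areaᵢ),

so the linear predictor is log expected indicated pairs per km².  The
model menu is

    M0: s(X,Y)
    M1: s(X,Y) + s(Year)
    M2: s(X,Y) + s(Year) + ti(X,Y,Year)
    M3: s(X,Y) + s(Year) + s(fYear)
    M4: s(X,Y) + s(fYear)

optionally plus an observer random effect and/or a fixed survey factor
for combined-survey fits.

**Bases.**  All smooths are tensor-product cubic B-splines with
second-order difference penalties (P-splines).  The contract is the
penalty structure, not the basis family: any quadratic roughness penalty
with the same null space serves, and the basis family is recorded in the
fit metadata (`basis="ps"`).  Coordinates are centred and scaled by the
*mean* of the X and Y standard deviations (one common scale), and the 2D
smooth uses the isotropic penalty Sx⊗I + I⊗Sy under a single smoothing
parameter, so spatial roughness is direction-free after standardization.
Year is standardized separately.  Default basis dimensions: k = 30
spatial (6×6 margins), k = 10 temporal, (5,5,5) tensor margins —
comfortably above the effective degrees of freedom such surveys support.
Basis dimensions are reduced with a warning when they exceed the unique
covariate support (systematic east-west designs can have very few unique
y values).

**Space×time interaction.**  `ti(X,Y,Year)` is built from two margins —
the 2D spatial surface and the 1D year smooth — each sum-to-zero centred
before their row-wise tensor product, with one penalty per margin and a
final overall centring.  Centring both margins removes everything
constant in space or constant in time, so the term is a pure interaction
excluding the main effects beneath it (functional ANOVA).  Using a
(space, time) margin pair rather than three 1D margins keeps two-way
structure such as a planar tilt drifting through years *inside* the term;
a product of three centred 1D margins would exclude it, leaving the model
unable to represent exactly the kind of drift these surveys exhibit.
The interaction's penalty null space is the linearly drifting plane.

**Constraints.**  Every spline term is reparameterized into the null
space of the constraint 1′B β = 0, so fitted smooth terms average to zero
over the fitting data and the intercept carries the overall level.
Random-effect terms (year/observer as factor levels with an identity
penalty) are left unconstrained, as usual for ridge random effects; fixed
factors are treatment-coded against their first level.

**Fitting.**  Inner loop: penalized IRLS (Fisher scoring with step
halving) for β at fixed (λ, θ), converged when the penalized deviance is
stationary to 1e-8 relative *and* the coefficient step is below 1e-8
relative — the second condition matters because Fisher scoring converges
linearly and a deviance-only stop leaves coefficients ~√tol short.
Outer loop: Nelder-Mead over (log λ, log θ) maximizing the
Laplace-approximate restricted marginal likelihood

    V = ℓ(β̂) − ½β̂′S β̂ + ½log|S|₊ − ½log|X′WX + S| + ½Mₚ log 2π,

with |S|₊ the blockwise pseudo-determinant (exact for single-penalty
terms, top-rank eigenvalues for multi-penalty tensor blocks) and W the NB
working weights.  The simplex starts with O(1) steps in log-λ space
(scipy's default simplex around a zero start is ~2.5e-4 wide and stalls
immediately) and stops at 1e-4 absolute in the criterion / 1e-2 in the
parameters: tighter outer tolerances chase the inner-IRLS noise floor
rather than real precision.  log λ is clipped to ±18 and θ to
[1e-4, 1e7]; the linear predictor is clipped at ±30 before
exponentiation.  All-zero counts are rejected as degenerate.

**Effective degrees of freedom and AIC.**  edf = tr[(X′WX+S)⁻¹X′WX],
summed per term; unpenalized columns count fully.  Model comparison uses
"edf-AIC" = −2ℓ + 2·edf.  This is the trace-based df, not the
degeneracy-corrected GAM df of more elaborate treatments; consequently
absolute AIC/df values from other software will differ, while *rankings*
on clear-cut comparisons agree (verified on simulated data where the
generating model is known).  Candidates that fail to converge are
reported and excluded from a ranking, not fatal; ties break to smaller
edf.

**Coefficient posterior.**  V_b = (X′WX + S)⁻¹, the Bayesian covariance
of the penalized fit at scale 1 (θ enters the weights).  At λ = 0 this
reduces to the classical GLM covariance (checked against an independent
GLM implementation).

**Diagnostics.**  Randomized-quantile residuals from the exact NB CDF
(uniform under a correct model), the Pearson dispersion ratio, and an
observed/expected zero-fraction ratio with the expectation simulated from
the fitted model.

## Posterior simulation of totals

The study area is gridded into ≤1 km² cells (boundary cells clipped, so
cell areas sum to the study area); predictions use cell centroids, no
offset, with factor covariates fixable (e.g. the survey factor set to the
dense-survey baseline).  Coefficient draws come from

* **MVN**: bᵢ ~ N(β̂, V_b) via symmetric eigen-factorization with negative
  eigenvalues clipped at zero — the default for dense surveys; or
* **Metropolis-Hastings** targeting exp(penalized log-likelihood),
  alternating a multivariate-t independence proposal (df 4, shape V_b)
  with a Gaussian random walk (0.25² V_b), reporting acceptance rates —
  preferred for sparse surveys where large empty regions make the
  Gaussian approximation optimistic.  Proposal scales, burn-in (200) and
  thinning are exposed as configuration; the defaults give 40–80%
  acceptance on the fits tested here.

Totals: Yᵢⱼ = Σₖ aₖ exp(x′ⱼₖ bᵢ) per draw i and year j — an expectation,
hence strictly positive.  Detection: one draw dᵢ per posterior draw from
the Beta prior, constant across years within a draw (the decoy study
estimates an average rate) and independent of the coefficient draws;
Nᵢⱼ = 2Yᵢⱼ/dᵢ.  Trends T = (log N_{j+t} − log N_j)/t are computed per
draw; a constant-per-draw detection cancels from them exactly.
Summaries use the mean and type-7 (linear interpolation) 0.025/0.5/0.975
quantiles.  Models whose only temporal structure is a year random effect
refuse prediction years outside the fitted levels: a pure random effect
has nothing to interpolate with.

## Detection prior

Per-distance-bin detection estimates (mean, 95% interval) are averaged
with equal weights — the design makes birds uniform in distance and bins
are equal-width — with per-bin SE recovered as (hi−lo)/(2·1.96).  The
overall variance is the *mean of the bin variances*, deliberately not
divided by the bin count: the target is the uncertainty of a detection
draw applied to an observation, not the standard error of the averaged
mean — only this reading propagates a realistic ~0.09 SD into the
population posterior.  Moment matching gives ν = m(1−m)/s² − 1,
α = mν, β = (1−m)ν.  The canonical configured prior is mean 0.307,
SD 0.092 (α ≈ 7.41, β ≈ 16.73; 5th/95th percentiles ≈ 0.165/0.467,
i.e. a 2–6-fold population correction).  Whether the source intervals
were symmetric is not knowable from the published summary; the SE
recovery assumes they were.

## Wavelet analysis

Annual series are standardized, zero-padded to the next power of two, and
transformed with a Morlet mother wavelet (ω₀ = 6) over the geometric
scale ladder s_j = s0·2^{j·dj}, defaults dt = 1 yr, dj = 1/20, s0 = 2dt,
J reaching period ≈ series length; period = scale × 4π/(ω₀+√(2+ω₀²)).
Power is the squared modulus; detection uses the time-averaged power per
period.  Significance: 200 Gaussian white-noise simulations of the same
length; p per period is the fraction of simulations with average power at
or above the observed.  The dominant period is the argmax of average
power (ties to the smallest period, logged; an argmax within three steps
of either ladder end is flagged as a boundary hit).  Its 95% interval
perturbs the observed average-power curve by each simulation's deviation
from the null mean and collects the perturbed argmaxes — a
null-calibrated bootstrap of the package's own construction; it makes no
claim to reproduce any particular toolkit's internal interval.  Series
are standardized but *not* detrended by default (a cycle and a slow trend
can coexist; detrending would destroy the long-period component), and
boundary-affected times are reported via the cone of influence but not
excluded from the time average — on a 25-point series excluding them
would leave almost nothing.  The posterior of the dominant period maps
each posterior draw of the population series through the same analysis.

## Synthetic surveys

The generator emulates the statistical structure the analysis assumes:
log intensity = log baseline + coastal gradient (linear in y) + sinusoidal
log-scale cycle (default period 6.5 yr, amplitude 1 → ≈ e² ≈ 7.4-fold
swings) + optional linear space×time drift + optional Gaussian hotspot;
NB(μ, θ) latent counts per generation segment; Binomial(latent, d)
detection thinning (so the thinned marginal is NB(dμ, θ) and the
detection correction has a true latent target); observations placed
uniformly in their segment strip; systematic east-west transects with a
uniform random start per stratum.  A truth record carries the numeric
integral of intensity per year (midpoint rule on a 0.25 km lattice,
accurate to ≪0.5% for these smooth surfaces) and the per-segment
latent/observed counts.  Presets:

* `triangle_like` — triangular area of 216 km², 1.1 km spacing (36%
  coverage), 25 consecutive years, baseline 0.3 pairs/km², gradient 1.5,
  θ = 1.5, d = 0.307 → ≈ 380 observed pairs over the series, matching
  the rare-species regime of a dense coastal survey.
* `acp_like` — 2400 km² rectangle, two strata (7 and 10 km spacing: 5.7%
  and 4% coverage), 16 surveyed years of 2007–2024 with 2020–2021
  missing, baseline 0.05, gradient 2 → a handful of observations per
  year, frequent zero strata.
* `combined` — both at once, overlapping region, with a log 0.4
  survey-level offset on the sparse survey's counts.

What the generator does **not** emulate: flushing/flocking behaviour,
availability-vs-perception components of detection, observer-specific
biases (observer labels can be attached but carry no effect), covariate
drivers of the cycle, non-sinusoidal cycle shapes, and irregular transect
geometry.  Passing tests therefore demonstrate correct inference *under
the assumed data-generating structure*, not robustness to violations of
it.

## Problem sizes used in the test suite

Test problem sizes are chosen as the smallest that make each property
sharp: the dense-survey recovery test uses one `triangle_like` replicate
(25 years, ~5100 segments, 500 posterior draws); the design-estimator
unbiasedness check uses 500 single-year replicates of a small flat
square; the shrinkage comparison uses 200 `acp_like` replicates with
60-draw posterior means (point summaries need far fewer draws than
intervals); wavelet calibration uses length-64 series and 200 bootstrap
simulations.

## Known limitations

* AIC uses trace-based edf; absolute values are not comparable with
  software using corrected df.
* The REML criterion uses the Laplace/working-weight approximation
  throughout; θ is selected jointly with λ on the same criterion rather
  than by an exact marginal.
* Variance of the design estimator can overstate uncertainty under
  systematic designs with strong gradients (inherited property of the
  estimator, not corrected here).
* Spatially varying detection is out of scope: the correction applies at
  the year-total level; a per-cell correction would need to enter below
  the totals.
* Segment-level covariates other than location, year, observer and survey
  are not supported.
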