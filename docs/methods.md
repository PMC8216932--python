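# Methods

## Mid-domain-effect null model

The domain is the ordered set of `D` discrete, evenly spaced sampling
positions `1..D`, suitable for transects sampled at constant elevational
steps. Each species contributes its **interpolated range**: the contiguous
block between its lowest and highest occupied positions, interior gaps
filled (`r = hi − lo + 1`). This is the convention of the classical
bounded-domain null-model lineage; the alternative (occupied-site count)
would understate geometric overlap for patchily detected species.

The null hypothesis keeps every empirical range size fixed and re-places
each block uniformly over its `D − r + 1` feasible start positions — ranges
must sit wholly inside the domain, which is the constraint that concentrates
overlap mid-domain. Placement of a start position uniform over feasible
starts is equivalent to a uniform feasible midpoint, so the distinction has
no effect here. Each Monte Carlo replicate places the full multiset of
empirical range sizes exactly once (sizes are never resampled), and per-site
richness is recorded; the expectation is also available in closed form as
`E[S_j] = Σ_s c(j, r_s)/(D − r_s + 1)` with `c(j, r)` the number of
placements covering `j`. Two invariants pin the implementation down: every
replicate conserves `Σ_j S_j = Σ_s r_s` exactly, and the expected curve is
symmetric about the domain midpoint.

Confidence bands use the percentile method (2.5th/97.5th percentiles of
replicate richness per site) rather than a normal approximation, which
misbehaves at the low, discrete richness typical of edge sites. The
production default is 100,000 replicates; tests and the bundled experiments
use 2,000–20,000, which puts Monte Carlo error on per-site means well below
0.1 species at the survey scale used here.

## Candidate models and information-theoretic comparison

Per-site richness is modelled by Gaussian identity-link GLMs (ordinary least
squares) on natural-log-transformed predictors: the MDE expectation, the
vegetation-type (VT) and community-type (CT) counts as habitat-complexity
indices, solar radiation (SR) for the energy hypothesis, and annual
precipitation (AP), mean temperature (AT) and wind speed (WS) for the
environment hypothesis. The Gaussian family is what adjusted R² and
standardized partial slopes presuppose; predictors are z-scored after the
log transform so slopes are standardized, while the response stays on the
species scale. Log transforms require strictly positive inputs; VT/CT
counts are ≥ 1 at any surveyed site and MDE expectations are > 0 whenever a
species pool exists, and a violation raises an error naming the offending
variable and site.

`AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1)` counts `k` as intercept + slopes +
residual variance (so the intercept-only model has k = 2). Candidates whose
VIF reaches 10 are excluded before Akaike weights are computed; exact
collinearity reports an infinite VIF rather than failing. Variable
importance is the sum of weights over candidate models containing the
variable (coefficients are not averaged — importance is the estimand of
interest here). Forward stepwise selection adds, at each stage, the variable
with the lowest resulting AICc and stops as soon as no addition strictly
lowers AICc; no ΔAICc threshold is imposed.

Uncertainty bands for fitted curves are produced by simulation from the
estimated sampling distribution: σ² drawn from its scaled inverse-χ²
distribution, then β ~ N(β̂, σ²(XᵀX)⁻¹). Under a flat prior this is exactly
the Gaussian linear model posterior, so the percentile bands double as
credible intervals and converge to the classical t-based confidence band
(the test suite checks agreement within 5% relative width).

## Additive partition and the elevation split

γ = ᾱ + β with ᾱ the mean site richness. β is split against a predicted
richness curve — either the MDE null mean or the quadratic polynomial fit of
richness on elevation — as β_elevation = S_max − ᾱ, β_replace = β −
β_elevation, where **S_max is the maximum of the predicted curve over
sites**, not the fitted value at the richest site. A predicted maximum below
ᾱ (possible for badly misspecified curves) is clamped to β_elevation = 0
with a warning rather than propagated as a negative component.

The **contribution of elevation** is defined as
`100 · S_max / max observed site richness`: the share of the richest site's
diversity that the elevational curve can account for. This definition is a
package design choice — it is the unique simple formula under which the
contribution and the β_elevation share are mutually consistent through the
identity `β_elevation = (contribution/100) · max_obs − ᾱ`, a reconciliation
the test suite enforces on every dataset. It is isolated in
`partition.contribution_of_elevation` so an alternative definition can be
substituted without touching the partition arithmetic. Percentages are
reported at one decimal place with half-up rounding; derived summaries
(e.g. the replace:elevation ratio) are computed from the reported
one-decimal figures, matching how such summaries are conventionally quoted.

## Habitat use

Per-family occurrence is a binomial logistic GLM on standardized elevation
with linear and quadratic terms. Curve shape is classified from the
coefficients: a quadratic term beyond 1.96 SE of zero with the vertex inside
the observed span gives "hump" (negative curvature) or "u"; a vertex outside
the span demotes to a monotone label; otherwise the linear term decides
increasing/decreasing/flat. The 1.96 SE gate and the vertex-in-span rule are
explicit, configurable thresholds, not tuned constants. Complete separation
is detected (non-convergence or exploding estimates) and handled by a
ridge-penalized refit flagged on the result.

Substrate use per family is a multinomial logit of the community type
(aquatic, stone, soil, woody) on elevation, reference category soil (the
most ubiquitous substrate; configurable). Default inference is maximum
likelihood with parametric-bootstrap bands. An optional random-walk
Metropolis mode samples the same likelihood under flat priors — two chains
of 10,000 iterations, burn-in 1,000, thinned by two, convergence by split
R-hat — and is provided as a cross-check: with flat priors the estimands
coincide, and the tests confirm ML and posterior means agree within Monte
Carlo error. Fitted category proportions sum to 1 at every elevation by
construction.

## Synthetic data generator

The generator emulates a temperate-montane moss survey: 73 sites at ~19 m
spacing over 923–2,282 m, 191 species in 26 families with a skewed family
composition, and mean site richness near 12.8. Range sizes are truncated
geometric with mean ᾱ·D/γ ≈ 4.9 sites — many narrow species, few wide ones,
matching the low mean occupancy such surveys report. Placement regimes:

- `mde_uniform` — uniform feasible placement; the MDE null is the true
  process.
- `covariate_driven` — placement probability proportional to
  `exp(effect · mean standardized driver over the covered sites)`, by
  default driven by the CT count, so habitat complexity causes richness.
- `mixed` — each species drawn into one regime by a Bernoulli weight.

Covariates follow the emulated system's reported behaviour: CT count is
hump-shaped (peak ~1,500 m, maximum 4); temperature falls and precipitation,
wind speed and solar radiation rise smoothly with elevation; VT count is
trendless noise. VT and SR deliberately carry **no** richness signal because
the emulated survey found them uninformative (adjusted R² ≈ 0 for both); a
hump-shaped VT or SR would manufacture a spurious correlate of the
mid-elevation richness peak that the real system does not contain. Within a
placed range, occupancy defaults to 1 (full occupancy, consistent with
interpolated-range analysis); an occupancy-thinning option exists and always
keeps the range endpoints so the realized extent equals the placed range.

What the generator does **not** emulate: spatial autocorrelation beyond the
elevational trend, detection error, temporal turnover, and the
speciation/dispersal/extinction dynamics that shape real β-diversity.
Passing recovery tests therefore show the estimators identify the generating
process among the stated alternatives under clean conditions — not that the
same contrasts are identifiable in noisier field data.

## Recovery experiments

The bundled experiments (also run by `scripts/acceptance.py`) use a *strong*
generating signal, since identifiability claims are only meaningful when the
generating effect is strong: mean range size 20 sites for the MDE regime
(wide ranges make the geometric hump pronounced) and covariate effect 3.0
for the CT regime. Success is defined as the AICc-best candidate
*containing* the generating predictor. Exact-candidate identification is not
attainable in principle when candidates are nested: AICc admits one
pure-noise extra variable (here VT alongside CT) at a fixed ~15% rate
regardless of effect size, which is a property of the criterion, not of the
data or the fit. At the survey's own signal strength (mean range ≈ 4.9
sites, observed MDE R² ≈ 0.25-class signals), exact recovery runs in the
80–90% range — reported here for transparency, not as a test target.

## Numerical notes

- Site order: ascending elevation, ties broken by site ID; positions are
  1-based along the ordered gradient.
- Species with zero presences are dropped with a warning by default (they
  cannot enter range-based analyses); all-zero *sites* are accepted and
  flagged, since a surveyed site genuinely can hold no focal taxa.
- A constant response in polynomial selection short-circuits to the
  intercept-only model (every degree fits exactly; parsimony decides).
- Monte Carlo richness uses a start/stop difference-array accumulation,
  chunked over replicates, so memory stays bounded at large replicate
  counts.
- The pipeline fans one global seed into per-stage child seeds via a
  `SeedSequence` spawn; fixed seed ⇒ bit-identical artifacts.
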