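# elevpart

Analysis toolkit for **elevational species-richness gradients**, built around
three questions ecologists ask of a site-by-species survey along a mountain
transect:

1. **Is the richness peak just geometry?** A discrete bounded-domain
   *mid-domain-effect* (MDE) null model re-places each species' empirical
   elevational range uniformly within the domain; overlap of randomly placed
   ranges alone produces a mid-elevation hump. The package provides both the
   closed-form expectation and a Monte Carlo randomization with percentile
   confidence bands.
2. **Which hypothesis best explains richness?** Candidate Gaussian GLMs
   (MDE, habitat complexity via vegetation/community-type counts, energy via
   solar radiation, environment via precipitation/temperature/wind) are
   ranked by AICc with Akaike weights, screened for collinearity (VIF < 10),
   and searched by forward stepwise selection.
3. **How much among-site heterogeneity does elevation explain?** Additive
   diversity partitioning, γ = ᾱ + β, with β further split against a
   predicted richness curve: β_elevation = S_max − ᾱ and
   β_replace = β − β_elevation, where S_max is the maximum of the MDE or
   quadratic-regression prediction.

Family-level habitat use (quadratic-logistic occurrence curves and
multinomial substrate-use curves) and a ground-truthed synthetic-data
generator for a 73-site montane moss survey round out the pipeline.

## The core model

For a domain of `D` evenly spaced sites and a species with interpolated
range size `r` (highest minus lowest occupied position + 1), uniform
placement over the `D − r + 1` feasible positions gives the expected
richness at site `j`:

```
E[S_j] = Σ_s c(j, r_s) / (D − r_s + 1),
c(j, r) = min(j, D − r + 1) − max(1, j − r + 1) + 1
```

Model comparison uses `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)` (k counts
intercept, slopes and the residual variance) and Akaike weights
`w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`.

## Worked example

```bash
elevpart simulate --seed 7 --out-dir syn          # synthetic survey, MDE-true
elevpart mde syn/occurrence.csv --reps 20000 --seed 7 --out pred.csv
```

```
observed ~ predicted: R^2 = 0.507, p = 1.69e-12; wrote pred.csv
```

The regression of observed on null-predicted richness shows the geometric
null explaining about half the variance in this realization — expected,
since the data were generated with uniform range placement. Continuing:

```bash
elevpart select syn/occurrence.csv syn/covariates.csv --predictions pred.csv
```

prints the candidate table (AICc-sorted; here MDE wins with weight ≈ 1.00
and the habitat/energy/environment candidates fall ≥ 2 AICc behind), and

```bash
elevpart partition syn/occurrence.csv --predictions MDE pred.csv
```

reports `gamma = 191`, `alpha_bar ≈ 12.1`, `beta ≈ 178.9` with the
elevation split (`beta_elevation_share_pct ≈ 1.4`): even when elevational
geometry shapes the richness curve, almost all among-site heterogeneity is
species replacement — individual sites hold small, idiosyncratic subsets of
the regional pool. The full pipeline (`elevpart run --config cfg.yaml`)
writes `predictions.csv`, `model_table.csv`, `stepwise.csv`,
`partition.json`, `habitat_curves.csv` and a seeded run manifest.

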