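# Methods

## The biometric model

For `p` traits measured on both members of a twin pair, the stacked
2p-vector of observations is modelled as multivariate normal with mean
`(μ, μ)` and covariance

```
Σ_zyg = [ A + C + E      ρ·A + C   ]
        [ ρ·A + C        A + C + E ],    ρ = 1 (MZ), 0.5 (DZ)
```

where A, C and E are the additive-genetic, shared-environment and
unique-environment covariance contributions.  The contrast between MZ and DZ
cross-twin blocks identifies A against C; E is always present because it
absorbs measurement error.  Dominance (D) is only flagged by the
correlation-pattern heuristic (rMZ > 2·rDZ) and never fitted, and
sex-limitation, gene–environment interplay and liability-threshold
likelihoods are out of scope; composites are treated as continuous.

**Estimation.** Full-information maximum likelihood: complete pairs
contribute the 2p-variate density, unpaired responders the p-variate
marginal (A + C + E), and missing entries within a record drop the
corresponding rows/columns.  Records are grouped by (zygosity ×
missingness pattern) and each group is evaluated from its sufficient
statistics (count, mean, scatter); this is algebraically identical to
record-wise evaluation (verified against a dense per-record oracle in the
tests) and makes a 4-variate fit take well under a second.  Whether singles
enter the twin likelihood is a flag (`include_singles`, default on, the
natural choice for full-information estimation).

**Parameterizations.** `cholesky` writes each component as L·Lᵀ (PSD by
construction; the default); `direct` leaves the symmetric matrices
unconstrained, so negative variance estimates are possible and standardized
shares outside [0, 1] are reported as-is with a warning rather than
truncated.  Both reach the same −2LL whenever the direct optimum is PSD
(tested).

**Optimization.** L-BFGS-B with numerical gradients from a
phenotypic-covariance start (the pooled sample covariance split evenly
across the included components), with `n_starts` (default 5)
multiplicatively jittered restarts.  A fit is flagged converged when the
implied covariances are PD at the optimum, the gradient is small, and the
best two starts agree within 0.01 −2LL units.  Non-PD implied covariances
during the search return a large penalized value (1e10, scaled by the
magnitude of the most negative eigenvalue) instead of raising, so the
optimizer can retreat.

**Model comparison.** Δ−2LL between nested fits is referred to χ² with the
parameter-count difference as df; negative deltas (optimizer noise) are
clipped to zero with a warning.  AIC = −2LL + 2k.  The more parsimonious
model is preferred when p ≥ 0.05.  No chi-bar-square boundary correction is
applied when a variance component sits on the zero boundary — the same
convention as the standard likelihood-ratio reporting this mirrors; the
type-I rate of e.g. ACE-vs-AE is therefore conservative.

**Confidence intervals.** Profile likelihood by default: the bound on a
scalar quantity (a standardized share, an rA/rE cell, a shared fraction) is
where the re-optimized −2LL rises by χ²₁(0.95) = 3.841, found by an
expanding bracket plus bisection to 1e−4 on the quantity scale, with the
constrained re-optimization done by SLSQP.  Bounds that never reach the
critical rise inside the quantity's natural window ([0, 1] for shares,
[−1, 1] for correlations) are returned at the window edge and flagged open.
If constrained re-optimization fails, a Wald interval from the numerical
Hessian (delta method) is used and a warning logged.

**Assumption tests.** On complete pairs, a saturated two-group model (free
2p mean and free 2p×2p covariance per zygosity, within-pair symmetry not
imposed) is compared against a chain of constraints: means equal within
pairs, means also equal across zygosity, and variances equal within pairs
and across zygosity (off-diagonal covariances stay free per group).
Constrained covariances are parameterized directly with a non-PD penalty.

**Descriptives.** Twin intraclass correlations are Pearson correlations of
(twin 1, twin 2) over complete pairs with SE = (1 − r²)/√(n − 1); this
analytic form reproduces the printed standard errors of the reference
descriptive tables exactly after rounding.

## Multivariate structure

Genetic and environmental correlations are read off the fitted component
matrices: rA_ij = A_ij/√(A_ii·A_jj).  Cells with a nonpositive diagonal are
reported as NaN.  For the ordered Cholesky, predictors are entered by
descending |β| from the clustered regression (ties broken by inventory
order and logged, since unrounded coefficients are unavailable) and the
target last; the target's shared fraction in component X is
Σ_{j<t} l_tj² / Σ_{j≤t} l_tj², which in the bivariate standardized case
equals rX² exactly.  Joint fits are intended for the screened facet sets
(up to ~8 predictors); beyond ~11 variables the numerical-gradient
optimizer becomes slow and the pipeline refuses by configuration rather
than silently degrading.

## Phenotypic layer

GEE with a Gaussian family, exchangeable working correlation by default
(the natural choice for twins; independence is available) and the
family-clustered sandwich covariance, via statsmodels.  Standardized betas
come from z-scoring the response and all non-binary predictors before
fitting; binary covariates (sex) stay on their 0/1 scale.  Marginal R² is
the squared Pearson correlation between fitted and observed values.
Benjamini–Hochberg adjustment is applied within each regression model over
the facet p-values only, excluding the age and sex covariates.  Facets pass
to the twin models when their raw p < 0.01.  Phenotypic correlations use
one member per family (deterministically twin order 1, plus all singles) to
avoid the within-family dependence; any deterministic member-selection rule
moves r only in the third decimal at these sample sizes.

## The synthetic-data generator

The generator emulates the study conditions the package is validated under:
same-sex MZ/DZ pairs (defaults 431/190 complete pairs, with unpaired
responders addable either directly or by `drop_to_singles`), age uniform on
31–55 years, sex Bernoulli(0.66) shared within a pair, standardized trait
scales, and the published four-dimension generating values (a² =
0.50/0.40/0.38/0.52 with the corresponding rA/rE matrices, verified PSD).
Genetic latents use g_i = √ρ·g_pair + √(1−ρ)·g_own coloured by a factor of
A, which reproduces the required cross-twin correlation exactly for any PSD
A (including singular ones, via an eigenvalue factor).  Age enters the mean
model centred at the mid-range so standardized specs stay standardized in
expectation.  Likert items are generated by thresholding
±loading·trait + acquiescence + uniqueness noise at four increasing cut
points; acquiescence is a single person-level intercept shared by all items
regardless of keying, which is exactly what the un-recoded mean of a
balanced inventory recovers.  Missingness from `drop_to_singles` is
completely at random — the study's actual missingness mechanism is unknown.

What the generator does **not** emulate: non-normal trait distributions,
assortative mating, gene–environment correlation or interaction,
opposite-sex DZ pairs, item-level local dependence, or informative
missingness.  Passing recovery tests therefore show that the estimators are
correct under the stated model, not that the model is correct for any given
real dataset.

## Preprocessing choices

Acquiescence is the mean of the raw (un-recoded) responses to a perfectly
balanced inventory minus the scale midpoint — the standard
operationalization when half the items are reverse-keyed, and the only one
available without item-level modelling.  Composites are means of recoded
items, requiring at least half the (non-excluded) items answered; item
exclusion supports sensitivity analyses such as removing a
domain-overlapping item from a facet.  The adjustment order is:
acquiescence regression (target scales only, standardized residuals), then
age/sex OLS residualization of every analysis variable, then twin
modelling — mean effects removed first so they cannot masquerade as C.
Cronbach's alpha uses complete-case rows and the classical
k/(k−1)·(1 − Σs²ᵢ/s²ₜ) form (cross-checked against an independent
implementation in the tests).

## Problem sizes used in validation

Simulation-based checks run at the study's complete-pair counts (418 MZ,
188 DZ) with 50 seeded replicates for recovery of shares and correlations,
80 replicates for profile-CI coverage, and up to 10⁵ pairs for the
moment-level generator checks; these sizes give Monte-Carlo error
comfortably inside the stated tolerances (±0.03 on variance shares, ±0.05
on component correlations) while keeping the full suite in a couple of
minutes.  Noiseless oracles (moment-matched cohorts, whose sample moments
equal the implied moments exactly) are used wherever an exact recovery
statement is possible.

## Known limitations

- No ADE/ACDE, sex-limitation or heterogeneity models; D is flagged, never
  fitted.
- Numerical gradients make very high-dimensional Cholesky fits (≫10 traits)
  slow; analytic gradients would be the natural extension.
- Profile CIs assume a unimodal likelihood in the profiled quantity; flat
  ridges (e.g. A vs C at small DZ counts) can make bounds sensitive to the
  bracket and are flagged only through the convergence diagnostics.
- The acquiescence correction assumes the response style is additive and
  uniform across items; pattern-based styles (extreme responding) are not
  modelled.
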