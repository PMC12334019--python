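# twinace

Classical twin-design analysis of questionnaire composites: cohort
simulation with known genetic/environmental structure, acquiescence-aware
preprocessing, full-information maximum-likelihood (FIML) biometric
modelling, ordered Cholesky decomposition, and cluster-robust phenotypic
association.

## The problem

Monozygotic (MZ) twins share all of their segregating genes; dizygotic (DZ)
twins share on average half.  Comparing trait similarity across the two
groups lets one partition phenotypic variance into additive genetic (A),
shared-environment (C) and unique-environment (E) components: for a twin
pair the within-person covariance is A + C + E while the cross-twin
covariance is A + C (MZ) or ½A + C (DZ).  `twinace` implements this model
for multivariate questionnaire composites — e.g. music-use-motivation
subscales alongside personality facets — estimated by FIML so that unpaired
responders and partially missing records still contribute their marginal
likelihood.  On top of the variance decomposition it provides

- **genetic and environmental correlations** rA<sub>ij</sub> =
  A<sub>ij</sub>/√(A<sub>ii</sub>A<sub>jj</sub>) (rE analogous) with
  profile-likelihood confidence intervals,
- **ordered Cholesky decompositions** that split a target trait's genetic
  and environmental variance into the part shared with predictor traits
  entered before it and the part unique to it,
- **saturated-model assumption tests** (equal means/variances across twin
  order and zygosity),
- a **phenotypic layer**: GEE regression with family-clustered sandwich
  standard errors, Fisher-z correlation intervals, and Benjamini–Hochberg
  FDR control, feeding a p < 0.01 facet screen for the twin models, and
- a **synthetic-cohort generator** (twin correlation structure, 5-point
  Likert items with an acquiescence response style, age/sex mean effects,
  unpaired responders) so every stage is testable without restricted data.

## Worked example

Simulate a bivariate AE cohort at realistic sample sizes (418 MZ and 188 DZ
complete pairs) with heritabilities 0.50/0.40, genetic correlation 0.85 and
environmental correlation 0.75, then refit it:

```python
from twinace import (BiometricSpec, simulate_phenotypes, fit_biometric,
                     compare_models, intraclass_corr, profile_ci,
                     share_quantity, heuristic_components)
from twinace.multivariate import genetic_env_correlations

spec = BiometricSpec.from_standardized(
    [0.50, 0.40], rA=[[1, 0.85], [0.85, 1]], rE=[[1, 0.75], [0.75, 1]],
    trait_names=["transcendence", "emotion_regulation"])
cohort = simulate_phenotypes(spec, n_mz=418, n_dz=188, seed=42)

icc_mz = intraclass_corr(cohort, "transcendence", "MZ")
icc_dz = intraclass_corr(cohort, "transcendence", "DZ")
print(f"rMZ = {icc_mz.r:.2f} ({icc_mz.se:.2f}),  "
      f"rDZ = {icc_dz.r:.2f} ({icc_dz.se:.2f})")

ace = fit_biometric(cohort, components=("A", "C", "E"), seed=0)
ae = fit_biometric(cohort, components=("A", "E"), seed=0)
cmp = compare_models(ace, ae)
print(f"ACE vs AE: d-2LL = {cmp.delta_minus2LL:.3f}, df = {cmp.delta_df}, "
      f"p = {cmp.p_value:.3f}, dAIC = {cmp.delta_aic:.3f} -> {cmp.preferred}")

lo, hi = profile_ci(ae, share_quantity("A", 0))
print(f"a2(transcendence) = {ae.standardized['A'][0]:.2f} [{lo:.2f}; {hi:.2f}]")
rA, rE = genetic_env_correlations(ae)
print(f"rA = {rA[0,1]:.2f}, rE = {rE[0,1]:.2f}")
```

Output:

```
rMZ = 0.47 (0.04),  rDZ = 0.34 (0.06)
ACE vs AE: d-2LL = 1.663, df = 3, p = 0.645, dAIC = -4.337 -> AE
a2(transcendence) = 0.49 [0.42; 0.56]
rA = 0.87, rE = 0.76
```

Reading the output: the MZ pairs are clearly more alike than the DZ pairs
(twin correlations 0.47 vs 0.34, standard error (1−r²)/√(n−1) in
parentheses), so genetic influences are indicated.  Dropping C costs no fit
(p = 0.645) and improves AIC, so the AE model is preferred.  It attributes
49% of the transcendence variance to additive genetic effects, with a
profile-likelihood 95% CI of [0.42; 0.56], and recovers the strong genetic
(0.87) and environmental (0.76) overlap between the two composites — all
close to the generating values, as they should be at this sample size.

A full pipeline (simulate → preprocess → descriptives → assumption tests →
model menu → association → decomposition → report tables) runs from a YAML
config via the console script:

```sh
twinace all config.yaml        # or: twinace simulate / fit / assoc / ...
```

## Layout

| module | contents |
| --- | --- |
| `twinace.cohort` | `TwinCohort` container, CSV schema and sidecar metadata |
| `twinace.simulate` | generating specs, phenotype/Likert simulation, singles |
| `twinace.preprocess` | acquiescence score/adjustment, composites, alpha, residualization |
| `twinace.biometric` | FIML engine, ACE/AE/CE/E fits, profile CIs, assumption tests, ICCs |
| `twinace.multivariate` | rA/rE matrices, beta-ordered Cholesky, shared/unique split |
| `twinace.association` | GEE with sandwich errors, Fisher-z CIs, BH-FDR, facet screen |
| `twinace.pipeline`, `twinace.cli` | staged workflow, report tables, console script |

See `docs/methods.md` for the model details, numerical choices and known
limitations.
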