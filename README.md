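# satsem

Satisfaction-index structural equation modelling for ordinal surveys:
PLS path models with second-order constructs, classical-test-theory and
item-response-theory item screening, bootstrap and multigroup inference,
and the full measurement/structural assessment suite.

## The problem

Public-satisfaction instruments in the ACSI (American Customer
Satisfaction Index) tradition model satisfaction as a node in a causal
chain of latent variables: public expectations (PE) drive perceived
quality (PQ) and perceived value (PV); all three drive public
satisfaction (PS); satisfaction raises public trust (PT) and lowers
public complaints (PC).  Each latent variable is reflected by a block of
ordinal survey items.  `satsem` implements the complete workflow used to
build and validate such an instrument for China's urban and rural
resident-based basic medical insurance scheme (URRBMI), where perceived
quality is a second-order construct over five first-order facets
(overall, information, service, policy, and institution quality), with
28 measurement variables on a ten-category scale.

The package is for biostatisticians and health-services researchers who
need to (i) screen a draft item pool with the combined CTT + IRT criteria,
(ii) estimate the path model by PLS-SEM with a higher-order construct,
and (iii) report the standard reliability/validity/prediction statistics
— or to replay all of these from published summary tables when the raw
survey is not available.

## The model

Measurement (reflective, mode A): each standardized item `x` loads on its
construct's composite score, `λ = corr(x, ξ̂)`.  Item screening uses
eleven criteria — floor/ceiling (≥20% at a bound), extreme-group Welch
t-test (27% tails), item-dimension r < 0.6, item-total r < 0.4, Cronbach's
α-if-deleted, stepwise regression (sle 0.05 / sls 0.10), EFA loading
< 0.4, and from Samejima's graded response model
`P(X ≥ k | θ) = logistic(a(θ − b_k))` the rules a < 0.3, b outside (−4, 4),
and mean item information Ī < 16/K.  An item reaching three criteria is
deleted (explicit overrides supported).

Structure: the classic PLS algorithm (path-weighting inner scheme,
mode-A outer estimation) yields standardized composite scores; structural
coefficients are then OLS solutions of the normal equations `R_pp β = r`,
so every coefficient, R², f² = (R²_full − R²_reduced)/(1 − R²_full),
adjusted R², and inner VIF is recoverable from the latent correlation
matrix alone.  The second-order quality construct is estimated by the
embedded two-stage approach (facet scores from stage one become its
indicators in stage two).  Inference is by respondent-level bootstrap
(percentile CIs, normal-approximation p), group heterogeneity by
distribution-based PLS-MGA, predictive relevance by blindfolding Q², and
reliability/validity by Cronbach's α, composite reliability
CR = (Σλ)²/[(Σλ)² + Σ(1−λ²)], AVE = mean(λ²), cross-loadings and the
Fornell–Larcker criterion.

Survey data with exactly this generative structure (standardized latent
DAG, GRM measurement, ceiling effects, urban/rural groups, missingness)
can be simulated with `satsem.synthetic`, so the entire pipeline is
testable end to end.

## Worked example

```python
import satsem
from satsem.synthetic import GeneratorConfig, simulate_survey, split_sample

survey = simulate_survey(GeneratorConfig(n_respondents=1909, seed=42))
construction, evaluation = split_sample(survey, n_construction=574, seed=42)

fit = satsem.pls_estimate(evaluation, satsem.default_initial_model())
for p in [("PQ", "PV"), ("PQ", "PS"), ("PV", "PS"), ("PS", "PT"), ("PS", "PC")]:
    print(f"  {p[0]} -> {p[1]}: {fit.path_coefficients[p]:+.3f}")
print("total PQ -> PS:", round(fit.effects().loc[("PQ", "PS"), "total"], 3))
```

prints

```
  PQ -> PV: +0.531
  PQ -> PS: +0.436
  PV -> PS: +0.325
  PS -> PT: +0.526
  PS -> PC: -0.229
total PQ -> PS: 0.608
```

The signs reproduce the hypothesized structure (only satisfaction →
complaints is negative), and quality has the largest total effect on
satisfaction; the magnitudes sit below the generating values because
ten-category ordinal measurement attenuates composite correlations (see
`docs/methods.md`).  `satsem.measurement_report(fit)` and
`satsem.structural_report(fit)` then produce the α/CR/AVE,
Fornell–Larcker, R²/f²/Q²/VIF tables, and `fit.bootstrap(...)` adds
SE/t/p/CI columns.

A command line wraps the same pipeline:

```sh
satsem simulate -n 1909 --seed 42 --outdir out/
satsem assess --seed 42 --outdir out/          # screen + fit + assess
satsem replay-summaries                        # recompute published tables
```

`satsem replay-summaries` recomputes, from the instrument's published
outer loadings and latent correlation matrix, the reliability table
(e.g. CR 0.897–0.960), the structural solution (PE→PS 0.070,
PQ→PS 0.421, PV→PS 0.467), the adjusted R² column
(PS 0.783, PV 0.654, PC 0.088, PT 0.400) and the total effects.

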