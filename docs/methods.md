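# Methods

## Model

The instrument's path model is a DAG over six top-level latent variables
— public expectations (PE, exogenous), perceived quality (PQ), perceived
value (PV), public satisfaction (PS), public complaints (PC), public
trust (PT) — with hypothesized paths PE→{PQ, PV, PS}, PQ→{PV, PS},
PV→PS, PS→PT (positive) and PS→PC (negative).  PQ is a second-order
construct over five first-order facets (overall, information, service,
policy, institution quality).  The shipped draft instrument has 29 items
on a 1–10 ordinal scale (nine GRM thresholds imply ten categories); the
final instrument drops the formal-complaint item PC2, leaving 28 items
and, counting the five facets, eleven latent variables.

## Synthetic data generator

Because the original survey is not public, the generator emulates its
stated conditions and is itself first-class, tested code.

* Latent scores follow a standardized linear system: exogenous latents
  are N(0, 1); each endogenous latent is Σ β·parent + disturbance, with
  the disturbance variance derived so every marginal variance is one.
  Infeasible coefficient sets (implied disturbance variance < 0) are
  rejected with an error naming the latent.  The model-implied
  correlation matrix is available in closed form
  (`implied_latent_correlations`) and doubles as the oracle in tests.
* Default structural coefficients are the instrument's published
  estimates (e.g. PQ→PV 0.676, PS→PT 0.634, PS→PC −0.243).  The five
  facets are generated as loaded children of PQ, facet = λ·PQ + noise,
  with λ equal to the published facet–quality correlations (0.692, 0.705,
  0.815, 0.937, 0.908).  The published facet→PQ *weights* (0.069–0.472)
  are second-stage regression weights, not generative loadings, and would
  not reproduce the observed facet–quality correlations; the correlations
  are therefore the generative parameterization.
* Items are drawn from a logistic graded response model (no 1.7 scaling
  constant) with one shared trait per first-order latent.  Default
  discrimination is a = 2.5, matching the 2.4–2.8 range reported for the
  most discriminating items; thresholds are evenly spaced on (−2.4, 2.4).
  Five items (PQ1, PQ14, PE2, PT1, PT2) carry compressed, down-shifted
  thresholds, linspace(−2.2, 0.6), so that >20% of respondents land in
  the top category and the screening stage sees realistic ceiling
  positives.  The lower end is chosen to stay inside the (−4, 4)
  screening band even after the ≈1/λ outward stretch that shared-trait
  calibration applies to items of weakly loading facets; deeper
  thresholds would push the single-item overall-quality facet into a
  spurious third flag, contradicting the documented screening outcome
  (ceiling items marked by the ceiling criterion only; no item reaching
  three criteria).
* Group structure: labels drawn with the study's urban/rural proportions
  (899/1020); per-group offsets on any structural coefficient support
  multigroup scenarios.  Missingness is completely at random at a
  configurable rate and always encoded as NaN, never as an in-range
  category.  Defaults: n = 1909, split 574/1335 (explicit counts;
  fraction-based splitting rounds to the nearest integer).

What the generator does **not** emulate: the three-stage school-based
cluster sampling (respondents are i.i.d.), demographic covariates,
informative missingness, local item dependence, and cross-loading items.
Passing tests therefore demonstrate correctness of the estimators under
the hypothesized measurement/structural model, not robustness to those
real-data complications.

## Item screening

Eight CTT criteria and three IRT criteria produce per-item flags; an item
reaching three or more applicable criteria is deleted automatically, and
explicit overrides (shipped default: PC2, near-zero information) are
recorded with reasons.  Selection is single-pass: flags are not
recomputed after deletions.

Notable conventions, all configurable:

* "Large increase" in α after removal is unquantified in common usage;
  the default margin is +0.01.  α-if-deleted is undefined in two-item
  dimensions (marked not applicable; not counted).
* Item-dimension correlations are self-inclusive (SPSS convention);
  a corrected-total option exists.
* Extreme groups are the top/bottom ⌈0.27 n⌉ respondents by total score,
  ties broken by stable respondent order; the t-test is Welch's.
  Complaint items are excluded from the t-test (not applicable), and all
  total-score criteria reverse-score complaint items first — without
  this, every negatively keyed item is trivially item-total-flagged.
* Stepwise regression (forward p < 0.05, backward p > 0.10) uses the
  dimension total as the dependent variable.  Because that total is an
  exact sum of the candidates, entry stops once the fit is numerically
  saturated; with duplicate items exactly one (the first) enters.
* EFA uses iterated principal-axis extraction with varimax rotation
  (rotation via statsmodels); a PCA option exists.  Non-convergent
  extraction marks items indeterminate rather than deleting them.
* GRM calibration blocks default to top-level constructs (all 17 quality
  items share one trait), which identifies single-item facets; per-facet
  and global (one satisfaction trait, reverse-keyed items flipped) modes
  are available.  The a < 0.3 cutoff is applied verbatim on the logistic
  metric; note it is metric-dependent.

## Graded response model

Marginal maximum likelihood via EM: the trait is integrated over 21
equally spaced nodes on (−6, 6) weighted by the standard-normal density;
the M-step maximizes each item's expected complete-data likelihood with
a log-parameterized discrimination and log-gap-parameterized thresholds
(strict ordering by construction); convergence at max |Δparameter| <
1e−4 or 500 iterations, with the log-likelihood checked non-decreasing.
Standard errors use the per-item block of the outer-product-of-scores
(BHHH) approximation to the observed information, delta-methoded back to
(a, b).  Unobserved categories are collapsed with the mapping recorded.
Item information follows Samejima's formula; Ī is the standard-normal-
weighted mean of the information curve (a uniform-on-(−4,4) weighting is
available for sensitivity), and the screening floor is 16/K for a K-item
draft (16/29 ≈ 0.55).

## PLS estimation

Classic Lohmöller/Wold iteration: mode-A outer weights (indicator
correlations with the inner proxy), path-weighting inner scheme
(regression weights toward predecessors, correlations toward
successors), convergence at max |Δweight| < 1e−7 (max 300 iterations).
Missing responses are mean-replaced before standardization (listwise
optional).  Sign ambiguity is resolved by forcing the dominant
indicator's loading positive; bootstrap resamples are aligned to the
original fit's dominant indicators.

The second-order construct uses the embedded two-stage approach by
default: stage one replaces PQ by its facets in the path set and yields
facet scores; stage two uses those scores as PQ's indicators under the
original path set.  Repeated indicators are available.  The structural
solution regresses PQ on its facets (R² ≈ 1 by construction) and each
original predecessor's influence on PQ is reported as the facet-mediated
total (sum over facet chains), without a direct regression coefficient —
regressing PQ jointly on PE and the facets would drive the PE
coefficient to zero by construction.

Bootstrap: respondent-level resampling with replacement (default 5000
resamples), SE = resample SD, t = estimate/SE with two-sided normal p,
percentile 95% CIs; singular resamples are redrawn, capped at 10%.
PLS-MGA: separate fit + bootstrap per group; the probability that one
group's coefficient exceeds the other's is computed over all bootstrap
pairs and reported two-sided as 2·min(q, 1−q) (identical groups give
p ≈ 1).  The inverse-square-root sample-size rule returns the smallest
integer strictly above (2.486/|β|min)², inflated by attrition and
multiplied by the number of groups.

## Assessment

CR, AVE/√AVE, cross-loadings and Fornell–Larcker are computed from outer
loadings and latent correlations — either a fit's or published ones
(`replay_structural_summary` replays a full structural table from a
printed correlation matrix).  R²adj uses the evaluation-sample n.  f²
refits the reduced regression from the latent correlation matrix;
saturated constructs (a second-order construct on its facets) report
NaN.  Q² is construct cross-validated redundancy with omission distance
7 (adjusted up by one when it divides n): every D-th data point of the
endogenous block is omitted in turn and predicted from the structural
model (predicted construct score carried to the indicator by its
loading), Q² = 1 − SSE/SSO; predecessor scores are unaffected by
omission within the target block, so the procedure is deterministic
given D.  Inner VIFs come from predictor-on-predictor regressions on the
correlation matrix; singular blocks are flagged infinite.

## Numerical and testing choices

* Degenerate inputs are errors, not silent results: zero-variance items,
  all-missing items, infeasible generator coefficients, singular
  predictor blocks, cyclic path sets.
* Category probabilities are clipped at 1e−300 inside likelihoods;
  information terms with category probability below 1e−12 at a grid
  point are skipped.
* Test problem sizes: structural recovery runs at n = 2000 with
  high-discrimination items (a = 8), the regime in which measurement
  error is negligible and the structural engine itself is isolated; at
  the survey-realistic default (a = 2.5) ordinal attenuation biases
  composite-level coefficients toward zero by up to ≈0.13 on
  quality-adjacent paths, and a separate test pins that bound (≤0.15,
  never amplification).  Bootstrap calibration uses 100 replications of
  199 resamples at n = 200 on a single-indicator null model (the
  PLS = OLS case); screening runs at n ≈ 600.
* One master seed derives all stage seeds through
  `SeedSequence([master, stage])`, keeping them below 2³¹.

## Known limitations

* PLS composites are not disattenuated (no consistent-PLS option);
  with few, coarsely measured indicators per construct the structural
  coefficients are conservative.
* The GRM assumes unidimensionality within a calibration block and no
  differential item functioning.
* Blindfolding predicts indicators through the construct's own loading
  and the structural regression only (construct cross-validated
  redundancy); the communality variant is not the default.
* Published-summary replay is limited by the three-decimal rounding of
  its inputs; one published coefficient (satisfaction→complaints,
  −0.243) is not reproducible from the published correlation matrix,
  whose OLS solution is −0.297 (= the printed correlation, consistent
  with the printed R² of 0.088); the package reports the OLS value.
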