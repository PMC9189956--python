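# Methods

`famcoagg` studies how two lifetime binary traits — a neurodevelopmental
disorder ("ADHD", trait 1) and a composite of autoimmune diseases
("anyAD", trait 2) — co-occur within individuals and across biological
relatives, on data shaped like Nordic population registers. Because real
register extracts cannot be shared, the package pairs every analysis
stage with a synthetic-register generator whose ground truth is known, so
correctness is established by parameter recovery rather than by
comparison with protected data.

## The liability-threshold ACE model

Each trait k is modelled through a latent standard-normal liability
L_k = A_k + C_k + E_k, split into additive-genetic (A), shared-environment
(C) and unique-environment (E) components with variance proportions
a²_k + c²_k + e²_k = 1. The two traits are coupled by component-wise
correlations rA, rC, rE. A person is affected when L_k exceeds a
threshold t_k; with lifetime prevalence p_k, t_k = Φ⁻¹(1 − p_k).

For a relative pair the four liabilities (member 1 × trait 1/2, member 2
× trait 1/2) are jointly normal. The cross-person entries follow from
kinship: full siblings share 50% of A and 100% of C; full cousins share
12.5% of A and none of C. The within-person cross-trait correlation is
rA·√(a²₁a²₂) + rC·√(c²₁c²₂) + rE·√(e²₁e²₂); cross-person cross-trait
terms carry the A- and C-parts scaled by the sharing coefficients.

The default parameter set (`STUDY_COMPONENTS`) is the published best
model for this trait pair: a²₁ = 0.84, e²₁ = 0.16 (no C for trait 1);
a²₂ = 0.23, c²₂ = 0.09, e²₂ = 0.68; rA = 0.13, rE = 0.02; prevalences
2.30% and 4.14%.

## Synthetic registers

`synthetic_register` simulates three-generation families: two
grandparental couples, a maternal and a paternal sibship (mother, father,
aunts, uncles), married-in spouses, and a grandchild generation (index
children and cousins). Sibship sizes are drawn from a configurable
distribution (default uniform on {1, 2, 3}); parent–child birth-year gaps
are ≥ 18 years and sibling spacing 1–4 years, with the grandchild
generation centred on the configured 1960–2010 birth window. Liabilities
follow the additive-genetic recursion (child A = parental mid-value plus
a segregation deviate with half the founder covariance), C is drawn once
per nuclear sibship, E per person — so siblings share C fully, cousins
and parent–child pairs not at all, matching the fitted model's
assumptions (no assortative mating, no dominance).

Thresholds carry two kinds of structure:

* **Sex.** Female-minus-male threshold shifts default to +0.218 (trait 1)
  and −0.144 (trait 2), derived from the published case sex distributions
  (36.0% and 56.3% female in a 48.6%-female cohort). Baseline thresholds
  are re-calibrated by root finding so the sex-averaged prevalence hits
  the target exactly. This matters: at these parameters the crude
  within-individual odds ratio is 1.39 with a single threshold per trait
  but 1.34 under the sex mixture — the published value.
* **Birth year.** Linear and cubic coefficients on the birth year
  standardized to [−1, 1] are supported and default to zero, because no
  quantitative secular trend is published to calibrate against; tests
  exercise non-zero settings explicitly.

Observability is separated from truth: a liability case is recorded in
the truth table even when death/emigration before age 10 (default rate
3.9%) or the register eras make it invisible. Events are coded by era
(ICD-7 1964–67, ICD-8 1968–86, ICD-9 1987–96, ICD-10 from 1997;
dispensations from 2005, ATC-coded); the shipped disease-code
configuration is deliberately *illustrative* — conventional ICD stems per
disease, weights proportional to published case counts — not a published
code list. Cases whose only possible event year precedes the first era
leave no record, which reproduces register-era censoring; drug-only cases
before 2005 are likewise invisible.

What the generator does **not** emulate: half-siblings and blended
families, twins, assortative mating, diagnosis trajectories (each case
emits one diagnosis event), regional/provider coding variation, and
misdiagnosis noise (the default specificity is 1). Passing tests
therefore demonstrate the statistical machinery under the stated model,
not robustness to real-register messiness.

## Cohorts

The index cohort applies the study's exclusion cascade: born in window,
biological mother known, no death/emigration before age 10 ("before age
10" = event year at most 9 years after birth year; age exactly 10 stays).
Six index–relative pair cohorts are built from the link table (mother,
father, full sibling, aunt, uncle, cousin), with maternal/paternal side
labels for aunts/uncles/cousins, a late (1980–2010) index window for
parent-generation relatives, survival filtering of relatives, and
de-duplication of symmetric relations to unique unordered pairs.
Aunts/uncles are restricted to *full* siblings of parents. The
robust-variance cluster is the connected component of the parent–child
graph — the most conservative reading of "familial clustering". For the
variance-component model, one sibling pair per nuclear sibship and one
cousin pair per grandparental lineage are sampled uniformly (seeded),
with greedy resolution of the rare person overlaps between lineages.

## Association analyses

Odds ratios come from maximum-likelihood logistic regression (IRLS,
tolerance 1e-8 on coefficients, ≤100 iterations) with cluster-robust
sandwich standard errors, Wald 95% intervals (multiplier 1.96) and
two-sided p-values; no multiple-testing adjustment. Birth year enters as
a natural cubic spline with 5 knots at the 5/27.5/50/72.5/95 percentiles
(linear beyond the boundary knots); pair analyses include both members'
splines, within-individual analyses one spline plus sex (covariate
adjustment by default; stratification via the interaction estimator).
Perfect separation and single-cluster data are flagged, not silently
accepted; with one cluster the estimator falls back to
heteroscedasticity-robust errors.

Standardized absolute risks average the fitted model's predicted outcome
probability over all analysis rows with the exposure forced to 1 and 0
("total population" standard); risk difference is their difference.
Intervals are cluster-bootstrap percentiles (default 500 resamples,
seeded); the bootstrap refits by plain IRLS since only point predictions
are resampled. When covariates depend on the exposure (interaction
columns), a design-builder hook rebuilds the design at each forced level.

Maternal-effect probes are ratio-of-odds-ratio (ROR) contrasts: two pair
cohorts are merged and the exposure × group interaction is estimated with
the group main effect and shared covariates (group-specific covariate
interactions are off by default — the contrast is the single interaction
term). Contrasts shipped: mother vs father, aunt vs uncle, maternal-side
vs paternal-side aunts/uncles.

## Quantitative genetic model fitting

Pairs are collapsed to 16-cell pattern counts per relative class; the
likelihood is multinomial with cell probabilities equal to rectangle
probabilities of the 4-variate normal implied by the parameters.
Rectangles are evaluated by Genz separation-of-variables with scrambled
Sobol points: the public `pattern_probability` tightens a randomized-QMC
error estimate below 1e-7; the fitting loop uses a fixed deterministic
point set (default 2048 points, ~1e-6 accuracy) vectorized over all 32
class × pattern rectangles, cross-checked in tests against scipy's MVN
CDF and brute-force Monte Carlo.

Free parameters are optimized unconstrained: additive log-ratios on each
trait's variance simplex, atanh for correlations, raw thresholds.
Sub-models (ACE/AE/CE/E per trait) structurally remove components; a
correlation exists only when its component is present for both traits
(reported as absent otherwise). Identifiability is verified up front: A
and C are jointly estimable only with ≥2 relative classes whose
(a-share, c-share) rows are linearly independent. Optimization is
L-BFGS-B with numerical gradients (gradient tolerance 1e-6), multi-start
(default 5) from a method-of-moments start — pooled-margin thresholds,
tetrachoric correlations, sharing equations solved by least squares —
plus seeded perturbations. Confidence intervals are profile-likelihood
(χ²₁ cutoff, bisection) by default, delta-method as the fast fallback.
Model selection ranks candidates by AIC = 2k − 2logL, ties broken by
fewer parameters. A per-pair likelihood mode supports sex and birth-year
(linear + cubic) threshold shifts per member; it reduces exactly to the
collapsed mode when all coefficients are zero.

**Estimator behaviour worth knowing.** With 400,000 sibling and 100,000
cousin pairs at the default parameters, the trait-2 A/C split is
identified solely by the cousin same-trait concordance (joint probability
≈ 0.0019), giving asymptotic standard errors of about 0.13 for a²₂ and
0.05–0.17 for rA. The single-fit MLE is heavy-tailed: in roughly a fifth
of replicates a²₂ collapses toward 0 and rA inflates along the ridge
rA·√(a²₁a²₂) ≈ const (these are genuine global optima, not optimizer
failures). Replicate *medians* are unbiased; means are not. The
acceptance script therefore reports medians over 15 replicate
simulate-and-fit runs, and downstream users should prefer the
well-identified combinations (a²₁, e²₂, 0.5·a²₂ + c²₂, the genetic
covariance rA·√(a²₁a²₂), thresholds) when working at comparable sizes.

## Numerical conventions and degenerate inputs

Probabilities are floored at 1e-300 inside log-likelihoods (flagged by a
floor constant, not hidden); non-PSD pair correlation matrices raise a
parameter-domain error, which the optimizer treats as an infinite
penalty. Spline construction rejects constant inputs and coincident
knots. Logistic outcomes without variation are rejected. The bootstrap
skips degenerate resamples (no cases) and reports percentile intervals
over the valid ones. All randomness flows from explicit seeds; pipeline
stages derive seeds from the master seed via `SeedSequence(master,
spawn_key=(stage_index,))`, so identical configuration plus seed yields
byte-identical outputs.

## Problem sizes

Defaults are sized for a laptop-class single core: the demo pipeline
simulates 20,000 families (~650,000 persons, ~6 minutes end-to-end); the
test suite uses 250–4,000-family bundles, 30k–400k-pair model fits and
2,000-replicate calibration studies; the acceptance script runs 15
replicate fits of 500,000 pairs each plus 5M- and 2M-row odds-ratio
simulations. Register-scale sample sizes (millions of index persons) are
configuration changes, not code changes.
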