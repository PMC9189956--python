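# famcoagg

Familial co-aggregation analysis of two lifetime binary traits on
register-shaped data. The package re-implements, as a reusable and fully
tested pipeline, the design of population-register studies that ask
whether a neurodevelopmental disorder (ADHD) and autoimmune diseases run
together in families: within individuals, across six classes of
relatives (mother, father, full sibling, aunt, uncle, cousin), and in a
bivariate liability-threshold ACE model that splits the cross-trait
covariance into genetic and environmental parts.

It is written for epidemiologists and statistical geneticists who have
(or want to emulate) person/parent-link/diagnosis/dispensation tables in
the shape of the Nordic national registers. Because real register
extracts cannot be shared, a first-class synthetic-register generator
produces three-generation pedigrees with known ground truth, so every
stage of the pipeline is validated by parameter recovery.

## The model

Each trait k has a latent liability L_k = A_k + C_k + E_k ~ N(0, 1) with
variance proportions a²_k + c²_k + e²_k = 1 (additive-genetic, shared-
and unique-environment); a person is affected when L_k > t_k, the
threshold fixed by lifetime prevalence. Traits are coupled by factor
correlations r_A, r_C, r_E, so the within-person cross-trait liability
correlation is

    r_wp = r_A √(a²₁ a²₂) + r_C √(c²₁ c²₂) + r_E √(e²₁ e²₂).

For a relative pair the four liabilities are jointly normal; full
siblings share 0.5 of A and all of C, full cousins 0.125 of A and no C.
Pairs collapse to 16-cell pattern counts whose multinomial likelihood is
built from 4-variate normal rectangle probabilities; maximum likelihood
over sibling + cousin classes identifies (a², c², e²) per trait, the
factor correlations, and the thresholds. Sub-models (ACE/AE/CE/E per
trait) are compared by AIC. Association stages estimate odds ratios by
cluster-robust logistic regression with natural-cubic-spline birth-year
adjustment, standardized absolute risks by regression standardization,
and maternal-effect ratio-of-odds-ratio (ROR) contrasts.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and known limitations.

## Worked example: recovering variance components

Simulate 400,000 sibling and 100,000 cousin pairs at the package's
default study parameters (AE for trait 1, ACE for trait 2; prevalences
2.30% / 4.14%) and refit them:

```python
import numpy as np
from famcoagg import STUDY_COMPONENTS, SIBLING, COUSIN
from famcoagg.quantgen import (simulate_pattern_counts, PatternCounts,
                               default_specs, BivariateLiabilityACE)

rng = np.random.default_rng(7)
counts = {
    "full_sibling": simulate_pattern_counts(STUDY_COMPONENTS, SIBLING, 400_000, rng),
    "cousin": simulate_pattern_counts(STUDY_COMPONENTS, COUSIN, 100_000, rng),
}
est = BivariateLiabilityACE("AE", "ACE", n_starts=2, ci_method="delta").fit(
    PatternCounts(counts=counts, specs=default_specs())
)
print(est.result_.summary_frame().to_string(index=False))
print("AIC:", round(est.aic_, 1), " covariance shares:", est.result_.covariance_shares)
```

```
parameter  estimate    ci_low  ci_high
     a2_1  0.825182  0.796294 0.854070
     c2_1  0.000000       NaN      NaN
     e2_1  0.174818       NaN      NaN
     a2_2  0.031560  0.000000 0.267438
     c2_2  0.192130  0.073468 0.310792
     e2_2  0.776310       NaN      NaN
       rA  0.326471 -0.903230 1.000000
       rC       NaN       NaN      NaN
       rE  0.036384 -0.036146 0.108913
       t1  1.998958       NaN      NaN
       t2  1.736781       NaN      NaN
AIC: 557487.1  covariance shares: {'A': 0.797..., 'C': None, 'E': 0.202...}
```

Reading this: trait 1's heritability (truth 0.84) and both thresholds
(truth 1.995 / 1.735) are recovered tightly. The trait-2 A/C split is
identified only by the cousin concordance and is genuinely noisy at
100,000 cousin pairs — this particular seed lands low on a²₂ (truth
0.23, interval 0.00–0.27) and compensates with a large, wide-intervalled
r_A (truth 0.13). The well-identified combinations — 0.5·a²₂ + c²₂
(here 0.208, truth 0.205) and the A-share of the cross-trait covariance
(here 0.80, truth 0.90 ± wide) — behave much better; replicate medians
are unbiased for every parameter. `docs/methods.md` discusses this
estimator behaviour in detail.

## The pipeline

```bash
famcoagg run-all --seed 3 --outdir results     # ~6 min: 20,000 families
famcoagg report results
```

`run-all` simulates a register bundle (persons, parent links, era-coded
diagnoses, post-2005 dispensations), builds the index cohort and the six
relative-pair cohorts, derives lifetime phenotypes from configurable
ICD/ATC prefix rules (13 illustrative autoimmune definitions plus their
composite), and writes pair-count and case-count tables, the OR forest
table, standardized risks, three ROR contrasts and the fitted
variance-component report. `report` renders a text summary, e.g.:

```
                self anyAD      OR  1.373 (1.167-1.614)
              mother anyAD      OR  1.152 (0.925-1.435)
        full_sibling anyAD      OR  1.259 (1.016-1.559)
              cousin anyAD      OR  0.955 (0.793-1.151)
...
                  mother_vs_father ROR  1.396 (0.957-2.036) p=0.083
```

At 20,000 families the intervals are wide; the configuration file
(`famcoagg.config.PipelineConfig`, YAML) scales every stage up to
register-sized cohorts and swaps in real register tables via
`famcoagg.register_model.load_registers`.

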