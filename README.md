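# patternsurv

Residual-survival prediction for glioblastoma (GBM) patients from
temporal patterns mined over longitudinal clinical and imaging events.

GBM patients treated with chemoradiation are followed at roughly
monthly visits with neurologic exams (KPS, mental status, neurologic
function, overall neurologic status on the Levin scale), interventions,
and volumetric tumor measurements.  *Residual survival* is the number
of days from a given visit until death.  `patternsurv` asks, at every
visit: will this patient die within 2, 6, or 9 months?  It answers by

1. encoding each visit as an itemset of discrete `(variable, state)`
   events (KPS change states, neurologic scores, tumor-volume
   representations discretized into equal-frequency deciles);
2. mining frequent **temporal patterns** — ordered itemset sequences
   under minimum-support, max-gap, max-length and max-size constraints
   (SPADE-family semantics, patient-level support);
3. converting patterns into per-visit binary features anchored at the
   current visit (with a minimum documented-history rule of
   (max_length − 1) × max_gap days);
4. fitting an L1-penalized (LASSO) logistic model per horizon under a
   stratified 75/25 patient split, 3 × 10-fold patient-based
   cross-validation with majority down-sampling, selection by mean CV
   AUC, and a single held-out test evaluation.

The model is the per-visit logistic regression

  logit P(residual ≤ h | visit) = β₀ + Σⱼ βⱼ·1[patternⱼ anchored at visit] + Σₖ γₖ·covariateₖ

with exp(βⱼ) reported as adjusted odds ratios, univariate Fisher-exact
odds ratios (conditional MLE with exact CI) per pattern, stratified
bootstrap CIs for AUC, and a paired bootstrap test for AUC differences
between approaches (volume threshold alone, volume + covariates,
patterns + covariates).

Because the motivating study's institutional data is not public, the
package ships a synthetic cohort generator
(`patternsurv.cohort.generate_cohort`) that reproduces the published
cohort structure (n = 304, ~23 visits/patient, ~28-day gaps, 84.5 %
deceased, published covariate marginals) and **plants** prognostic
temporal patterns with a known hazard log-odds, so the entire pipeline
is testable against ground truth.  See `docs/methods.md` for the model,
generator, and all numerical choices.

## Worked example

```python
import warnings
from patternsurv import CohortParams, ResidualSurvivalModel, generate_cohort
from patternsurv.mining import MiningParams

records = generate_cohort(CohortParams(seed=1))   # 304 synthetic patients
model = ResidualSurvivalModel(
    records, horizon=6,
    mining_grid=[MiningParams(0.3, 60, 2, 2)],    # support, gap, length, size
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")               # single-class CV folds
    results = model.fit(seed=1)
print(results.summary())
```

prints

```
Residual-survival LASSO logistic model
======================================================
Horizon:              6 months (180 days)
Volume encoding:      rate_change
Mining params:        min_support=0.3, max_gap=60d, max_length=2, max_size=2
Patterns mined:       1971
Patients (train/test): 228/76
Visits (train/test):  3278/1146
Lambda (L1):          0.003
Selected features:    74
Mean CV AUC:          0.877
Mean CV avg prec:     0.698
Test AUC:             0.888
Test avg precision:   0.713
Threshold (Youden J): 0.506
------------------------------------------------------
Top features by adjusted OR:
    4.894  kps=significant_decrease
    2.597  kps=significant_decrease -> kps=unchanged
    2.591  mental_status=0 -> kps=decreased
    2.028  mental_status=0 -> neurologic_function=3 & overall_neuro_status=-1
    1.750  neurologic_function=4
    ...
```

Reading this: from 1971 mined temporal patterns the model selected 74
features at λ = 0.003; patient-based cross-validated AUC on the
training partition is 0.877 and held-out test AUC 0.888.  The
top-ranked features are exactly the generator's prognostic structure:
KPS collapse to ≤ 60 and sustained decline sequences (products of the
terminal-decline dynamics), and the planted severe-decline pattern
(neurologic function 4) with adjusted OR ≈ 1.8 — the generator injects
it with hazard log-odds 2.0 (anchor-level odds ratio e² ≈ 7.4),
attenuated in the multivariable model by the correlated decline
features.  Exact numbers vary with the seed.

`results.trajectory(record)` returns one patient's per-visit predicted
probabilities against the Youden threshold;
`results.rank_patterns()` returns the top-10 tables per class with
supports and univariate Fisher statistics; `compare_approaches(...)`
runs the three-approach AUC comparison with bootstrap CIs and paired
tests.

A command-line interface mirrors the stages:

```sh
patternsurv simulate --seed 1 --out cohort/
patternsurv run-all --config config.yaml
```

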