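# Methods

`patternsurv` models *residual survival* — the number of days remaining
until death, evaluated at each clinical visit — for glioblastoma (GBM)
patients followed after standard chemoradiation.  The prediction task is
cast as per-visit binary classification at three horizons (2, 6, and 9
months; one month = 30 days, so 60/180/270 days, boundary inclusive on
the short side): does the patient die within the horizon of this visit?
Features are patient covariates plus *temporal patterns* — ordered
combinations of discrete clinical and imaging events mined from the
longitudinal record.

## Event encoding

Raw visits are converted to itemsets of `(variable, state)` events:

- **Surgery / radiation**: occurrence items (initiation dates only).
- **KPS** (Karnofsky performance status, 0–100 in steps of 10): change
  states relative to the *immediately preceding* observed KPS —
  `initial`, `decreased` (dropped but still > 60), `significant_decrease`
  (dropped to ≤ 60, including drops that start at or below 60),
  `increased` (was > 60 and rose), `significant_increase` (was ≤ 60 and
  rose), `unchanged`.
- **Mental status** (0–2), **neurologic function** (0–4), and **overall
  neurologic status** (Levin scale, −2…+2): direct categorical items.
- **Tumor volume** (mm³): one of five representations — raw volume,
  per-patient baseline volume (the first post-chemoradiation
  measurement, attached to every visit as a static item), rate of change
  (V₂−V₁)/(D₂−D₁) in mm³/day, percent change 100·(V₂−V₁)/V₁, or the
  volumetric RANO response category (complete = all enhancement
  resolved; partial = ≥ 65 % decrease; progression = ≥ 40 % increase;
  stable otherwise).  The ≥ 40 % progression rule treats the printed
  "≤ 40 %" convention of some sources as a typographical inversion; a
  flag (`progression_geq=False`) restores the literal reading.

Continuous representations are discretized into ten equal-frequency
bins whose edges are order statistics of the *training patients'*
values (right-open intervals, last bin closed).  Fitting bins on
training patients only is enforced by fingerprinting the edges; bins
fitted on the full cohort produce a different fingerprint and fail the
leakage test.  Rate, percent, and RANO items appear only from the
second volume measurement onward; volume items only at visits with a
measurement.  Visits encoding no event at all are dropped.

## Pattern mining

A temporal pattern is an ordered list of itemsets; a patient's sequence
contains it if the elements can be assigned to strictly increasing
visits, each element a subset of its visit's items, with at most
`max_gap_days` between consecutive *matched* visits (unmatched
intervening visits are allowed — standard SPADE gap semantics).
Support is patient-level: the fraction of patients containing the
pattern at least once; within-patient multiplicity is ignored.

The miner performs a depth-first prefix growth with two operations:
itemset extension (adding a lexicographically larger event to the last
element, bounded by `max_size`) and sequence extension (appending a new
single-event element, bounded by `max_length`).  It maintains, per
pattern and patient, the list of visits where the pattern can *end*;
both growth operations only shrink these lists, so pruning at
`min_support` is exact.  Note that anti-monotonicity under a max-gap
constraint holds for prefixes and itemset subsets (the operations the
search uses) but **not** for deletion of interior elements — the
bridged gap may exceed the constraint — so no such pruning is used.
Correctness is verified against `enumerate_patterns_bruteforce`, an
exhaustive oracle for databases of ≤ 10 patients × ≤ 6 visits.

## Featurization and labeling

Each mined pattern becomes a per-visit binary feature via *anchored*
matching: the final element must match at the current visit, earlier
elements at earlier visits under the gap rule.  A visit is usable only
with at least `(max_length − 1) × max_gap_days` days of documented
history (120 days for the canonical 3-visit / 60-day configuration), so
every pattern occurrence is decidable; the first predictable day for a
patient whose visits start at day *d* is *d* + 120.

Labels: visits of deceased patients are `residual ≤ horizon` when
death − visit ≤ horizon days, else `> horizon`.  Visits of alive
patients at least a horizon before censoring are safely `> horizon`;
visits within a horizon of censoring are indeterminable and excluded by
default (`censor_policy="optimistic"` labels them `> horizon`, the
literal reading of the original protocol; the default is the
conservative choice).

Covariates: sex, MGMT methylation, laterality, ethnicity and tumor
location one-hots, and age-decade indicators (< 40, 40s, 50s, 60s,
≥ 70) recomputed at each visit from initial age plus elapsed time.

## Model estimation

Patients are split 75/25 into train/test by a two-step stratification:
survival subgroup (overall survival below vs. above the cohort mean) ×
sex, with cascade rounding so per-stratum shares stay within one
patient of 75 % while the cohort total is exact.  Discretization bins
and mined patterns come from training patients only.

For each candidate mining configuration and each L1 penalty λ on a
logarithmic path, the model is scored by patient-based 10-fold
cross-validation repeated 3 times with different fold seeds (patients
in a validation fold contribute no visits to its training folds).  The
majority class is down-sampled to the minority size inside each
training fold only; validation and test sets are never balanced.  The
penalty is parameterized per observation (objective: mean log-loss +
λ‖w‖₁); binary features are not standardized.  The configuration with
the highest mean CV AUC wins, ties broken toward fewer selected
features and then lexicographic parameter order; it is refit with
down-sampling on the full training partition and evaluated once on the
held-out test patients.  Adjusted odds ratios are exp(coefficients).
The classification threshold maximizes Youden's J on training
predictions (candidate cuts are midpoints between consecutive unique
scores; the rule is configurable, standing in for an unavailable
protocol detail).

## Evaluation

Three approaches are compared on the identical held-out test visits:
(1) a volume-threshold rule — sweeping all thresholds over the last
observed tumor volume, which is exactly the ROC AUC with volume as the
score; (2) logistic regression on standardized volume plus covariates;
(3) the temporal-pattern model.  AUC uses the Mann–Whitney formulation
(ties count ½); average precision is precision averaged at positive
ranks.  95 % CIs come from a stratified percentile bootstrap (cases and
controls resampled within class, 2000 replicates by default).  The
ΔAUC test is a paired stratified bootstrap in the normal-deviate form:
the observed difference divided by the bootstrap standard deviation of
the difference, referred to a standard normal.  Under a
label-permutation null with paired scorers it is well calibrated
(type-I ≈ 5 %); with *independent* scorers on fewer than ~300 visits it
is mildly anti-conservative (~9 % at n = 200) because the bootstrap SD
underestimates the sampling SD at that size — a known limitation.
Univariate pattern statistics use Fisher's exact test: conditional
maximum-likelihood odds ratio with exact (Cornfield) CI and two-sided
exact p; zero cells yield 0/∞ estimates with finite one-sided bounds
and no continuity correction.  α = 0.05 throughout.

## Synthetic cohort generator

No patient-level data from the motivating study is public, so the
generator emulates its structure: 304 patients; visit gaps 1 + Poisson
(mean 28.4 days); visit counts Poisson (mean 23.3) truncated at death;
~84.5 % deceased (Bernoulli per patient); male fraction 61.8 % by
deterministic rounding; ethnicity, MGMT, laterality, and location drawn
from the published marginals; initial age Normal(54.6, 11.9²) clipped
to [18, 90].  Overall survival is log-logistic (shape 2.5, scale set so
the mean is 721.2 days).  Trajectories: KPS is a bounded random walk on
the decile grid; neurologic function a sticky walk on 0–3 coupled to
KPS drops; mental status mostly normal with minor confusion more
likely under neurologic impairment; overall neurologic status reflects
the sign of recent KPS/function changes; tumor volume follows
log-scale linear growth with an optional treatment-response dip and
multiplicative log-normal noise (~10 % of measurements missing).
Terminal decline: within 180 days of death the KPS and
neurologic-function walks drift downward; earlier they drift mildly
toward recovery.  The 180-day window matches the planted-residual
horizon below and reflects the clinical picture of accelerating
functional decline in end-stage GBM.

**Planted patterns.**  A configurable fraction of patients (default
prevalence 0.40) carries a pattern template (default: a single visit
with neurologic function 4) injected into consecutive visits ending at
an *anchor* visit.  The probability that the patient dies within
R = 180 days of the anchor is σ(logit(p₀) + h), with baseline
p₀ = 0.25 and hazard log-odds h = 2.0 per carried pattern; non-carriers
get a pseudo-anchor with the baseline probability, so the carrier
status vs. short-residual odds ratio is eʰ by construction.  The anchor
and death day are fixed *before* trajectories are simulated, so decline
aligns with the actual death.  The final element's direct-valued states
persist for `planted_persistence` = 2 visits after the anchor (severe
decline is not a one-visit blip), so the pattern anchors at several
consecutive visits per carrier; KPS change states do not persist, as
re-asserting them would rewrite the anchor's values.  Severe states (neurologic function 4,
mental status 2) are never emitted spontaneously — severely inactive
patients are assumed not to attend routine visits — which makes mined
support of the default template equal the carrier fraction exactly.
Templates may use any clinical variable but not volume states, whose
decile identity depends on downstream bin fitting.  Prevalence 0.40
keeps binomial fluctuation of support safely above the 0.3 minimum
support of the canonical mining cell at n = 304.

**What the generator does not emulate:** the real cohort's
inter-variable correlation structure (a `neuro_coupling` knob exists
but carries no fidelity claim), volume-driven mortality (volume is
deliberately uninformative so that approach comparisons isolate the
temporal-pattern signal), per-patient treatment histories beyond
initial radiation and occasional surgery, and the exact class-imbalance
ratios of the real data.  Passing tests therefore demonstrate that the
pipeline recovers known planted structure under realistic marginals —
not that the printed performance of any real-data study is reproduced.

## Problem sizes and defaults

The canonical mining cell is min support 0.3, max gap 60 days, max
length 3 visits, max size 3 events.  Synthetic sequences are denser
than the real cohort's (that cell yields ~27 000 patterns here versus
3758 reported on real data), so the end-to-end test and acceptance
suites use a reduced cell (0.3, 60 days, length 2, size 2, ~2000
patterns) with the λ path (0.01, 0.003); recovery suites run 20 (tests)
or 8 (acceptance script) seeded pipeline repetitions at n = 304, and
bootstrap calibration uses 200 × 500 (tests) or 100 × 500 (script)
trials × replicates.  These sizes are the package's reporting choices;
all protocol structure (75/25 split, 3 × 10-fold patient CV,
down-sampling, selection by mean CV AUC) is always exercised in full.

## Numerical choices

Equal-frequency bin edges are order statistics at ranks ⌊j·n/k⌋ with
duplicate edges collapsed (degenerate inputs give fewer bins, reported
via `scheme.k`).  Support thresholds compare counts with a 10⁻⁹ slack
to avoid floating-point misses at exact fractions.  Mining output is
canonically ordered (length, then lexicographic elements) and the
whole pipeline is deterministic given the master seed: every random
draw flows through named substreams (SHA-256 of `seed:name`, reduced
below 2³¹).  liblinear is seeded; CV folds shuffle patient ids with
`default_rng([seed, repeat])`.  Single-class CV folds are skipped with
a warning; a degenerate threshold falls back to 0.5 with a warning.
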