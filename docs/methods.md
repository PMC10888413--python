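# Methods

This note documents the models, parameter choices, and numerical
conventions behind `painstrat`, and what the synthetic-data tests do and
do not demonstrate about real cohorts.

## Outcomes and data model

Pain interference is assessed per Brief Pain Inventory area — mood, daily
activities, sleeping quality, social life, work performance — as five
separate binary outcomes, plus an ordinal count category of affected
areas: 0–1, 2, 3, 4+. The count category is always derived from the five
binaries ({sum ≤ 1 → "0-1", 2 → "2", 3 → "3", ≥ 4 → "4+"}); a supplied
count column that disagrees is a validation error, never silently
overwritten. Completeness is a precondition: missing values are rejected,
not imputed, because the pipeline's downstream arithmetic (levels,
weights, tallies) has no principled treatment of partial profiles.

Participants join a building table on `building_id`; building-level
features (orientation, flats, corridors, lifts, light wells, building
age, small-flat proportion, re-entrant bay, terrace, density) are
constant within building by construction. Category orderings (BMI
classes, count categories, ...) are fixed in the feature dictionary, not
inferred from data order, because the ordinal regression downstream
depends on them.

## Synthetic cohort generator

The generator emulates the marginal structure of a working-poor
public-housing cohort: continuous features as normals truncated to their
natural supports (age ≥ 18, pain scores in [0, 10], nonnegative building
counts, rounded to integers where the quantity is a count), discrete
features from fixed probability vectors, and the small-flat proportion
from a Beta distribution with mean 0.36 and concentration 20 (no
published dispersion exists for that quantity; concentration 20 gives an
SD of ≈ 0.10, a plausible between-building spread). One printed
orientation vector summed to 100.1% and is renormalized.

Participants are assigned to buildings with probability proportional to
flat counts (larger buildings house more residents), giving realistic
cluster-size imbalance; uniform assignment is available. Defaults are 30
buildings for pipeline-scale runs and 40 at n = 5000 in the heavier
experiments — enough clusters that building-level effects are estimable
while keeping within-building correlation visible.

Outcomes are planted through independent per-area logistic models:
outcome ~ Bernoulli(expit(α + Σ effects)), where effects are per-unit
slopes for continuous features and per-category log-odds increments for
discrete ones. The intercept α is found by bisection on [−20, 20] so the
expected prevalence over the realized feature draw matches the target
(defaults: mood 0.419, daily activities 0.729, sleep 0.500, social 0.252,
work 0.467) within 0.005; an unreachable target raises a calibration
error. One master seed spawns independent child streams for buildings,
assignment, features and outcomes, so the full pipeline is reproducible
from a single integer.

The default planted effects put roughly comparable log-odds variance at
the individual level (pain intensities, knee/lower-back pain, BMI,
occupation, a mild age slope) and a somewhat larger share at the building
level (building age, corridors, lifts, flats, small-flat proportion, and
orientation contrasts with south-facing protective). This reproduces the
qualitative study design: an individual-only model faces irreducible
cluster-level noise, while a mixed model can explain it.

**What the generator does not emulate:** correlations among features
beyond those induced by planted effects (an optional hook exists for
stress tests but marginals are independent by default), inter-area
dependence beyond shared features, medication use, pandemic-wave
dynamics, or spatial geography. Passing tests therefore demonstrate that
the algorithms recover structure that is present by construction — not
that real pain-interference data contain that structure.

## Forests and permutation importance

Forests are scikit-learn `RandomForestClassifier` ensembles grown
warm-start in chunks of 25 trees with bootstrap resampling and per-split
random feature subsets (default √p, Gini impurity). Training stops at 500
trees or when out-of-bag accuracy has improved by less than 1e-4 over the
last 50 trees, whichever comes first; both constants are configurable.
Discrete features enter as integer codes in dictionary order — trees
split on them directly, and a one-feature-one-column encoding is exactly
what joint permutation of a categorical feature requires.

Permutation importance is authored here rather than delegated: for each
feature, importance = baseline accuracy − mean accuracy over `n_repeats`
independent row permutations of that column, with per-repeat values
retained so a standard error is available. Groups of columns can be
permuted jointly under one shared row permutation, which measures the
combined contribution of collinear features (a single-column permutation
understates a feature whose twin covers for it). The implementation is
cross-checked against `sklearn.inspection.permutation_importance` with
the accuracy scorer in the test suite. Accuracy — not AUC — is the
permuted metric, with class labels from a 0.5 threshold on the ensemble
vote fraction. A constant feature's importance is exactly zero by
construction.

Ranking keeps only strictly positive importances (permuting a feature
that does not hurt the model is evidence of no unique contribution),
descending, ties broken lexicographically for determinism.

The count-supervised model is a 4-class forest on the ordinal categories;
its permutation importance uses multiclass accuracy. Class balancing is
not applied for the rarer outcomes.

## Evaluation

Train/validation is a stratified 70/30 split (seeded, configurable). The
validation AUC carries a percentile 95% CI over 100 bootstrap resamples
of the validation rows; resamples that lose an outcome class are redrawn.
Bands: poor [0, 0.70), acceptable [0.70, 0.80), excellent [0.80, 0.90],
outstanding (0.90, 1] — note the inclusive 0.90 on the excellent side.

When comparing the two feature pools with no building-level effects
planted, the difference CI is built from independent resamples per model:
the scientific question is whether the pools are distinguishable given
AUC sampling noise. (A paired bootstrap on shared resamples is far more
powerful and detects the small systematic cost of carrying irrelevant
extra features — a real random-forest property, but not the building
signal under test.)

## Rank aggregation

Summative score = Σ over the five areas of max(C − rank, 0), with C = 21
and unranked entries contributing zero. C = 21 is one more than a
20-feature pool, so the top rank is worth 20 points; it is configurable,
and the natural generalization C = pool size + 1 is available, but 21 is
the default because it is the offset under which the bundled reference
tables' scores reproduce exactly — including the sparse rows, which also
pin down that unranked means zero rather than an imputed worst rank.

## Score card

Continuous features are discretized at the empirical quantiles of the
interior grid (default 0/5/20/80/95/100%, per-feature overridable), with
linear-interpolation quantiles, half-open levels [low, high) and a closed
last level. Duplicate cuts collapse (a constant feature has one level);
cuts that would create a level with no training observations — which
interpolated quantiles produce on integer-valued features — are merged
into the following level. New out-of-range values clamp to the boundary
levels. Discrete features keep their observed categories as levels.

Weights come from a proportional-odds (cumulative logit) regression of
the count category on the one-hot levels of all selected features
jointly, fitted with statsmodels' `OrderedModel` (BFGS, convergence
checked; the thresholds absorb the intercept, so the design carries no
constant). Within each feature the coefficients are recentred so the
smallest is 0 — that level is the reference — and every recentred
coefficient is divided by the smallest strictly positive recentred
coefficient across the whole card and rounded half-away-from-zero. This
makes the weights: nonnegative integers, zero for every reference level,
exactly invariant to rescaling all coefficients by a positive constant,
and anchored so the finest distinguishable contrast is worth 1 point. A
"literal" variant that divides by the reference coefficient directly is
implemented behind a flag; it is undefined when a reference coefficient
is zero and is not the default because recentring is what produces the
characteristic zero-weight reference levels of a points-style card.

Rounding is half-away-from-zero (2.5 → 3) to avoid banker's-rounding
surprises in published score cards.

A participant's total is the sum of their levels' weights; the
stratification table row-normalizes the count-category composition within
non-overlapping closed integer score bins (defaults [21, 40], [41, 60],
[61, 80], [81, 100] for individual-level cards and [31, 40], [41, 50],
[51, 60], [61, 100] for mixed cards; the pipeline widens to equal-width
bins over the realized range when a card's scores fall outside the
defaults). Empty bins report zero occupancy and NaN proportions rather
than being dropped.

## Problem sizes used in the test battery

The distributional checks use what each estimate needs: marginal
calibration at n = 10000 (3-standard-error tolerance), pool-comparison
experiments at n = 5000 with 40 buildings over 20 seeds and 100-tree
forests, weight-recovery over 100 seeds at n = 1500, importance-recovery
over 100 seeds at n = 2000 with 25-tree forests (the planted signal is
perfectly separable, so small ensembles suffice), and pipeline smoke runs
at n = 500 with 40-tree forests.

## Known limitations

- The ordinal-regression design can be rank-deficient when few buildings
  realize many building-level categories; flat directions do not bias the
  fitted predictor but make individual coefficients — and hence weights —
  arbitrary along the deficiency. More buildings, or fewer selected
  building features, is the remedy.
- The scaling constant (smallest positive recentred coefficient) makes
  weights sensitive to one nearly-null contrast: a card can carry large
  integers when some level barely differs from its reference. Collapsing
  such levels before derivation is the practical fix.
- Permutation importance on correlated features understates unique
  contributions unless joint groups are specified explicitly.
- Bootstrap CIs for AUC are percentile-based; no BCa correction.
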