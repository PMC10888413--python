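# painstrat

Random-forest stratification and interpretable risk scoring for
multi-area pain interference in clustered cohorts.

## The problem

Pain interferes with distinct areas of life — mood, daily activities,
sleeping quality, social life, and work performance (the five Brief Pain
Inventory interference domains). Among working-poor residents of public
housing, the drivers of that interference include not only individual
characteristics (age, occupation, pain intensity and location, BMI, blood
pressure, blood glucose, smoking and drinking) but also the built
environment of the residential building: its cardinal orientation (a proxy
for access to light), the proportion of small flats, the numbers of
corridors and lifts (proxies for social connectivity), light wells, and
building age. These factors are strongly interrelated, which defeats the
coefficient-reading interpretability of ordinary regression.

`painstrat` implements a random-forest-based pipeline that (1) models each
interference area as a separate binary outcome and the number of affected
areas as an ordinal count, (2) quantifies each feature's unique
contribution by permutation importance — the drop in predictive accuracy
when that feature's column is replaced by a random permutation of itself —
(3) aggregates the per-area importance rankings into a single summative
score per feature, and (4) converts the selected features into a
points-style risk score card that a community screening programme can
apply with pencil and paper.

## The method in brief

**Per-outcome forests.** For each outcome *y* and feature pool (individual
only, or individual + building), an ensemble of CART trees is grown on
bootstrap subsamples with random feature subsets per split, up to 500
trees or until out-of-bag accuracy converges. Discrimination is reported
as the validation AUC with a 100-resample percentile bootstrap 95% CI,
banded as poor (< 0.70), acceptable (0.70 to < 0.80), excellent
(0.80–0.90), or outstanding (> 0.90).

**Rank aggregation.** Feature *j* with permutation-importance rank
*r\_{jk}* in area *k* receives the summative score

&nbsp;&nbsp;&nbsp;&nbsp;S\_j = Σ\_k max(C − r\_{jk}, 0),

with reverse-coding offset C = 21 (one more than a 20-feature pool, so
rank 1 is worth 20 points) and unranked entries contributing 0.

**Score card.** Continuous features are cut into ordinal levels at their
empirical 5/20/80/95-percent quantiles. A proportional-odds ordinal
regression of the count category (0–1, 2, 3, 4+ areas) on the one-hot
response levels of all selected features yields per-level log-odds
coefficients β; within each feature the coefficients are recentred so the
smallest is 0, divided by the smallest positive recentred coefficient in
the card, and rounded to integers. A participant's total score is the sum
of their levels' weights, and a stratification table reports the
distribution of the count category within score bins.

Because real cohorts of this kind are privacy-restricted, the package
ships a synthetic-cohort generator calibrated to published descriptive
statistics (marginal means/SDs and prevalences) with configurable planted
individual- and building-level effects, so every stage of the pipeline is
testable end to end.

## Worked example

```python
import painstrat as ps
from painstrat import reference

# Reverse-coded rank aggregation on the bundled published ranking:
scores = ps.summative_scores(reference.rank_table("individual"), offset=21).scores
print(scores.head(4))
# Age                                 99
# Main Occupation                     91
# Pain intensity: mild condition      91
# Pain intensity: severe condition    89

print(ps.band_auc(0.7129), ps.band_auc(0.9085))
# acceptable outstanding

# Synthetic cohort with planted building-level effects:
cohort = ps.simulate_cohort(n_participants=5000, n_buildings=40, seed=0)
train, val = ps.split_cohort(cohort, "mood", seed=0)
cfg = ps.ForestConfig(n_trees=100, seed=0)
for pool in ("individual", "mixed"):
    model = ps.fit_forest(train, "mood", pool, cfg)
    print(pool, round(ps.evaluate_model(model, val, seed=0).auc, 3))
# individual 0.662
# mixed 0.88
```

The AUC jump from 0.662 to 0.88 when building-level features join the
pool is the package's headline phenomenon: when the built environment
genuinely contributes to pain interference, a model blind to it leaves
most of the explainable signal on the table.

The full pipeline is also scriptable:

```bash
painstrat -v run --seed 7 --out runs/demo
```

which writes the simulated cohort, per-area model reports, rank and
summative-score tables, YAML score cards, and stratification tables under
`runs/demo/`.

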