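"""Interpretable risk score card: quantile discretization, integer weights
from a proportional-odds fit, participant tallies, and score-bin
stratification.

The card is built for the ordinal count of pain-interfered areas, not the
per-area binaries. Continuous features are first cut into ordinal levels at
empirical quantiles (default grid 0/5/20/80/95/100%); a proportional-odds
ordinal regression of the count category on the one-hot response levels of
all selected features jointly yields per-level coefficients; within each
feature the coefficients are recentered so the smallest is zero (that level
is the reference) and every coefficient is divided by the smallest positive
recentered coefficient across the whole card and rounded half-away-from-
zero to an integer weight. A participant's risk score is the sum of the
weights of their levels, and a stratification table reports the
distribution of the count category within user-supplied score bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .cohort import Cohort
from .features import COUNT_CATEGORIES

DEFAULT_GRID = (0.0, 5.0, 20.0, 80.0, 95.0, 100.0)

#: Default score bins for a card built from individual-level features only.
INDIVIDUAL_BINS = ((21, 40), (41, 60), (61, 80), (81, 100))
#: Default score bins for a mixed individual+building card.
MIXED_BINS = ((31, 40), (41, 50), (51, 60), (61, 100))


class WeightDerivationError(RuntimeError):
    """Non-identifiable design or non-converged ordinal fit."""


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (score-card style,
    no banker's rounding)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Quantile discretization


@dataclass
class FeatureLevels:
    """Ordinal levels of one feature.

    Continuous features carry strictly increasing interior cut points c_1..c_k
    defining levels (-inf, c_1), [c_1, c_2), ..., [c_k, +inf) labelled
    "<c_1", "[c_1, c_2)", ..., ">=c_k". Discrete features carry their
    categories directly as levels.
    """

    feature: str
    kind: str  # "continuous" or "discrete"
    cuts: tuple[float, ...] = ()
    labels: tuple[str, ...] = ()

    def assign(self, values: pd.Series) -> pd.Series:
        if self.kind == "discrete":
            out = values.astype(str)
            unknown = set(out.unique()) - set(self.labels)
            if unknown:
                raise ValueError(f"unknown level(s) {sorted(unknown)} for {self.feature!r}")
            return out
        idx = np.searchsorted(np.asarray(self.cuts), pd.to_numeric(values).to_numpy(), side="right")
        return pd.Series(np.asarray(self.labels, dtype=object)[idx], index=values.index)


def _fmt(x: float) -> str:
    return f"{x:g}"


def _interval_labels(cuts: tuple[float, ...]) -> tuple[str, ...]:
    if not cuts:
        return ("all",)
    labels = [f"<{_fmt(cuts[0])}"]
    labels += [f"[{_fmt(a)}, {_fmt(b)})" for a, b in zip(cuts[:-1], cuts[1:])]
    labels.append(f">={_fmt(cuts[-1])}")
    return tuple(labels)


def discretize_feature(
    values, grid=DEFAULT_GRID, feature: str = "feature"
) -> FeatureLevels:
    """Cut a continuous vector into ordinal levels at the empirical
    quantiles of the interior grid percentages (linear interpolation).
    Duplicate cut points collapse, so a constant vector yields one level."""
    values = np.asarray(pd.to_numeric(pd.Series(values)).dropna(), dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty vector")
    grid = tuple(float(g) for g in grid)
    if grid[0] != 0.0 or grid[-1] != 100.0 or any(a >= b for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must start at 0, end at 100, and be strictly increasing")
    interior = grid[1:-1]
    cuts = tuple(dict.fromkeys(float(np.quantile(values, q / 100.0)) for q in interior))
    # A cut equal to the minimum or maximum creates an empty extreme level.
    lo, hi = values.min(), values.max()
    cuts = tuple(c for c in cuts if lo < c <= hi)
    # Interpolated quantiles of discrete-valued data can leave an interior
    # level with no observations (e.g. [1.95, 2) on integer counts); such a
    # cut is merged into the following level.
    keep: list[float] = []
    for c in cuts:
        prev = keep[-1] if keep else -np.inf
        if ((values >= prev) & (values < c)).any():
            keep.append(c)
    cuts = tuple(keep)
    return FeatureLevels(feature=feature, kind="continuous", cuts=cuts, labels=_interval_labels(cuts))


@dataclass
class DiscretizationScheme:
    """Level assignments for a set of features."""

    levels: dict[str, FeatureLevels]

    def assign_frame(self, frame: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {name: fl.assign(frame[name]) for name, fl in self.levels.items()},
            index=frame.index,
        )


def discretize_cohort(
    cohort: Cohort,
    features: list[str],
    grid=DEFAULT_GRID,
    per_feature_grid: dict[str, tuple] | None = None,
) -> DiscretizationScheme:
    """Build a scheme for the selected features: continuous ones are cut on
    the quantile grid (overridable per feature); categorical/ordinal/binary
    ones keep their dictionary categories as levels."""
    frame = cohort.feature_frame(features)
    levels: dict[str, FeatureLevels] = {}
    for name in features:
        spec = cohort.dictionary[name]
        if spec.is_discrete:
            observed = set(frame[name].astype(str).unique())
            labels = tuple(c for c in spec.categories if c in observed)
            levels[name] = FeatureLevels(feature=name, kind="discrete", labels=labels)
        else:
            g = (per_feature_grid or {}).get(name, grid)
            levels[name] = discretize_feature(frame[name], grid=g, feature=name)
    return DiscretizationScheme(levels=levels)


# ---------------------------------------------------------------------------
# Weight derivation


@dataclass
class FeatureWeights:
    feature: str
    rank: int | None
    levels: tuple[str, ...]
    weights: dict[str, int] = field(default_factory=dict)


@dataclass
class WeightTable:
    """Ordered integer score card: per feature, a weight per response level."""

    entries: list[FeatureWeights]
    scaling: float | None = None  # log-odds per score point
    rule: str = "ratio"

    def __iter__(self):
        return iter(self.entries)

    def feature_names(self) -> list[str]:
        return [e.feature for e in self.entries]

    def to_yaml(self, path) -> None:
        doc = {
            "rule": self.rule,
            "scaling": self.scaling,
            "features": [
                {
                    "feature": e.feature,
                    "rank": e.rank,
                    "levels": [{"level": lv, "weight": e.weights[lv]} for lv in e.levels],
                }
                for e in self.entries
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "WeightTable":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        entries = [
            FeatureWeights(
                feature=f["feature"],
                rank=f.get("rank"),
                levels=tuple(lv["level"] for lv in f["levels"]),
                weights={lv["level"]: int(lv["weight"]) for lv in f["levels"]},
            )
            for f in doc["features"]
        ]
        return cls(entries=entries, scaling=doc.get("scaling"), rule=doc.get("rule", "ratio"))

    def to_text(self) -> str:
        """Human-readable card mirroring a published score-card layout."""
        lines = [f"{'Feature':<28} {'Level':<24} {'Rank':>4} {'Weight':>6}"]
        for e in self.entries:
            for i, lv in enumerate(e.levels):
                feat = e.feature if i == 0 else ""
                rank = str(e.rank) if (i == 0 and e.rank is not None) else ""
                lines.append(f"{feat:<28} {lv:<24} {rank:>4} {e.weights[lv]:>6}")
        return "\n".join(lines)


def weights_from_coefficients(
    coefficients: dict[str, dict[str, float]],
    rule: str = "ratio",
    ranks: dict[str, int] | None = None,
) -> WeightTable:
    """Turn per-level log-odds coefficients into an integer score card.

    ``rule="ratio"`` (default): within each feature, recenter so the
    smallest coefficient is 0 (the reference level); divide all recentered
    coefficients by the smallest strictly positive recentered coefficient
    across the whole card; round half-away-from-zero. Scaling all input
    coefficients by a positive constant leaves the weights unchanged.

    ``rule="literal"``: within each feature, the smallest coefficient is
    the reference and every coefficient is divided by it directly and
    rounded — the literal reading of a divide-by-reference recipe; it is
    undefined when a reference coefficient is zero.
    """
    if rule not in ("ratio", "literal"):
        raise ValueError(f"unknown rule {rule!r}")
    entries: list[FeatureWeights] = []
    if rule == "ratio":
        recentered = {
            feat: {lv: c - min(levels.values()) for lv, c in levels.items()}
            for feat, levels in coefficients.items()
        }
        positives = [c for levels in recentered.values() for c in levels.values() if c > 0]
        scale = min(positives) if positives else 1.0
        for feat, levels in recentered.items():
            weights = {lv: round_half_away(c / scale) for lv, c in levels.items()}
            entries.append(
                FeatureWeights(
                    feature=feat,
                    rank=(ranks or {}).get(feat),
                    levels=tuple(coefficients[feat].keys()),
                    weights=weights,
                )
            )
        return WeightTable(entries=entries, scaling=scale, rule=rule)
    for feat, levels in coefficients.items():
        ref = min(levels.values())
        if abs(ref) < 1e-12:
            raise WeightDerivationError(
                f"literal rule undefined for feature {feat!r}: reference coefficient is 0"
            )
        weights = {lv: round_half_away(c / ref) for lv, c in levels.items()}
        entries.append(
            FeatureWeights(
                feature=feat,
                rank=(ranks or {}).get(feat),
                levels=tuple(levels.keys()),
                weights=weights,
            )
        )
    return WeightTable(entries=entries, scaling=None, rule=rule)


def fit_ordinal_coefficients(
    level_frame: pd.DataFrame,
    count_codes: pd.Series,
    scheme: DiscretizationScheme,
) -> dict[str, dict[str, float]]:
    """Proportional-odds (cumulative logit) fit of the ordinal count on the
    one-hot response levels of all features jointly; returns per-feature
    {level: coefficient} with each feature's first level pinned at 0."""
    design_cols = {}
    col_meta = []
    for feat, fl in scheme.levels.items():
        observed = set(level_frame[feat].unique())
        empty = [lv for lv in fl.labels if lv not in observed]
        if empty:
            raise WeightDerivationError(
                f"level(s) {empty} of feature {feat!r} have no observations"
            )
        for lv in fl.labels[1:]:  # first level is the fitting baseline
            design_cols[f"{feat}::{lv}"] = (level_frame[feat] == lv).astype(float)
            col_meta.append((feat, lv))
    X = pd.DataFrame(design_cols, index=level_frame.index)
    endog = pd.Series(
        pd.Categorical(
            pd.Series(count_codes).map(dict(enumerate(COUNT_CATEGORIES))),
            categories=list(COUNT_CATEGORIES),
            ordered=True,
        ),
        index=level_frame.index,
    )
    # hasconst=False: the cumulative-logit thresholds absorb the intercept,
    # so statsmodels' implicit-constant check (which can trip on collinear
    # building-level dummies in small building samples) is not wanted here.
    model = OrderedModel(endog, X, distr="logit", hasconst=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    if not res.mle_retvals.get("converged", False):
        raise WeightDerivationError("proportional-odds fit did not converge")
    coefs: dict[str, dict[str, float]] = {
        feat: {fl.labels[0]: 0.0} for feat, fl in scheme.levels.items()
    }
    for feat, lv in col_meta:
        coefs[feat][lv] = float(res.params[f"{feat}::{lv}"])
    # Restore level order.
    return {
        feat: {lv: coefs[feat][lv] for lv in scheme.levels[feat].labels}
        for feat in scheme.levels
    }


def derive_weights(
    cohort: Cohort,
    selected: list[str] | dict[str, int],
    scheme: DiscretizationScheme | None = None,
    grid=DEFAULT_GRID,
    rule: str = "ratio",
) -> tuple[WeightTable, DiscretizationScheme]:
    """Build the score card for the count outcome.

    ``selected`` is the ranked feature list (or {feature: rank}); the card
    keeps that order. Returns the weight table and the discretization
    scheme used (needed later to place new participants into levels).
    """
    if isinstance(selected, dict):
        ranks = dict(selected)
        features = sorted(ranks, key=lambda f: (ranks[f], f))
    else:
        features = list(selected)
        ranks = {f: i + 1 for i, f in enumerate(features)}
    scheme = scheme or discretize_cohort(cohort, features, grid=grid)
    level_frame = scheme.assign_frame(cohort.feature_frame(features))
    coefs = fit_ordinal_coefficients(level_frame, cohort.outcome_series("count"), scheme)
    ordered = {f: coefs[f] for f in features}
    table = weights_from_coefficients(ordered, rule=rule, ranks=ranks)
    return table, scheme


# ---------------------------------------------------------------------------
# Tally and stratification


def tally_score(levels: dict[str, str] | pd.Series, weights: WeightTable) -> int:
    """Total risk score: sum of the weights of the participant's levels."""
    total = 0
    for entry in weights:
        if entry.feature not in levels:
            raise ValueError(f"participant has no level for feature {entry.feature!r}")
        lv = str(levels[entry.feature])
        if lv not in entry.weights:
            raise ValueError(f"unknown level {lv!r} for feature {entry.feature!r}")
        total += entry.weights[lv]
    return total


def tally_cohort(
    cohort: Cohort, weights: WeightTable, scheme: DiscretizationScheme
) -> pd.Series:
    """Risk score for every participant."""
    frame = cohort.feature_frame(weights.feature_names())
    level_frame = scheme.assign_frame(frame)
    return level_frame.apply(lambda row: tally_score(row, weights), axis=1).rename("score")


@dataclass
class StratificationTable:
    """Distribution of the count category within ordered score bins."""

    table: pd.DataFrame  # index = bin label, columns = COUNT_CATEGORIES
    occupancy: pd.Series  # participants per bin

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["n"] = self.occupancy
        out.index.name = "total_score"
        out.to_csv(path)


def stratification_table(
    scores: pd.Series, counts: pd.Series, bins=INDIVIDUAL_BINS
) -> StratificationTable:
    """Row-normalized count-category composition per closed score bin.

    Bins must be non-overlapping closed integer intervals covering the
    observed score range. Empty bins keep occupancy 0 and NaN proportions.
    """
    bins = [tuple(b) for b in bins]
    ordered = sorted(bins)
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        if hi1 >= lo2:
            raise ValueError(f"overlapping bins [{lo1},{hi1}] and [{lo2},{hi2}]")
    for lo, hi in bins:
        if lo > hi:
            raise ValueError(f"bin [{lo},{hi}] is empty as an interval")
    uncovered = [
        s for s in scores if not any(lo <= s <= hi for lo, hi in bins)
    ]
    if uncovered:
        raise ValueError(
            f"scores outside all bins: {sorted(set(uncovered))[:5]} "
            f"(observed range {scores.min()}..{scores.max()})"
        )

    labels = [f"[{lo}, {hi}]" for lo, hi in bins]
    rows, occ = [], []
    counts = pd.Categorical(counts.astype(str), categories=list(COUNT_CATEGORIES))
    counts = pd.Series(counts, index=scores.index)
    for (lo, hi), label in zip(bins, labels):
        mask = (scores >= lo) & (scores <= hi)
        sub = counts[mask]
        n = int(mask.sum())
        occ.append(n)
        if n == 0:
            rows.append([np.nan] * len(COUNT_CATEGORIES))
        else:
            freq = sub.value_counts().reindex(list(COUNT_CATEGORIES)).fillna(0)
            rows.append((freq / n).tolist())
    table = pd.DataFrame(rows, index=labels, columns=list(COUNT_CATEGORIES))
    return StratificationTable(table=table, occupancy=pd.Series(occ, index=labels, name="n"))
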