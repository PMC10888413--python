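"""Per-outcome random forests, permutation importance and AUC evaluation.

The forest is an ensemble of CART trees on bootstrap subsamples with random
feature subsets per split. Trees are added in chunks up to a cap (default
500) with early stopping when out-of-bag accuracy stops improving. Feature
importance is the permutation kind: the drop in predictive accuracy when a
feature's column is replaced by a random permutation of itself, the outcome
held fixed. Discrimination is summarized by the validation AUC with a
percentile bootstrap confidence interval and the conventional band labels
(poor < 0.70 <= acceptable < 0.80 <= excellent <= 0.90 < outstanding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .cohort import Cohort, encode_features

AUC_BANDS = ("poor", "acceptable", "excellent", "outstanding")


@dataclass
class ForestConfig:
    """Training knobs for one forest."""

    n_trees: int = 500
    features_per_split: int | float | str = "sqrt"
    split_criterion: str = "gini"
    subsample_size: float = 1.0  # bootstrap sample fraction
    convergence_window: int = 50  # trees; early stop lookback
    convergence_tol: float = 1e-4  # min OOB-accuracy gain over the window
    chunk: int = 25  # trees added between OOB checks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.split_criterion not in ("gini", "entropy"):
            raise ValueError(f"unknown split criterion {self.split_criterion!r}")
        if isinstance(self.features_per_split, float) and not 0 < self.features_per_split <= 1:
            raise ValueError("features_per_split fraction must lie in (0,1]")
        if not 0 < self.subsample_size <= 1:
            raise ValueError("subsample_size must lie in (0,1]")


@dataclass
class ForestModel:
    """A fitted forest plus the metadata needed to score new cohort rows."""

    estimator: RandomForestClassifier
    pool: list[str]
    outcome: str
    dictionary: object
    oob_history: list[tuple[int, float]] = field(default_factory=list)

    @property
    def n_trees_used(self) -> int:
        return len(self.estimator.estimators_)

    def design(self, cohort: Cohort) -> pd.DataFrame:
        return encode_features(cohort.feature_frame(self.pool), cohort.dictionary, self.pool)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Majority-vote class labels (threshold 0.5 on the vote fraction)."""
        return self.estimator.predict(X.to_numpy())

    def predict_score(self, X: pd.DataFrame) -> np.ndarray:
        """Positive-class vote fraction (binary) or class-probability matrix."""
        proba = self.estimator.predict_proba(X.to_numpy())
        if proba.shape[1] == 2:
            return proba[:, 1]
        return proba


def split_cohort(
    cohort: Cohort, outcome: str, test_size: float = 0.3, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Stratified train/validation split on the outcome (default 70/30)."""
    y = cohort.outcome_series(outcome)
    idx_train, idx_val = train_test_split(
        cohort.participants.index.to_numpy(),
        test_size=test_size,
        random_state=seed,
        stratify=y.to_numpy(),
    )
    make = lambda idx: Cohort(
        participants=cohort.participants.loc[idx].copy(),
        buildings=cohort.buildings,
        dictionary=cohort.dictionary,
    )
    return make(np.sort(idx_train)), make(np.sort(idx_val))


def fit_forest(
    cohort: Cohort, outcome: str, pool: list[str] | str, config: ForestConfig | None = None
) -> ForestModel:
    """Train a forest for one outcome on a feature pool.

    Trees are grown warm-start in chunks; training stops once the cap is
    reached or OOB accuracy has improved by less than ``convergence_tol``
    over the last ``convergence_window`` trees.
    """
    config = config or ForestConfig()
    pool_names = cohort.dictionary.pool(pool) if isinstance(pool, str) else list(pool)
    if not pool_names:
        raise ValueError("feature pool is empty")

    X = encode_features(cohort.feature_frame(pool_names), cohort.dictionary, pool_names)
    y = cohort.outcome_series(outcome).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome!r} has a single class; AUC undefined")

    est = RandomForestClassifier(
        n_estimators=0,
        criterion=config.split_criterion,
        max_features=config.features_per_split,
        max_samples=None if config.subsample_size >= 1.0 else config.subsample_size,
        bootstrap=True,
        oob_score=True,
        warm_start=True,
        random_state=config.seed,
        n_jobs=1,
    )

    history: list[tuple[int, float]] = []
    n = 0
    while n < config.n_trees:
        n = min(n + config.chunk, config.n_trees)
        est.set_params(n_estimators=n)
        est.fit(X.to_numpy(), y)
        history.append((n, float(est.oob_score_)))
        lookback = [acc for k, acc in history if k <= n - config.convergence_window]
        if lookback and history[-1][1] - lookback[-1] < config.convergence_tol:
            break

    model = ForestModel(
        estimator=est, pool=pool_names, outcome=outcome,
        dictionary=cohort.dictionary, oob_history=history,
    )
    return model


@dataclass
class ImportanceVector:
    """Permutation importances: mean accuracy drop, per-repeat values kept."""

    means: pd.Series  # indexed by feature (or group) name
    repeats: pd.DataFrame  # columns = feature names, rows = repeats
    baseline_accuracy: float

    def se(self) -> pd.Series:
        return self.repeats.std(axis=0, ddof=1) / np.sqrt(len(self.repeats))


def permutation_importance(
    model: ForestModel,
    cohort: Cohort,
    n_repeats: int = 10,
    seed: int = 0,
    groups: dict[str, list[str]] | None = None,
) -> ImportanceVector:
    """Accuracy drop under per-feature permutation on ``cohort``.

    ``groups`` optionally maps a group name to several columns permuted
    jointly (with one shared row permutation), which measures the combined
    contribution of collinear features; ungrouped features are permuted
    singly as usual.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = model.design(cohort)
    y = cohort.outcome_series(model.outcome).to_numpy()
    baseline = float(np.mean(model.predict(X) == y))

    units: dict[str, list[str]] = {}
    grouped_cols: set[str] = set()
    if groups:
        for gname, cols in groups.items():
            units[gname] = list(cols)
            grouped_cols.update(cols)
    for col in model.pool:
        if col not in grouped_cols:
            units[col] = [col]

    rng = np.random.default_rng(seed)
    rows = np.arange(len(X))
    drops = {name: [] for name in units}
    for _ in range(n_repeats):
        for name, cols in units.items():
            perm = rng.permutation(rows)
            Xp = X.copy()
            Xp.loc[:, cols] = X[cols].to_numpy()[perm]
            acc = float(np.mean(model.predict(Xp) == y))
            drops[name].append(baseline - acc)
    repeats = pd.DataFrame(drops)
    return ImportanceVector(
        means=repeats.mean(axis=0), repeats=repeats, baseline_accuracy=baseline
    )


def rank_features(importance: ImportanceVector) -> dict[str, int]:
    """Dense ranking of strictly positive importances, 1 = most important.

    Nonpositive importance means permuting the feature did not hurt the
    model, so the feature goes unranked. Ties break lexicographically.
    """
    positive = importance.means[importance.means > 0]
    ordered = sorted(positive.items(), key=lambda kv: (-kv[1], kv[0]))
    return {name: i + 1 for i, (name, _) in enumerate(ordered)}


def band_auc(auc: float) -> str:
    """Discrimination band for an AUC value."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC {auc} outside [0, 1]")
    if auc < 0.70:
        return "poor"
    if auc < 0.80:
        return "acceptable"
    if auc <= 0.90:
        return "excellent"
    return "outstanding"


@dataclass
class ModelEval:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    band: str


def bootstrap_auc_ci(
    y: np.ndarray, score: np.ndarray, n_boot: int = 100, seed: int = 0
) -> tuple[float, float]:
    """Percentile 95% CI of the AUC over bootstrap resamples of the rows.

    Resamples that lose one outcome class (possible for rare outcomes) are
    redrawn, so every replicate contributes a defined AUC.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = []
    for _ in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) > 1:
                break
        else:
            raise ValueError("could not draw a two-class bootstrap resample")
        aucs.append(roc_auc_score(y[idx], score[idx]))
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def evaluate_model(
    model: ForestModel, validation: Cohort, n_boot: int = 100, seed: int = 0
) -> ModelEval:
    """Validation AUC with a percentile bootstrap 95% CI and band label."""
    X = model.design(validation)
    y = validation.outcome_series(model.outcome).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("validation set has a single outcome class")
    score = model.predict_score(X)
    if score.ndim > 1:  # multiclass count model: macro one-vs-rest
        auc = float(roc_auc_score(y, score, multi_class="ovr", average="macro"))
        lo = hi = auc  # bootstrap CI reported for binary outcomes only
    else:
        auc = float(roc_auc_score(y, score))
        lo, hi = bootstrap_auc_ci(y, score, n_boot=n_boot, seed=seed)
    return ModelEval(auc=auc, ci_low=lo, ci_high=hi, n_boot=n_boot, band=band_auc(auc))
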