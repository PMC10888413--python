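"""End-to-end orchestration: simulate -> train per outcome x pool -> rank ->
aggregate -> score card -> tally -> stratify, with all artifacts written
deterministically from (config, seed)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .features import OUTCOME_AREAS
from .forest import (
    ForestConfig,
    evaluate_model,
    fit_forest,
    permutation_importance,
    rank_features,
    split_cohort,
)
from .ranking import DEFAULT_OFFSET, RankTable, summative_scores
from .scorecard import (
    DEFAULT_GRID,
    INDIVIDUAL_BINS,
    MIXED_BINS,
    derive_weights,
    stratification_table,
    tally_cohort,
)
from .simulate import EffectConfig, MarginalConfig, simulate_cohort

log = logging.getLogger("painstrat")

POOLS = ("individual", "mixed")


@dataclass
class RunConfig:
    """Everything a full run depends on; round-trips through YAML."""

    seed: int = 0
    n_participants: int = 2000
    n_buildings: int = 30
    building_effects: bool = True
    split_ratio: float = 0.3
    n_trees: int = 500
    n_repeats: int = 5
    n_boot: int = 100
    offset: int = DEFAULT_OFFSET
    grid: tuple = DEFAULT_GRID
    top_k: int = 10  # features carried into the score card
    bins: dict = field(
        default_factory=lambda: {"individual": INDIVIDUAL_BINS, "mixed": MIXED_BINS}
    )

    def to_yaml(self, path) -> None:
        doc = {
            **{k: getattr(self, k) for k in (
                "seed", "n_participants", "n_buildings", "building_effects",
                "split_ratio", "n_trees", "n_repeats", "n_boot", "offset", "top_k",
            )},
            "grid": list(self.grid),
            "bins": {p: [list(b) for b in bs] for p, bs in self.bins.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if "grid" in doc:
            doc["grid"] = tuple(doc["grid"])
        if "bins" in doc:
            doc["bins"] = {p: tuple(tuple(b) for b in bs) for p, bs in doc["bins"].items()}
        return cls(**doc)


def train_all(cohort: Cohort, config: RunConfig) -> dict:
    """Fit, evaluate and rank a forest for every area x pool plus the
    count-supervised model per pool. Returns a nested result dict."""
    results: dict = {}
    fc = ForestConfig(n_trees=config.n_trees, seed=config.seed)
    for pool in POOLS:
        per_area_ranks: dict[str, dict[str, int]] = {}
        pool_res: dict = {"areas": {}, "ranks": None, "count": None}
        for area in OUTCOME_AREAS:
            train, val = split_cohort(cohort, area, test_size=config.split_ratio, seed=config.seed)
            model = fit_forest(train, area, pool, fc)
            ev = evaluate_model(model, val, n_boot=config.n_boot, seed=config.seed)
            imp = permutation_importance(model, val, n_repeats=config.n_repeats, seed=config.seed)
            ranks = rank_features(imp)
            per_area_ranks[area] = ranks
            pool_res["areas"][area] = {
                "auc": ev.auc, "ci": [ev.ci_low, ev.ci_high], "band": ev.band,
                "n_trees": model.n_trees_used,
                "importance": imp.means.to_dict(), "ranks": ranks,
            }
            log.info("pool=%s area=%s auc=%.3f band=%s trees=%d",
                     pool, area, ev.auc, ev.band, model.n_trees_used)
        pool_res["rank_table"] = RankTable.from_rankings(per_area_ranks)

        train, val = split_cohort(cohort, "count", test_size=config.split_ratio, seed=config.seed)
        cmodel = fit_forest(train, "count", pool, fc)
        cimp = permutation_importance(cmodel, val, n_repeats=config.n_repeats, seed=config.seed)
        pool_res["count"] = {"ranks": rank_features(cimp), "importance": cimp.means.to_dict()}
        results[pool] = pool_res
    return results


def run_pipeline(config: RunConfig, out_dir, cohort: Cohort | None = None) -> dict:
    """Run the whole pipeline and write the report bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run start seed=%d n=%d", config.seed, config.n_participants)

    if cohort is None:
        cohort = simulate_cohort(
            n_participants=config.n_participants,
            n_buildings=config.n_buildings,
            seed=config.seed,
            effects=EffectConfig.default(building_effects=config.building_effects),
        )
    cohort.write_csv(out / "participants.csv", out / "buildings.csv")

    trained = train_all(cohort, config)

    metrics: dict = {"seed": config.seed, "n": cohort.n, "pools": {}}
    for pool in POOLS:
        res = trained[pool]
        rank_table: RankTable = res["rank_table"]
        rank_table.to_csv(out / f"ranks_{pool}.csv")
        scores = summative_scores(rank_table, offset=config.offset)
        scores.to_csv(out / f"summative_scores_{pool}.csv")

        count_ranks = res["count"]["ranks"]
        selected = dict(
            sorted(count_ranks.items(), key=lambda kv: kv[1])[: config.top_k]
        )
        weights, scheme = derive_weights(cohort, selected, grid=config.grid)
        weights.to_yaml(out / f"scorecard_{pool}.yaml")
        (out / f"scorecard_{pool}.txt").write_text(weights.to_text() + "\n", encoding="utf-8")

        tallies = tally_cohort(cohort, weights, scheme)
        lo, hi = int(tallies.min()), int(tallies.max())
        bins = [
            b for b in map(tuple, config.bins[pool])
        ]
        covered = all(any(blo <= s <= bhi for blo, bhi in bins) for s in tallies)
        if not covered:  # widen default bins to the realized score range
            bins = _auto_bins(lo, hi, len(bins))
        strat = stratification_table(tallies, cohort.participants["count_category"], bins)
        strat.to_csv(out / f"stratification_{pool}.csv")

        aucs = {a: res["areas"][a]["auc"] for a in OUTCOME_AREAS}
        metrics["pools"][pool] = {
            "areas": res["areas"],
            "mean_auc": float(np.mean(list(aucs.values()))),
            "score_range": [lo, hi],
            "bins": [list(b) for b in bins],
        }
    metrics["auc_gap"] = {
        a: metrics["pools"]["mixed"]["areas"][a]["auc"]
        - metrics["pools"]["individual"]["areas"][a]["auc"]
        for a in OUTCOME_AREAS
    }
    with open(out / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)

    summary = [
        f"seed={config.seed} n={cohort.n} buildings={len(cohort.buildings)}",
        "area AUCs (individual vs mixed):",
    ]
    for a in OUTCOME_AREAS:
        ind = metrics["pools"]["individual"]["areas"][a]
        mix = metrics["pools"]["mixed"]["areas"][a]
        summary.append(
            f"  {a:<14} {ind['auc']:.3f} ({ind['band']})  vs  {mix['auc']:.3f} ({mix['band']})"
        )
    (out / "summary.txt").write_text("\n".join(summary) + "\n", encoding="utf-8")
    return metrics


def _auto_bins(lo: int, hi: int, k: int) -> list[tuple[int, int]]:
    """Equal-width closed integer bins covering [lo, hi]."""
    edges = np.linspace(lo, hi + 1, k + 1).astype(int)
    bins = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - 1 >= a:
            bins.append((int(a), int(b - 1)))
    if not bins:
        bins = [(lo, hi)]
    return bins
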