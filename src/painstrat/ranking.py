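"""Reverse-coded rank aggregation across the five interference areas.

Each per-area forest yields a rank ordering of its feature pool. To combine
the five orderings into a single importance score per feature, each rank r
is reverse-coded as max(C - r, 0) with offset C (default 21, one more than
a 20-feature pool, so rank 1 is worth 20 points) and the five reverse-coded
values are summed. A feature left unranked by an area's model contributes
zero for that area — absence of evidence is not penalized further.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import OUTCOME_AREAS

DEFAULT_OFFSET = 21


@dataclass
class RankTable:
    """Feature x area matrix of ranks; NaN marks an unranked entry."""

    ranks: pd.DataFrame  # index = feature, columns = OUTCOME_AREAS, float w/ NaN

    def __post_init__(self) -> None:
        missing = [c for c in OUTCOME_AREAS if c not in self.ranks.columns]
        if missing:
            raise ValueError(f"rank table missing outcome columns: {missing}")
        self.ranks = self.ranks[list(OUTCOME_AREAS)].astype(float)
        for col in OUTCOME_AREAS:
            vals = self.ranks[col].dropna()
            if (vals < 1).any() or (vals != vals.round()).any():
                raise ValueError(f"ranks in column {col!r} must be positive integers")
            if vals.duplicated().any():
                dup = sorted(vals[vals.duplicated()].unique().astype(int).tolist())
                raise ValueError(f"duplicate ranks {dup} within column {col!r}")

    @classmethod
    def from_rankings(cls, per_area: dict[str, dict[str, int]]) -> "RankTable":
        """Build from per-area {feature: rank} mappings (e.g. rank_features
        output per outcome)."""
        features = sorted({f for ranks in per_area.values() for f in ranks})
        frame = pd.DataFrame(index=features, columns=list(OUTCOME_AREAS), dtype=float)
        for area in OUTCOME_AREAS:
            for feat, r in per_area.get(area, {}).items():
                frame.loc[feat, area] = r
        return cls(frame)

    def to_csv(self, path) -> None:
        out = self.ranks.copy()
        out.index.name = "feature"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "RankTable":
        return cls(pd.read_csv(path, index_col="feature"))


def reverse_coded_rank(rank: int | float | None, offset: int = DEFAULT_OFFSET) -> int:
    """Reverse-code one rank: offset - rank, floored at zero; unranked
    (None/NaN) contributes zero."""
    if offset < 2:
        raise ValueError("offset must be >= 2")
    if rank is None or (isinstance(rank, float) and np.isnan(rank)):
        return 0
    r = int(rank)
    if r != rank or r <= 0:
        raise ValueError(f"rank must be a positive integer, got {rank!r}")
    return max(offset - r, 0)


@dataclass
class ScoreTable:
    """Summative scores per feature, sorted descending (ties by name)."""

    scores: pd.Series  # index = feature, int
    offset: int

    def to_csv(self, path) -> None:
        out = self.scores.rename("score").to_frame()
        out.index.name = "feature"
        out.to_csv(path)


def summative_scores(ranks: RankTable, offset: int = DEFAULT_OFFSET) -> ScoreTable:
    """Sum each feature's reverse-coded ranks over the five areas."""
    coded = ranks.ranks.map(lambda r: reverse_coded_rank(r, offset))
    totals = coded.sum(axis=1).astype(int)
    ordered = totals.sort_index().sort_values(ascending=False, kind="stable")
    return ScoreTable(scores=ordered, offset=offset)
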