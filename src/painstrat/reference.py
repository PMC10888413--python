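"""Bundled worked-example inputs: the published feature-importance rank
tables from the working-poor pain-interference study this tool
operationalizes, together with the summative scores and AUCs printed
alongside them.

Each entry maps a feature label to its per-area ranks in the order
(mood, daily activities, sleeping quality, social life, work performance);
``None`` marks an entry the area's model left unranked. The tables let the
rank-aggregation arithmetic be exercised end-to-end without access to the
underlying (privacy-restricted) cohort.
"""

from __future__ import annotations

import pandas as pd

from .features import OUTCOME_AREAS
from .ranking import RankTable

#: Ranking from the model restricted to individual-level features,
#: with its published summative score per feature.
INDIVIDUAL_MODEL_RANKS: dict[str, tuple] = {
    # feature: ((mood, daily, sleep, social, work), published score)
    "Age": ((1, 1, 1, 1, 2), 99),
    "Main Occupation": ((4, 2, 3, 4, 1), 91),
    "Pain intensity: mild condition": ((2, 3, 2, 3, 4), 91),
    "Pain intensity: severe condition": ((3, 4, 4, 2, 3), 89),
    "BMI": ((5, 5, 5, 5, 5), 80),
    "Blood Glucose": ((7, 6, 9, 12, 6), 65),
    "Pain Position: Shoulder": ((8, 9, 8, 6, 10), 64),
    "Pain Position: Lower back": ((9, 7, 7, 8, 11), 63),
    "Pain Position: Knee": ((10, 8, 10, 10, 8), 59),
    "Pain Position: Hand": ((12, 11, 6, 9, 9), 58),
    "Pain Position: Neck": ((6, 13, 11, 13, 12), 50),
    "Blood Pressure": ((14, 12, 13, 11, 7), 48),
    "Pain Position: Foot": ((13, 14, 12, 7, 14), 45),
    "Sex": ((11, 10, 15, 14, 13), 42),
    "Pain Position: Other": ((15, 16, 16, 16, 15), 27),
    "Pain Position: Upper back": ((18, 15, 14, None, 16), 21),
    "Drinker": ((16, None, 18, 15, 17), 18),
    "Smoker": ((None, 17, 17, None, 18), 11),
    "Pain Position: Elbow": ((17, None, None, 17, None), 8),
    "Sub-divided flat": ((None, 18, None, 18, None), 6),
}

#: Ranking from the mixed individual- and building-level model.
MIXED_MODEL_RANKS: dict[str, tuple] = {
    "Cardinal orientation": ((1, 1, 4, 1, 1), 97),
    "Age": ((3, 2, 1, 2, 3), 94),
    "Main Occupation": ((5, 3, 3, 7, 2), 85),
    "Pain intensity: mild condition": ((2, 4, 5, 4, 7), 83),
    "Pain intensity: severe condition": ((4, 8, 2, 5, 6), 80),
    "Proportion of flat with <3 non-functional room": ((7, 7, 6, 3, 4), 78),
    "Age of the building": ((6, 5, 7, 6, 8), 73),
    "BMI": ((8, 6, 8, 8, 5), 70),
    "Number of corridors of the building": ((11, 11, 10, 13, 9), 51),
    "Number of lifts": ((12, 12, 13, 15, 11), 42),
    "Number of light wells": ((9, 9, None, 9, None), 36),
    "Pain Position: Lower back": ((14, 14, 14, 10, 14), 39),
    "Pain Position: Knee": ((13, 10, 11, 17, None), 33),
    "Blood Pressure": ((15, 15, 16, 14, 12), 33),
    "Pain Position: Hand": ((16, 17, 9, 18, 16), 29),
    "Pain Position: Neck": ((10, 16, 15, None, 17), 26),
    "Blood Glucose": ((17, None, 12, None, 10), 24),
    "Presence of terrace": ((18, None, None, 12, 15), 18),
    "Pain Position: Shoulder": ((None, 18, None, 11, None), 13),
    "Pain Position: Foot": ((19, None, 17, 19, 13), 16),
    "Pain Position: Other": ((None, 13, None, None, None), 8),
    "Pain Position: Upper back": ((None, None, None, 16, None), 5),
    "Sex": ((None, None, None, None, 18), 3),
}

#: AUCs published for the count-supervised score-card models.
INDIVIDUAL_CARD_AUC = 0.7129
MIXED_CARD_AUC = 0.9085

#: Validation AUCs published for the five per-area forests.
INDIVIDUAL_AREA_AUCS = (0.76, 0.78, 0.78, 0.79, 0.84)
MIXED_AREA_AUCS = (0.96, 0.98, 0.94, 0.99, 0.99)

#: First row of the published individual-card stratification table,
#: bin [21, 40]: composition over count categories 0-1 / 2 / 3 / 4+.
INDIVIDUAL_STRATIFICATION_ROW_21_40 = (0.600, 0.250, 0.075, 0.075)


def rank_table(which: str = "individual") -> RankTable:
    """The bundled ranking as a :class:`RankTable` (``"individual"`` or
    ``"mixed"``)."""
    source = {"individual": INDIVIDUAL_MODEL_RANKS, "mixed": MIXED_MODEL_RANKS}[which]
    frame = pd.DataFrame(
        {feat: list(ranks) for feat, (ranks, _score) in source.items()},
        index=list(OUTCOME_AREAS),
    ).T
    return RankTable(frame.astype(float))


def published_scores(which: str = "individual") -> pd.Series:
    """The published summative scores, indexed by feature label."""
    source = {"individual": INDIVIDUAL_MODEL_RANKS, "mixed": MIXED_MODEL_RANKS}[which]
    return pd.Series({feat: score for feat, (_ranks, score) in source.items()})
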