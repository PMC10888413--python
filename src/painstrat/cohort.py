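"""Cohort container, validation and CSV I/O.

A :class:`Cohort` holds one row per participant (individual-level features,
a ``building_id`` joining to a building table, and the six outcomes: five
binary pain-interference areas plus the ordinal count category) together
with the building table itself and the governing feature dictionary.

Completeness is a precondition: missing values are rejected at validation,
never imputed. The ordinal count category is always recomputed from the
five binaries under the mapping {sum<=1 -> "0-1", 2 -> "2", 3 -> "3",
>=4 -> "4+"} and, when an input file supplies its own column, the two are
required to agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    COUNT_CATEGORIES,
    OUTCOME_AREAS,
    FeatureDictionary,
    default_dictionary,
)

OUTCOME_COLUMNS = tuple(OUTCOME_AREAS) + ("count_category",)

BUILDING_COLUMNS = (
    "cardinal_orientation",
    "n_flats",
    "n_corridors",
    "n_lifts",
    "n_light_wells",
    "building_age",
    "prop_small_flats",
    "has_reentrant_bay",
    "has_terrace",
    "density",
)


class CohortValidationError(ValueError):
    """Raised when cohort data violate the dictionary or outcome contracts."""


def count_category(n_areas: int) -> str:
    """Map a count of pain-interfered areas (0-5) to its ordinal category."""
    if not 0 <= n_areas <= len(OUTCOME_AREAS):
        raise ValueError(f"count {n_areas} outside 0..{len(OUTCOME_AREAS)}")
    if n_areas <= 1:
        return "0-1"
    if n_areas >= 4:
        return "4+"
    return str(n_areas)


def count_categories_from_binaries(frame: pd.DataFrame) -> pd.Series:
    """Derive the count category for every row from the five binary areas."""
    total = frame[list(OUTCOME_AREAS)].sum(axis=1)
    return total.map(count_category)


@dataclass
class Cohort:
    """Validated participant table + building table + dictionary."""

    participants: pd.DataFrame
    buildings: pd.DataFrame
    dictionary: FeatureDictionary = field(default_factory=default_dictionary)

    @property
    def n(self) -> int:
        return len(self.participants)

    def has_outcomes(self) -> bool:
        return all(c in self.participants.columns for c in OUTCOME_COLUMNS)

    def feature_frame(self, pool: str | list[str]) -> pd.DataFrame:
        """Participant rows restricted to a feature pool, with building-level
        columns joined in from the building table."""
        names = self.dictionary.pool(pool) if isinstance(pool, str) else list(pool)
        merged = self.participants.merge(
            self.buildings, on="building_id", how="left", validate="many_to_one"
        )
        merged.index = self.participants.index
        return merged[names]

    def outcome_series(self, outcome: str) -> pd.Series:
        """One of the five binary areas (0/1) or ``"count"`` (ordinal codes)."""
        if outcome == "count":
            codes = pd.Categorical(
                self.participants["count_category"],
                categories=list(COUNT_CATEGORIES),
                ordered=True,
            ).codes
            return pd.Series(codes, index=self.participants.index, name="count")
        if outcome not in OUTCOME_AREAS:
            raise ValueError(f"unknown outcome {outcome!r}")
        return self.participants[outcome].astype(int)

    def validate(self) -> "Cohort":
        _validate_buildings(self.buildings)
        _validate_participants(self.participants, self.buildings, self.dictionary)
        return self

    # ------------------------------------------------------------------ I/O

    def write_csv(self, participant_path, building_path) -> None:
        self.participants.to_csv(participant_path, index=False)
        self.buildings.to_csv(building_path, index=False)


def _require_columns(frame: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"{what} table missing columns: {missing}")


def _validate_buildings(buildings: pd.DataFrame) -> None:
    _require_columns(buildings, ("building_id",), "building")
    if buildings["building_id"].duplicated().any():
        dup = buildings.loc[buildings["building_id"].duplicated(), "building_id"].tolist()
        raise CohortValidationError(f"duplicate building ids: {dup}")
    if buildings.isna().any().any():
        bad = buildings.columns[buildings.isna().any()].tolist()
        raise CohortValidationError(f"missing values in building columns: {bad}")
    for col in ("n_flats", "n_corridors", "n_lifts", "n_light_wells"):
        if col in buildings.columns and (buildings[col] < 0).any():
            raise CohortValidationError(f"negative counts in building column {col!r}")
    if "prop_small_flats" in buildings.columns:
        p = buildings["prop_small_flats"]
        if ((p < 0) | (p > 1)).any():
            raise CohortValidationError("prop_small_flats outside [0, 1]")


def _validate_participants(
    participants: pd.DataFrame, buildings: pd.DataFrame, dictionary: FeatureDictionary
) -> None:
    individual = dictionary.names(level="individual")
    _require_columns(participants, ["participant_id", "building_id"] + individual, "participant")

    if participants["participant_id"].duplicated().any():
        raise CohortValidationError("duplicate participant ids")

    unresolved = set(participants["building_id"]) - set(buildings["building_id"])
    if unresolved:
        raise CohortValidationError(f"unresolvable building ids: {sorted(unresolved)}")

    cols = ["participant_id", "building_id"] + individual
    if participants[cols].isna().any().any():
        bad = [c for c in cols if participants[c].isna().any()]
        raise CohortValidationError(f"missing values in participant columns: {bad}")

    for spec in dictionary:
        if spec.level != "individual" or not spec.is_discrete:
            continue
        observed = participants[spec.name]
        unknown = set(observed.astype(str)) - set(spec.categories)
        if unknown:
            rows = participants.index[observed.astype(str).isin(unknown)].tolist()
            raise CohortValidationError(
                f"unknown category {sorted(unknown)} in column {spec.name!r} (rows {rows[:5]})"
            )

    if all(c in participants.columns for c in OUTCOME_AREAS):
        for area in OUTCOME_AREAS:
            vals = set(participants[area].unique())
            if not vals <= {0, 1}:
                raise CohortValidationError(f"outcome {area!r} not 0/1: {sorted(vals)}")
        derived = count_categories_from_binaries(participants)
        if "count_category" in participants.columns:
            mismatch = participants["count_category"].astype(str) != derived
            if mismatch.any():
                ids = participants.loc[mismatch, "participant_id"].tolist()
                raise CohortValidationError(
                    "count_category inconsistent with the five binary areas for "
                    f"participants {ids[:10]}"
                )
        else:
            participants["count_category"] = derived


def load_cohort(
    participant_path,
    building_path=None,
    dictionary: FeatureDictionary | None = None,
) -> Cohort:
    """Load and validate a cohort from CSV.

    Two-file form: a participant table joined on ``building_id`` to a
    building table. One-file denormalized form (``building_path=None``):
    building columns repeated per participant row, from which the building
    table is reconstructed (values must be constant within building).
    """
    dictionary = dictionary or default_dictionary()
    participants = pd.read_csv(Path(participant_path))
    if building_path is not None:
        buildings = pd.read_csv(Path(building_path))
    else:
        present = [c for c in BUILDING_COLUMNS if c in participants.columns]
        _require_columns(participants, ["building_id"] + list(present), "denormalized participant")
        grouped = participants.groupby("building_id")[present].nunique()
        varying = grouped.columns[(grouped > 1).any()].tolist()
        if varying:
            raise CohortValidationError(
                f"building columns vary within building in denormalized input: {varying}"
            )
        buildings = (
            participants[["building_id"] + present].drop_duplicates("building_id").reset_index(drop=True)
        )
        participants = participants.drop(columns=present)
    cohort = Cohort(participants=participants, buildings=buildings, dictionary=dictionary)
    return cohort.validate()


def encode_features(
    frame: pd.DataFrame, dictionary: FeatureDictionary, names: list[str]
) -> pd.DataFrame:
    """Numeric design frame for tree models: continuous columns pass through,
    discrete columns become integer codes in dictionary category order."""
    out = {}
    for name in names:
        spec = dictionary[name]
        col = frame[name]
        if spec.is_discrete:
            codes = pd.Categorical(col.astype(str), categories=list(spec.categories)).codes
            if (codes < 0).any():
                raise CohortValidationError(f"unmapped category while encoding {name!r}")
            out[name] = codes.astype(np.int64)
        else:
            out[name] = pd.to_numeric(col).to_numpy(dtype=float)
    return pd.DataFrame(out, index=frame.index)
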