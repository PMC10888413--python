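"""Feature dictionary: typed specifications for cohort columns.

Every column the pipeline touches is declared by a :class:`FeatureSpec`
stating its measurement kind (continuous / ordinal / categorical / binary),
whether it lives at the individual or the building level, whether it is a
candidate predictor or a fixed adjustment, and — for discrete kinds — the
ordered category labels. Category order is authoritative: ordinal models
downstream rely on it, and it is never inferred from data order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

KINDS = ("continuous", "ordinal", "categorical", "binary")
LEVELS = ("individual", "building")
ROLES = ("candidate", "adjustment")

#: The five pain-interference areas, in canonical reporting order.
OUTCOME_AREAS = ("mood", "daily_activity", "sleep", "social", "work")

#: Ordinal categories for the count of pain-interfered areas.
COUNT_CATEGORIES = ("0-1", "2", "3", "4+")


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of a single cohort column."""

    name: str
    kind: str
    level: str = "individual"
    role: str = "candidate"
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for feature {self.name!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r} for feature {self.name!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for feature {self.name!r}")
        if self.kind == "continuous":
            if self.categories:
                raise ValueError(f"continuous feature {self.name!r} must not list categories")
        else:
            if len(self.categories) < 2:
                raise ValueError(
                    f"{self.kind} feature {self.name!r} needs >=2 categories, "
                    f"got {len(self.categories)}"
                )
            if len(set(self.categories)) != len(self.categories):
                raise ValueError(f"duplicate categories in feature {self.name!r}")

    @property
    def is_discrete(self) -> bool:
        return self.kind != "continuous"


@dataclass
class FeatureDictionary:
    """Ordered collection of :class:`FeatureSpec`, unique by name."""

    specs: list[FeatureSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dup}")

    def __iter__(self):
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.specs)

    def __getitem__(self, name: str) -> FeatureSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def names(self, level: str | None = None, role: str | None = None) -> list[str]:
        """Feature names, optionally filtered by level and/or role."""
        return [
            s.name
            for s in self.specs
            if (level is None or s.level == level) and (role is None or s.role == role)
        ]

    def pool(self, which: str) -> list[str]:
        """Candidate-feature pool: ``"individual"`` or ``"mixed"``."""
        if which == "individual":
            return self.names(level="individual", role="candidate")
        if which == "mixed":
            return self.names(role="candidate")
        raise ValueError(f"unknown pool {which!r} (expected 'individual' or 'mixed')")

    # ------------------------------------------------------------------ I/O

    def to_yaml(self, path) -> None:
        entries = [
            {
                "name": s.name,
                "kind": s.kind,
                "level": s.level,
                "role": s.role,
                "categories": list(s.categories),
            }
            for s in self.specs
        ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(entries, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "FeatureDictionary":
        with open(path, encoding="utf-8") as fh:
            entries = yaml.safe_load(fh)
        return cls(
            [
                FeatureSpec(
                    name=e["name"],
                    kind=e["kind"],
                    level=e.get("level", "individual"),
                    role=e.get("role", "candidate"),
                    categories=tuple(e.get("categories") or ()),
                )
                for e in entries
            ]
        )


OCCUPATIONS = (
    "Catering Staff",
    "Cleaning Worker",
    "Clerk",
    "Driver",
    "Domestic Helper",
    "Sales",
    "Security Guard/Watchman",
    "Technician",
    "Construction/Manual Worker",
)

ORIENTATIONS = (
    "East",
    "North",
    "Northeast",
    "Northwest",
    "South",
    "Southeast",
    "Southeast and Northwest",
    "Southwest",
    "West",
)

BMI_CLASSES = (
    "Underweight",
    "Normal weight",
    "Pre-obesity",
    "Obesity class (mid)",
    "Obesity class (severe)",
)

PAIN_POSITIONS = (
    "elbow",
    "foot",
    "hand",
    "knee",
    "lower_back",
    "neck",
    "shoulder",
    "upper_back",
    "other",
)

_YN = ("No", "Yes")


def default_dictionary() -> FeatureDictionary:
    """The study's feature pool: individual-level demographics, biometrics,
    pain characteristics and behaviours, plus building-level architectural
    features of the public-housing block each participant lives in."""
    specs: list[FeatureSpec] = [
        FeatureSpec("age", "continuous"),
        FeatureSpec("sex", "binary", categories=("F", "M")),
        FeatureSpec("occupation", "categorical", categories=OCCUPATIONS),
        FeatureSpec("blood_pressure", "ordinal", categories=("Low", "Normal", "High")),
        FeatureSpec("bmi_class", "ordinal", categories=BMI_CLASSES),
        FeatureSpec("blood_glucose", "ordinal", categories=("Low", "Normal", "High")),
        FeatureSpec("drinker", "binary", categories=_YN),
        FeatureSpec("smoker", "binary", categories=_YN),
        FeatureSpec("pain_mild", "continuous"),
        FeatureSpec("pain_severe", "continuous"),
        FeatureSpec("subdivided_flat", "binary", categories=_YN),
        FeatureSpec("followup_plan", "binary", role="adjustment", categories=_YN),
        FeatureSpec("covid_period", "binary", role="adjustment", categories=("wave 4-5", "wave 5")),
    ]
    specs += [
        FeatureSpec(f"pain_{pos}", "binary", categories=_YN) for pos in PAIN_POSITIONS
    ]
    specs += [
        FeatureSpec("cardinal_orientation", "categorical", level="building", categories=ORIENTATIONS),
        FeatureSpec("n_flats", "continuous", level="building"),
        FeatureSpec("n_corridors", "continuous", level="building"),
        FeatureSpec("n_lifts", "continuous", level="building"),
        FeatureSpec("n_light_wells", "continuous", level="building"),
        FeatureSpec("building_age", "continuous", level="building"),
        FeatureSpec("prop_small_flats", "continuous", level="building"),
        FeatureSpec("has_reentrant_bay", "binary", level="building", categories=_YN),
        FeatureSpec("has_terrace", "binary", level="building", categories=_YN),
        FeatureSpec("density", "continuous", level="building"),
    ]
    return FeatureDictionary(specs)
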