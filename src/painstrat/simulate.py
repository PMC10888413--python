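"""Synthetic working-poor cohort generator.

Real data for this kind of study are privacy-restricted, so the generator
produces public-housing buildings, residents and pain-interference outcomes
with the marginal structure of the study population: continuous features as
(truncated) normals with the published means/SDs, discrete features from
the published prevalence vectors, participants assigned to buildings in
proportion to flat counts, and outcomes planted through per-area logistic
models whose intercepts are calibrated by bisection so each area hits its
target prevalence.

Planted effects are configurable per feature at both the individual and the
building level, which is what makes the downstream claims testable: a
cohort with nonzero building-level coefficients is one where a mixed
individual+building model genuinely has more signal available than an
individual-only model.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .cohort import Cohort, count_categories_from_binaries
from .features import (
    BMI_CLASSES,
    OCCUPATIONS,
    ORIENTATIONS,
    OUTCOME_AREAS,
    PAIN_POSITIONS,
    FeatureDictionary,
    default_dictionary,
)


class ConfigError(ValueError):
    """Invalid marginal or effect configuration."""


class CalibrationError(RuntimeError):
    """Target prevalence unreachable for the planted effects."""


@dataclass(frozen=True)
class ContinuousMarginal:
    mean: float
    sd: float
    lower: float | None = None
    upper: float | None = None
    integer: bool = False  # round draws (counts such as lifts, corridors)

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigError(f"SD must be positive, got {self.sd}")


@dataclass(frozen=True)
class CategoricalMarginal:
    categories: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.probs):
            raise ConfigError("categories and probs differ in length")
        if any(p < 0 for p in self.probs):
            raise ConfigError("negative probability")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ConfigError(f"probabilities sum to {sum(self.probs)}, not 1")


@dataclass(frozen=True)
class BetaMarginal:
    """Fraction in [0,1] drawn from Beta(mean*conc, (1-mean)*conc)."""

    mean: float
    concentration: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.mean < 1:
            raise ConfigError("Beta mean must lie in (0,1)")
        if self.concentration <= 0:
            raise ConfigError("Beta concentration must be positive")


def _yes_no(p_yes: float) -> CategoricalMarginal:
    return CategoricalMarginal(("No", "Yes"), (1.0 - p_yes, p_yes))


def _normalized(probs) -> tuple[float, ...]:
    total = float(sum(probs))
    return tuple(p / total for p in probs)


# Published prevalence of each pain location (fraction answering "Yes").
PAIN_POSITION_RATES = {
    "elbow": 0.043,
    "foot": 0.205,
    "hand": 0.295,
    "knee": 0.362,
    "lower_back": 0.424,
    "neck": 0.205,
    "shoulder": 0.324,
    "upper_back": 0.076,
    "other": 0.081,
}

# The printed orientation percentages total 100.1%; renormalized here.
ORIENTATION_PROBS = _normalized(
    (0.081, 0.119, 0.144, 0.157, 0.131, 0.106, 0.025, 0.125, 0.113)
)

OCCUPATION_PROBS = (0.103, 0.259, 0.060, 0.011, 0.371, 0.043, 0.103, 0.025, 0.025)


@dataclass
class MarginalConfig:
    """Per-feature marginal distributions, defaulting to the study cohort's
    descriptive statistics."""

    individual: dict = field(default_factory=dict)
    building: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "MarginalConfig":
        individual = {
            "age": ContinuousMarginal(55.58, 12.08, lower=18.0),
            "sex": CategoricalMarginal(("F", "M"), (0.778, 0.222)),
            "occupation": CategoricalMarginal(OCCUPATIONS, OCCUPATION_PROBS),
            "blood_pressure": CategoricalMarginal(("Low", "Normal", "High"), (0.0, 0.786, 0.214)),
            "bmi_class": CategoricalMarginal(BMI_CLASSES, (0.033, 0.310, 0.238, 0.324, 0.095)),
            "blood_glucose": CategoricalMarginal(("Low", "Normal", "High"), (0.105, 0.838, 0.057)),
            "drinker": _yes_no(0.063),
            "smoker": _yes_no(0.074),
            "pain_mild": ContinuousMarginal(3.0, 2.4, lower=0.0, upper=10.0),
            "pain_severe": ContinuousMarginal(6.5, 1.9, lower=0.0, upper=10.0),
            "subdivided_flat": _yes_no(0.038),
            "followup_plan": _yes_no(0.886),
            "covid_period": CategoricalMarginal(("wave 4-5", "wave 5"), (0.476, 0.524)),
        }
        for pos, rate in PAIN_POSITION_RATES.items():
            individual[f"pain_{pos}"] = _yes_no(rate)
        building = {
            "cardinal_orientation": CategoricalMarginal(ORIENTATIONS, ORIENTATION_PROBS),
            "n_flats": ContinuousMarginal(695.98, 238.34, lower=1.0, integer=True),
            "n_corridors": ContinuousMarginal(3.79, 1.93, lower=0.0, integer=True),
            "n_lifts": ContinuousMarginal(5.02, 1.31, lower=0.0, integer=True),
            "n_light_wells": ContinuousMarginal(12.71, 7.95, lower=0.0, integer=True),
            "building_age": ContinuousMarginal(26.04, 9.66, lower=0.0),
            "prop_small_flats": BetaMarginal(0.36),
            "has_reentrant_bay": _yes_no(0.893),
            "has_terrace": _yes_no(0.369),
            "density": ContinuousMarginal(1970.9, 731.0, lower=0.0),
        }
        return cls(individual=individual, building=building)


@dataclass
class AreaEffect:
    """Planted log-odds contributions for one outcome area.

    ``slopes`` maps a continuous feature to a per-unit log-odds slope;
    ``levels`` maps a discrete feature to {category: log-odds increment}.
    """

    slopes: dict = field(default_factory=dict)
    levels: dict = field(default_factory=dict)

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        eta = np.zeros(len(frame))
        for feat, slope in self.slopes.items():
            eta += slope * pd.to_numeric(frame[feat]).to_numpy(dtype=float)
        for feat, table in self.levels.items():
            eta += frame[feat].astype(str).map(lambda v, t=table: t.get(v, 0.0)).to_numpy(dtype=float)
        return eta


# Area-level prevalence targets (fraction answering "Yes").
DEFAULT_PREVALENCES = {
    "mood": 0.419,
    "daily_activity": 0.729,
    "sleep": 0.500,
    "social": 0.252,
    "work": 0.467,
}


def _default_individual_effect() -> AreaEffect:
    return AreaEffect(
        slopes={"pain_severe": 0.50, "pain_mild": 0.25, "age": 0.02},
        levels={
            "pain_knee": {"Yes": 0.7},
            "pain_lower_back": {"Yes": 0.6},
            "bmi_class": {"Pre-obesity": 0.4, "Obesity class (mid)": 0.6, "Obesity class (severe)": 0.7},
            "occupation": {"Clerk": 0.6, "Catering Staff": 0.5, "Cleaning Worker": 0.3},
        },
    )


def _default_building_effect() -> AreaEffect:
    return AreaEffect(
        slopes={
            "building_age": 0.14,
            "n_corridors": 0.50,
            "n_lifts": 0.40,
            "n_flats": 0.0025,
            "prop_small_flats": 2.5,
        },
        levels={
            "cardinal_orientation": {
                "North": 1.0,
                "Northwest": 1.2,
                "Northeast": 0.8,
                "West": 0.5,
                "South": -1.0,
                "Southeast": -0.6,
                "Southwest": -0.4,
            },
        },
    )


def _merge_effects(a: AreaEffect, b: AreaEffect) -> AreaEffect:
    merged = AreaEffect(slopes=dict(a.slopes), levels=copy.deepcopy(a.levels))
    for k, v in b.slopes.items():
        merged.slopes[k] = merged.slopes.get(k, 0.0) + v
    for k, tbl in b.levels.items():
        cur = merged.levels.setdefault(k, {})
        for cat, inc in tbl.items():
            cur[cat] = cur.get(cat, 0.0) + inc
    return merged


@dataclass
class EffectConfig:
    """Per-area planted effects plus target prevalences."""

    effects: dict[str, AreaEffect]
    prevalences: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))

    def __post_init__(self) -> None:
        for area, p in self.prevalences.items():
            if not 0 < p < 1:
                raise ConfigError(f"prevalence for {area!r} must lie in (0,1), got {p}")

    @classmethod
    def default(cls, building_effects: bool = True) -> "EffectConfig":
        """Individual-level effects for every area, plus (optionally) the
        building-level effects that give the mixed model its edge."""
        base = _default_individual_effect()
        if building_effects:
            base = _merge_effects(base, _default_building_effect())
        return cls(effects={area: copy.deepcopy(base) for area in OUTCOME_AREAS})

    @classmethod
    def null(cls) -> "EffectConfig":
        """No planted effects at all: outcomes are pure coin flips at the
        target prevalences."""
        return cls(effects={area: AreaEffect() for area in OUTCOME_AREAS})


# ---------------------------------------------------------------------------
# Generators


def _draw_continuous(rng: np.random.Generator, m: ContinuousMarginal, n: int) -> np.ndarray:
    x = rng.normal(m.mean, m.sd, size=n)
    # Truncation by redraw keeps the shape near-normal for mild truncation.
    for _ in range(100):
        bad = np.zeros(n, dtype=bool)
        if m.lower is not None:
            bad |= x < m.lower
        if m.upper is not None:
            bad |= x > m.upper
        if not bad.any():
            break
        x[bad] = rng.normal(m.mean, m.sd, size=int(bad.sum()))
    else:
        x = np.clip(x, m.lower, m.upper)
    if m.integer:
        x = np.round(x)
        if m.lower is not None:
            x = np.maximum(x, np.ceil(m.lower))
    return x


def _draw_marginal(rng: np.random.Generator, marginal, n: int):
    if isinstance(marginal, ContinuousMarginal):
        return _draw_continuous(rng, marginal, n)
    if isinstance(marginal, CategoricalMarginal):
        idx = rng.choice(len(marginal.categories), size=n, p=np.asarray(marginal.probs))
        return np.asarray(marginal.categories, dtype=object)[idx]
    if isinstance(marginal, BetaMarginal):
        a = marginal.mean * marginal.concentration
        b = (1.0 - marginal.mean) * marginal.concentration
        return rng.beta(a, b, size=n)
    raise ConfigError(f"unknown marginal type {type(marginal).__name__}")


def generate_buildings(
    n_buildings: int, config: MarginalConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw a building table of ``n_buildings`` public-housing blocks."""
    if n_buildings < 0:
        raise ValueError("n_buildings must be nonnegative")
    config = config or MarginalConfig.default()
    rng = np.random.default_rng(seed)
    data = {"building_id": [f"B{i:04d}" for i in range(n_buildings)]}
    for name, marginal in config.building.items():
        data[name] = _draw_marginal(rng, marginal, n_buildings)
    return pd.DataFrame(data)


def generate_participants(
    buildings: pd.DataFrame,
    n: int,
    config: MarginalConfig | None = None,
    seed: int = 0,
    assignment: str = "flats",
    dictionary: FeatureDictionary | None = None,
) -> Cohort:
    """Draw ``n`` participants, assign them to buildings, and draw all
    individual-level features (no outcomes yet).

    ``assignment="flats"`` allocates participants with probability
    proportional to each building's flat count; ``"uniform"`` ignores size.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if len(buildings) == 0:
        raise ValueError("building table is empty")
    config = config or MarginalConfig.default()
    rng = np.random.default_rng(seed)

    if assignment == "flats":
        w = buildings["n_flats"].to_numpy(dtype=float)
        probs = w / w.sum()
    elif assignment == "uniform":
        probs = np.full(len(buildings), 1.0 / len(buildings))
    else:
        raise ValueError(f"unknown assignment {assignment!r}")
    b_idx = rng.choice(len(buildings), size=n, p=probs)

    data = {
        "participant_id": [f"P{i:05d}" for i in range(n)],
        "building_id": buildings["building_id"].to_numpy()[b_idx],
    }
    for name, marginal in config.individual.items():
        data[name] = _draw_marginal(rng, marginal, n)
    cohort = Cohort(
        participants=pd.DataFrame(data),
        buildings=buildings.copy(),
        dictionary=dictionary or default_dictionary(),
    )
    return cohort.validate()


def _calibrate_intercept(
    eta: np.ndarray, target: float, tol: float = 0.005, lo: float = -20.0, hi: float = 20.0
) -> float:
    """Bisection on alpha so that mean(sigmoid(alpha + eta)) hits target."""

    def prev(alpha: float) -> float:
        return float(np.mean(expit(alpha + eta)))

    if prev(lo) > target or prev(hi) < target:
        raise CalibrationError(
            f"target prevalence {target} unreachable with planted effects "
            f"(range [{prev(lo):.4f}, {prev(hi):.4f}])"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = prev(mid)
        if abs(p - target) <= tol:
            return mid
        if p < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def plant_outcomes(cohort: Cohort, effects: EffectConfig | None = None, seed: int = 0) -> Cohort:
    """Draw the five binary areas from calibrated logistic models and derive
    the ordinal count category. Returns a new Cohort; input is not mutated."""
    effects = effects or EffectConfig.default()
    rng = np.random.default_rng(seed)
    frame = cohort.participants.merge(cohort.buildings, on="building_id", how="left")
    frame.index = cohort.participants.index

    participants = cohort.participants.copy()
    for area in OUTCOME_AREAS:
        eff = effects.effects[area]
        eta = eff.linear_predictor(frame)
        alpha = _calibrate_intercept(eta, effects.prevalences[area])
        p = expit(alpha + eta)
        participants[area] = (rng.uniform(size=len(p)) < p).astype(int)
    participants["count_category"] = count_categories_from_binaries(participants)
    return Cohort(
        participants=participants, buildings=cohort.buildings.copy(), dictionary=cohort.dictionary
    )


def simulate_cohort(
    n_participants: int = 2000,
    n_buildings: int = 30,
    seed: int = 0,
    marginals: MarginalConfig | None = None,
    effects: EffectConfig | None = None,
    assignment: str = "flats",
) -> Cohort:
    """End-to-end generation from one master seed: buildings, assignment,
    features and outcomes each consume an independent child stream."""
    ss = np.random.SeedSequence(seed)
    s_build, s_part, s_out = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    marginals = marginals or MarginalConfig.default()
    buildings = generate_buildings(n_buildings, marginals, seed=s_build)
    cohort = generate_participants(buildings, n_participants, marginals, seed=s_part, assignment=assignment)
    return plant_outcomes(cohort, effects, seed=s_out)


def effect_config_from_yaml(path) -> EffectConfig:
    """Load an EffectConfig from YAML: {prevalences: {...}, effects: {area:
    {slopes: {...}, levels: {feature: {category: incr}}}}}. Missing areas
    get empty effects."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    effects = {}
    for area in OUTCOME_AREAS:
        spec = (raw.get("effects") or {}).get(area) or {}
        effects[area] = AreaEffect(
            slopes=dict(spec.get("slopes") or {}),
            levels={k: dict(v) for k, v in (spec.get("levels") or {}).items()},
        )
    prev = dict(DEFAULT_PREVALENCES)
    prev.update(raw.get("prevalences") or {})
    return EffectConfig(effects=effects, prevalences=prev)
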