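import numpy as np
import pandas as pd
import pytest

import painstrat as ps
from painstrat.features import default_dictionary


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort with planted effects, shared read-only."""
    return ps.simulate_cohort(n_participants=800, n_buildings=20, seed=11)


@pytest.fixture()
def tiny_tables():
    """Hand-written 3-participant / 2-building tables, all values valid."""
    dictionary = default_dictionary()
    participants = pd.DataFrame(
        {
            "participant_id": ["P1", "P2", "P3"],
            "building_id": ["B1", "B1", "B2"],
            "age": [44.0, 61.0, 55.0],
            "sex": ["F", "F", "M"],
            "occupation": ["Clerk", "Domestic Helper", "Cleaning Worker"],
            "blood_pressure": ["Normal", "High", "Normal"],
            "bmi_class": ["Normal weight", "Pre-obesity", "Obesity class (mid)"],
            "blood_glucose": ["Normal", "Normal", "High"],
            "drinker": ["No", "No", "Yes"],
            "smoker": ["No", "Yes", "No"],
            "pain_mild": [2.0, 4.5, 3.0],
            "pain_severe": [6.0, 8.0, 7.0],
            "subdivided_flat": ["No", "No", "No"],
            "followup_plan": ["Yes", "Yes", "No"],
            "covid_period": ["wave 5", "wave 4-5", "wave 5"],
            **{f"pain_{p}": ["No", "Yes", "No"] for p in (
                "elbow", "foot", "hand", "knee", "lower_back",
                "neck", "shoulder", "upper_back", "other")},
            "mood": [1, 1, 0],
            "daily_activity": [1, 1, 1],
            "sleep": [1, 0, 0],
            "social": [0, 1, 0],
            "work": [0, 1, 0],
            "count_category": ["3", "4+", "0-1"],
        }
    )
    buildings = pd.DataFrame(
        {
            "building_id": ["B1", "B2"],
            "cardinal_orientation": ["South", "Northwest"],
            "n_flats": [700, 450],
            "n_corridors": [4, 2],
            "n_lifts": [5, 3],
            "n_light_wells": [12, 6],
            "building_age": [26.0, 38.0],
            "prop_small_flats": [0.36, 0.5],
            "has_reentrant_bay": ["Yes", "No"],
            "has_terrace": ["No", "Yes"],
            "density": [1970.0, 2400.0],
        }
    )
    return participants, buildings, dictionary


@pytest.fixture()
def tiny_cohort_files(tiny_tables, tmp_path):
    participants, buildings, _ = tiny_tables
    ppath = tmp_path / "participants.csv"
    bpath = tmp_path / "buildings.csv"
    participants.to_csv(ppath, index=False)
    buildings.to_csv(bpath, index=False)
    return ppath, bpath


def make_feature_outcome_cohort(n: int, seed: int, clone: bool = False):
    """Cohort whose 'knee pain' indicator IS each binary outcome: perfectly
    separable supervision for forest sanity checks. With ``clone=True`` the
    same signal also appears as the 'foot pain' column (a duplicate)."""
    cohort = ps.simulate_cohort(n_participants=n, n_buildings=12, seed=seed)
    part = cohort.participants.copy()
    rng = np.random.default_rng(seed + 1)
    signal = (rng.uniform(size=n) < 0.5).astype(int)
    part["pain_knee"] = np.where(signal == 1, "Yes", "No")
    if clone:
        part["pain_foot"] = part["pain_knee"]
    for area in ps.OUTCOME_AREAS:
        part[area] = signal
    part["count_category"] = np.where(signal == 1, "4+", "0-1")
    return ps.Cohort(participants=part, buildings=cohort.buildings, dictionary=cohort.dictionary)
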