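"""Quantile discretization, integer weight derivation, tallies, and
score-bin stratification."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import painstrat as ps
from painstrat.scorecard import (
    FeatureLevels,
    FeatureWeights,
    WeightDerivationError,
    WeightTable,
    _interval_labels,
    discretize_feature,
    fit_ordinal_coefficients,
    round_half_away,
)

warnings.filterwarnings("ignore", module="statsmodels")


class TestRoundHalfAway:
    @pytest.mark.parametrize(
        "x,expected", [(0.5, 1), (1.5, 2), (2.5, 3), (-0.5, -1), (-2.5, -3), (0.49, 0), (2.0, 2)]
    )
    def test_halves_go_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestDiscretizeFeature:
    def test_constant_vector_collapses_to_single_level(self):
        fl = discretize_feature([7.0] * 50)
        assert fl.cuts == ()
        assert len(fl.labels) == 1
        assert (fl.assign(pd.Series([7.0, 7.0])) == fl.labels[0]).all()

    def test_uniform_1_to_100_cuts_at_interior_percentiles(self):
        # Order-statistics oracle for 1..100 under linear interpolation:
        # q% quantile = 1 + (q/100) * 99.
        fl = discretize_feature(np.arange(1, 101, dtype=float))
        expected = tuple(1 + q / 100 * 99 for q in (5, 20, 80, 95))
        assert fl.cuts == pytest.approx(expected)
        assert len(fl.labels) == 5

    def test_interval_label_format_matches_card_style(self):
        labels = _interval_labels((3.0, 5.0, 8.0, 9.55))
        assert labels == ("<3", "[3, 5)", "[5, 8)", "[8, 9.55)", ">=9.55")

    def test_severe_pain_like_vector_produces_half_open_levels(self):
        rng = np.random.default_rng(0)
        vals = np.clip(rng.normal(6.5, 1.9, size=3000), 0, 10)
        fl = discretize_feature(vals)
        assert len(fl.labels) == 5
        assert fl.labels[0].startswith("<")
        assert all(lab.startswith("[") for lab in fl.labels[1:-1])
        assert fl.labels[-1].startswith(">=")
        # strictly increasing cuts
        assert all(a < b for a, b in zip(fl.cuts, fl.cuts[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            discretize_feature([])

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            discretize_feature([1.0, 2.0], grid=(0, 50, 40, 100))
        with pytest.raises(ValueError):
            discretize_feature([1.0, 2.0], grid=(5, 50, 100))

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200),
        st.lists(st.floats(-2e6, 2e6), min_size=1, max_size=20),
    )
    @settings(deadline=None, max_examples=60)
    def test_every_value_maps_to_exactly_one_level(self, train, new):
        fl = discretize_feature(train)
        assigned = fl.assign(pd.Series(train + new))
        assert assigned.isin(fl.labels).all()
        # out-of-range values clamp to the boundary levels
        below = fl.assign(pd.Series([min(train) - 1.0]))
        above = fl.assign(pd.Series([max(train) + 1.0]))
        assert below.iloc[0] == fl.labels[0]
        assert above.iloc[0] == fl.labels[-1]


class TestWeightsFromCoefficients:
    def test_single_binary_feature_scales_to_unit_weight(self):
        table = ps.weights_from_coefficients({"f": {"ref": 0.0, "hi": 0.693}})
        assert table.entries[0].weights == {"ref": 0, "hi": 1}

    def test_analytic_ratio_oracle(self):
        beta = 0.37
        table = ps.weights_from_coefficients(
            {"f1": {"a": 0.0, "b": beta}, "f2": {"a": 0.0, "b": 2 * beta, "c": 3 * beta}}
        )
        by_name = {e.feature: e.weights for e in table.entries}
        assert by_name["f1"] == {"a": 0, "b": 1}
        assert by_name["f2"] == {"a": 0, "b": 2, "c": 3}

    def test_recentering_makes_smallest_level_reference(self):
        table = ps.weights_from_coefficients({"f": {"a": -1.0, "b": -0.5, "c": 1.0}})
        w = table.entries[0].weights
        assert w["a"] == 0 and w["b"] == 1 and w["c"] == 4

    @given(st.floats(0.01, 100.0))
    @settings(deadline=None, max_examples=50)
    def test_scaling_invariance_exact(self, scale):
        coefs = {"f1": {"a": 0.0, "b": 0.41, "c": 1.3}, "f2": {"a": 0.2, "b": 0.9}}
        scaled = {f: {lv: c * scale for lv, c in lvls.items()} for f, lvls in coefs.items()}
        w1 = ps.weights_from_coefficients(coefs)
        w2 = ps.weights_from_coefficients(scaled)
        assert [e.weights for e in w1.entries] == [e.weights for e in w2.entries]

    def test_literal_rule_divides_by_reference(self):
        table = ps.weights_from_coefficients(
            {"f": {"a": 0.5, "b": 1.0, "c": 2.1}}, rule="literal"
        )
        assert table.entries[0].weights == {"a": 1, "b": 2, "c": 4}

    def test_literal_rule_undefined_for_zero_reference(self):
        with pytest.raises(WeightDerivationError):
            ps.weights_from_coefficients({"f": {"a": 0.0, "b": 1.0}}, rule="literal")

    def test_weights_nonnegative_with_minimum_zero_per_feature(self):
        rng = np.random.default_rng(3)
        coefs = {
            f"f{i}": {f"l{j}": float(rng.normal()) for j in range(4)} for i in range(5)
        }
        table = ps.weights_from_coefficients(coefs)
        for e in table.entries:
            vals = list(e.weights.values())
            assert min(vals) == 0
            assert all(v >= 0 for v in vals)


class TestDeriveWeights:
    def test_planted_binary_effect_recovered(self):
        # One strong binary feature driving the count outcome: the exposed
        # level must get a positive weight, reference 0.
        from painstrat.simulate import AreaEffect, EffectConfig

        eff = EffectConfig(
            effects={a: AreaEffect(levels={"pain_knee": {"Yes": 1.2}}) for a in ps.OUTCOME_AREAS}
        )
        cohort = ps.simulate_cohort(n_participants=2500, n_buildings=15, seed=21, effects=eff)
        table, scheme = ps.derive_weights(cohort, ["pain_knee"])
        w = table.entries[0].weights
        assert w["No"] == 0
        assert w["Yes"] >= 1

    def test_empty_level_raises_naming_the_level(self, small_cohort):
        scheme = ps.discretize_cohort(small_cohort, ["age"])
        fl = scheme.levels["age"]
        # widen the scheme with a level no one occupies
        scheme.levels["age"] = FeatureLevels(
            feature="age", kind="continuous",
            cuts=fl.cuts + (10000.0,), labels=_interval_labels(fl.cuts + (10000.0,)),
        )
        frame = scheme.assign_frame(small_cohort.feature_frame(["age"]))
        with pytest.raises(WeightDerivationError, match=">=10000"):
            fit_ordinal_coefficients(frame, small_cohort.outcome_series("count"), scheme)

    def test_card_yaml_round_trip(self, tmp_path):
        table = WeightTable(
            entries=[
                FeatureWeights("age", 1, ("<36", "[36, 44)", ">=44"), {"<36": 0, "[36, 44)": 3, ">=44": 6}),
                FeatureWeights("sex", 13, ("F", "M"), {"F": 1, "M": 0}),
            ],
            scaling=0.21,
        )
        table.to_yaml(tmp_path / "card.yaml")
        again = WeightTable.from_yaml(tmp_path / "card.yaml")
        assert [e.feature for e in again.entries] == ["age", "sex"]
        assert again.entries[0].weights == table.entries[0].weights
        assert again.scaling == pytest.approx(0.21)


# Published score-card weights for the two worked tally profiles.
_INDIVIDUAL_CARD = WeightTable(
    entries=[
        FeatureWeights("age", 1, ("<36", "[36, 44)", "[44, 67)", "[67, 73)", ">=73"),
                       {"<36": 3, "[36, 44)": 3, "[44, 67)": 6, "[67, 73)": 6, ">=73": 0}),
        FeatureWeights("occupation", 2, ("Catering", "Clerk", "Security"),
                       {"Catering": 11, "Clerk": 12, "Security": 0}),
        FeatureWeights("pain_mild", 3, ("<5", "[5, 7.55)", ">=7.55"),
                       {"<5": 0, "[5, 7.55)": 5, ">=7.55": 12}),
        FeatureWeights("pain_severe", 4, ("<3", "[3, 5)", "[5, 8)", "[8, 9.55)", ">=9.55"),
                       {"<3": 3, "[3, 5)": 3, "[5, 8)": 9, "[8, 9.55)": 9, ">=9.55": 21}),
        FeatureWeights("bmi_class", 5, ("Normal weight", "Pre-obesity"),
                       {"Normal weight": 0, "Pre-obesity": 9}),
        FeatureWeights("blood_glucose", 6, ("Normal", "Abnormal"), {"Normal": 0, "Abnormal": 5}),
        FeatureWeights("pain_knee", 7, ("No", "Yes"), {"No": 0, "Yes": 2}),
        FeatureWeights("pain_lower_back", 8, ("No", "Yes"), {"No": 0, "Yes": 3}),
        FeatureWeights("sex", 13, ("F", "M"), {"F": 1, "M": 0}),
    ]
)

_MIXED_CARD = WeightTable(
    entries=[
        FeatureWeights("cardinal_orientation", 1, ("Northwest", "Southeast"),
                       {"Northwest": 12, "Southeast": 0}),
        FeatureWeights("n_flats", 7, ("<267", ">=1140"), {"<267": 0, ">=1140": 10}),
        FeatureWeights("building_age", 8, ("<11", ">=37.8"), {"<11": 0, ">=37.8": 8}),
        FeatureWeights("n_corridors", 12, ("<2", "[2, 4)"), {"<2": 4, "[2, 4)": 10}),
        FeatureWeights("n_lifts", 13, ("<3", ">=4"), {"<3": 0, ">=4": 10}),
    ]
)


class TestTallyScore:
    def test_all_reference_participant_scores_zero(self):
        card = WeightTable(
            entries=[
                FeatureWeights("a", 1, ("x", "y"), {"x": 0, "y": 4}),
                FeatureWeights("b", 2, ("u", "v"), {"u": 0, "v": 2}),
            ]
        )
        assert ps.tally_score({"a": "x", "b": "u"}, card) == 0

    def test_published_individual_profile_tallies_71(self):
        profile = {
            "age": "[44, 67)", "occupation": "Clerk", "pain_mild": ">=7.55",
            "pain_severe": ">=9.55", "bmi_class": "Pre-obesity",
            "blood_glucose": "Abnormal", "pain_knee": "Yes",
            "pain_lower_back": "Yes", "sex": "F",
        }
        assert ps.tally_score(profile, _INDIVIDUAL_CARD) == 71

    def test_published_mixed_profile_tallies_50(self):
        profile = {
            "cardinal_orientation": "Northwest", "n_flats": ">=1140",
            "building_age": ">=37.8", "n_corridors": "[2, 4)", "n_lifts": ">=4",
        }
        assert ps.tally_score(profile, _MIXED_CARD) == 50

    def test_missing_level_rejected(self):
        with pytest.raises(ValueError, match="no level"):
            ps.tally_score({"cardinal_orientation": "Northwest"}, _MIXED_CARD)


class TestStratificationTable:
    def test_degenerate_single_category_bin(self):
        scores = pd.Series([85, 90, 95])
        counts = pd.Series(["4+", "4+", "4+"])
        table = ps.stratification_table(scores, counts, bins=[(81, 100)])
        assert table.table.iloc[0].tolist() == [0.0, 0.0, 0.0, 1.0]

    def test_toy_eight_participants_exact_fractions(self):
        scores = pd.Series([25, 30, 35, 38, 45, 50, 55, 58])
        counts = pd.Series(["0-1", "0-1", "2", "3", "2", "2", "4+", "4+"])
        table = ps.stratification_table(scores, counts, bins=[(21, 40), (41, 60)])
        assert table.table.loc["[21, 40]"].tolist() == [0.5, 0.25, 0.25, 0.0]
        assert table.table.loc["[41, 60]"].tolist() == [0.0, 0.5, 0.0, 0.5]
        assert table.occupancy.tolist() == [4, 4]

    def test_row_sums_equal_one_for_occupied_bins(self, small_cohort):
        rng = np.random.default_rng(1)
        scores = pd.Series(
            rng.integers(0, 100, size=small_cohort.n), index=small_cohort.participants.index
        )
        table = ps.stratification_table(
            scores, small_cohort.participants["count_category"], bins=[(0, 49), (50, 99)]
        )
        assert np.allclose(table.table.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_bin_flagged_with_nan_and_zero_occupancy(self):
        table = ps.stratification_table(
            pd.Series([5, 6]), pd.Series(["2", "3"]), bins=[(0, 10), (11, 20)]
        )
        assert table.occupancy.tolist() == [2, 0]
        assert table.table.loc["[11, 20]"].isna().all()

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ps.stratification_table(pd.Series([5]), pd.Series(["2"]), bins=[(0, 10), (10, 20)])

    def test_uncovered_scores_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ps.stratification_table(pd.Series([150]), pd.Series(["2"]), bins=[(0, 100)])
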