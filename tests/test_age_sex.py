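"""Age-sex disaggregation chain: normalization, ratios, energy allocation,
consistency enforcement and shared-draw group nutrients."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrisupply.age_sex import (
    AgeSexGroup,
    apply_group_ratio,
    deadjust,
    energy_adjust,
    enforce_population_consistency,
    group_energy_supply,
    group_food_supplies,
    group_nutrients,
)
from nutrisupply.nutrient_mc import CompositionEntry, mc_nutrient_supply


class TestEnergyAdjust:
    def test_worked_normalization(self):
        assert energy_adjust(30.0, 3000.0) == pytest.approx(20.0)

    def test_reference_energy_is_identity(self):
        assert energy_adjust(17.0, 2000.0) == 17.0

    def test_zero_supply_and_bad_energy(self):
        assert energy_adjust(0.0, 2500.0) == 0.0
        with pytest.raises(ValueError):
            energy_adjust(1.0, 0.0)

    @given(
        supply=st.floats(min_value=0, max_value=1e4),
        energy=st.floats(min_value=500, max_value=6000),
    )
    @settings(max_examples=50, derandomize=True)
    def test_deadjust_inverts_adjust_at_national_energy(self, supply, energy):
        assert deadjust(energy_adjust(supply, energy), energy) == pytest.approx(
            supply, rel=1e-12
        )


class TestGroupRatio:
    def test_mapped_food_scales_by_ratio(self):
        assert apply_group_ratio(20.0, "fruit", 1.10, is_adult=True) == pytest.approx(22.0)

    def test_uniform_food_unchanged_for_every_group(self):
        assert apply_group_ratio(20.0, "uniform", 1.3, is_adult=True) == 20.0
        assert apply_group_ratio(20.0, "uniform", None, is_adult=False) == 20.0

    def test_adult_only_food_zero_for_minors(self):
        assert apply_group_ratio(8.0, "adult_only", 1.2, is_adult=False) == 0.0
        assert apply_group_ratio(8.0, "adult_only", 1.2, is_adult=True) == pytest.approx(9.6)

    def test_children_without_ratio_take_the_average(self):
        assert apply_group_ratio(20.0, "fruit", None, is_adult=False) == 20.0

    def test_fatty_acid_proxy_behaves_like_a_category(self):
        assert apply_group_ratio(10.0, "fatty_acid_proxy:pufa", 0.9, True) == pytest.approx(9.0)


GROUPS = [
    AgeSexGroup("female", 50, 54, 1000.0, 2200.0),
    AgeSexGroup("male", 50, 54, 1000.0, 2800.0),
]


class TestGroupEnergy:
    def test_worked_surplus_allocation(self):
        # avg requirement 2500, national 3000 -> 20% surplus; 2200 -> 2640
        out = group_energy_supply(3000.0, GROUPS)
        assert out["F50_54"] == pytest.approx(2640.0)
        assert out["M50_54"] == pytest.approx(3360.0)

    def test_equal_requirements_all_get_national(self):
        groups = [
            AgeSexGroup("female", 20, 24, 500.0, 2100.0),
            AgeSexGroup("male", 20, 24, 900.0, 2100.0),
        ]
        out = group_energy_supply(2430.0, groups)
        assert all(v == pytest.approx(2430.0) for v in out.values())

    @given(
        pops=st.lists(st.floats(min_value=1, max_value=1e6), min_size=2, max_size=6),
        reqs=st.lists(st.floats(min_value=1200, max_value=3200), min_size=2, max_size=6),
        national=st.floats(min_value=1500, max_value=4000),
    )
    @settings(max_examples=50, derandomize=True)
    def test_population_weighted_mean_equals_national(self, pops, reqs, national):
        n = min(len(pops), len(reqs))
        groups = [
            AgeSexGroup("female" if i % 2 else "male", 20 + 5 * i, 24 + 5 * i,
                        pops[i], reqs[i])
            for i in range(n)
        ]
        out = group_energy_supply(national, groups)
        weighted = sum(g.population * out[g.group_id] for g in groups) / sum(
            g.population for g in groups
        )
        assert weighted == pytest.approx(national, rel=1e-12)


class TestDeadjust:
    def test_worked_absolute_supply(self):
        assert deadjust(22.0, 2640.0) == pytest.approx(29.04)
        assert round(deadjust(22.0, 2640.0)) == 29

    def test_reference_energy_is_identity(self):
        assert deadjust(13.0, 2000.0) == 13.0


class TestConsistencyEnforcement:
    def test_already_consistent_is_identity(self):
        frame = pd.DataFrame({"F": [10.0], "M": [30.0]}, index=["apples"])
        out = enforce_population_consistency(frame, {"F": 1.0, "M": 1.0}, {"apples": 20.0})
        pd.testing.assert_frame_equal(out, frame)

    def test_ten_percent_high_scaled_down_uniformly(self):
        frame = pd.DataFrame({"F": [11.0], "M": [33.0]}, index=["apples"])
        out = enforce_population_consistency(frame, {"F": 1.0, "M": 1.0}, {"apples": 20.0})
        assert out.loc["apples", "F"] == pytest.approx(10.0)
        assert out.loc["apples", "M"] == pytest.approx(30.0)

    def test_random_34_group_fixture_hits_1e12_relative(self):
        rng = np.random.default_rng(2)
        cols = [f"g{i}" for i in range(34)]
        frame = pd.DataFrame(
            rng.uniform(0, 50, size=(5, 34)), index=[f"f{i}" for i in range(5)], columns=cols
        )
        pops = {c: float(p) for c, p in zip(cols, rng.uniform(1e3, 1e6, 34))}
        national = {f: float(x) for f, x in zip(frame.index, rng.uniform(1, 40, 5))}
        out = enforce_population_consistency(frame, pops, national)
        pvec = np.array([pops[c] for c in cols])
        for food in frame.index:
            weighted = float(out.loc[food].to_numpy() @ pvec) / pvec.sum()
            assert weighted == pytest.approx(national[food], rel=1e-12)

    def test_zero_groups_with_positive_national_rejected(self):
        frame = pd.DataFrame({"F": [0.0], "M": [0.0]}, index=["apples"])
        with pytest.raises(ValueError, match="all-zero"):
            enforce_population_consistency(frame, {"F": 1.0, "M": 1.0}, {"apples": 5.0})


class TestFullChain:
    def test_uniform_ratios_and_equal_requirements_reproduce_national(self):
        groups = [
            AgeSexGroup("female", 30, 34, 400.0, 2000.0),
            AgeSexGroup("male", 30, 34, 600.0, 2000.0),
        ]
        supplies = {"apples": 30.0, "bread": 120.0}
        ratios = {("fruit", g.group_id): 1.0 for g in groups}
        ratios.update({("cereal", g.group_id): 1.0 for g in groups})
        out = group_food_supplies(
            supplies, 2400.0, groups, {"apples": "fruit", "bread": "cereal"}, ratios
        )
        for food, amount in supplies.items():
            assert out.loc[food].to_numpy() == pytest.approx(amount)

    def test_weighted_group_supplies_match_national_per_food(self, country_x):
        fx = country_x
        out = group_food_supplies(
            fx.national_supplies, fx.national_energy_kcal, fx.groups,
            fx.gdd_map, fx.ratios,
        )
        pops = np.array([g.population for g in fx.groups])
        for food, national in fx.national_supplies.items():
            weighted = float(out.loc[food].to_numpy() @ pops) / pops.sum()
            assert weighted == pytest.approx(national, rel=1e-12)


class TestGroupNutrients:
    CANDIDATES = {
        "a": [
            CompositionEntry("t", "a", {"calories": 50.0}),
            CompositionEntry("t", "a", {"calories": 90.0}),
        ],
        "b": [
            CompositionEntry("t", "b", {"calories": 300.0}),
            CompositionEntry("t", "b", {"calories": 340.0}),
        ],
    }

    def test_single_candidate_groups_are_deterministic_weighted_sums(self):
        cand = {
            "a": [CompositionEntry("t", "a", {"calories": 50.0})],
            "b": [CompositionEntry("t", "b", {"calories": 300.0})],
        }
        frame = pd.DataFrame({"F": [100.0, 10.0], "M": [200.0, 0.0]}, index=["a", "b"])
        out = group_nutrients(frame, cand, 20, 0, ["calories"])
        assert out["F"]["calories"].median == pytest.approx(100 * 0.5 + 10 * 3.0)
        assert out["M"]["calories"].median == pytest.approx(200 * 0.5)
        assert out["F"]["calories"].lower_95 == out["F"]["calories"].upper_95

    def test_zero_supply_group_has_all_zero_nutrients(self):
        frame = pd.DataFrame({"F": [100.0, 10.0], "Z": [0.0, 0.0]}, index=["a", "b"])
        out = group_nutrients(frame, self.CANDIDATES, 50, 1, ["calories"])
        z = out["Z"]["calories"]
        assert (z.lower_95, z.median, z.upper_95) == (0.0, 0.0, 0.0)

    def test_shared_draws_couple_group_and_national_medians(self):
        # group supplies proportional to the national pattern with
        # population-weighted coefficients summing to 1: iteration totals are
        # comonotonic, so medians aggregate linearly and the weighted group
        # medians reproduce the national median exactly under shared draws
        national = {"a": 100.0, "b": 40.0}
        frame = pd.DataFrame(
            {"F": [120.0, 48.0], "M": [80.0, 32.0]}, index=["a", "b"]
        )  # 1.2x and 0.8x national, equal populations
        out = group_nutrients(frame, self.CANDIDATES, 800, 5, ["calories"])
        nat = mc_nutrient_supply(national, self.CANDIDATES, 800, 5, ["calories"])
        weighted = 0.5 * out["F"]["calories"].median + 0.5 * out["M"]["calories"].median
        assert weighted == pytest.approx(nat["calories"].median, rel=1e-12)
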