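"""Balance-sheet disaggregation: arithmetic, ratio preservation, r² scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrisupply.disaggregation import (
    OffalFactors,
    apply_food_ratio,
    domestic_supply,
    offal_supply,
    one_to_one_r2,
    to_primary_equivalent,
)
from nutrisupply.pipeline import stage_disaggregate

amounts = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


class TestDomesticSupply:
    def test_production_plus_imports_minus_exports(self):
        assert domestic_supply(100, 20, 30) == 90
        assert domestic_supply(0, 0, 0) == 0

    def test_negative_balance_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="nutrisupply"):
            assert domestic_supply(10, 0, 50) == 0.0
        assert "clamped" in caplog.text

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            domestic_supply(float("nan"), 0, 0)

    @given(p=amounts, i=amounts, e=amounts)
    @settings(max_examples=50, derandomize=True)
    def test_matches_clamped_oracle(self, p, i, e):
        assert domestic_supply(p, i, e) == max(0.0, p + i - e)


class TestPrimaryEquivalent:
    def test_multiplication_and_zero(self):
        assert to_primary_equivalent(10.0, 3.5) == 35.0
        assert to_primary_equivalent(0.0, 7.0) == 0.0

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            to_primary_equivalent(1.0, 0.0)

    def test_summed_processed_forms_match_hand_total(self):
        forms = [(12.0, 3.0), (5.0, 2.5), (0.5, 8.0)]
        assert sum(to_primary_equivalent(a, f) for a, f in forms) == pytest.approx(
            12 * 3 + 5 * 2.5 + 0.5 * 8
        )


class TestFoodRatio:
    def test_proportional_split(self):
        assert apply_food_ratio({"A": 60, "B": 40}, 100, 80) == {"A": 48.0, "B": 32.0}

    def test_ratio_one_is_identity(self):
        out = apply_food_ratio({"A": 60, "B": 40}, 100, 100)
        assert out == {"A": 60.0, "B": 40.0}

    def test_zero_parent_with_positive_food_rejected(self):
        with pytest.raises(ValueError, match="ratio undefined"):
            apply_food_ratio({"A": 1}, 0.0, 5.0)

    @given(
        doms=st.lists(st.floats(min_value=0.01, max_value=1e5), min_size=1, max_size=6),
        parent_dom=st.floats(min_value=0.5, max_value=1e6),
        ratio=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_every_child_inherits_the_parent_ratio(self, doms, parent_dom, ratio):
        children = {f"c{i}": d for i, d in enumerate(doms)}
        out = apply_food_ratio(children, parent_dom, parent_dom * ratio)
        for c, dom in children.items():
            assert out[c] == pytest.approx(dom * ratio, rel=1e-12)
        assert sum(out.values()) == pytest.approx(sum(doms) * ratio, rel=1e-9)

    def test_monotone_in_child_production(self):
        lo = apply_food_ratio({"A": 50, "B": 40}, 100, 80)
        hi = apply_food_ratio({"A": 70, "B": 40}, 100, 80)
        assert hi["A"] > lo["A"] and hi["B"] == lo["B"]


class TestOffal:
    FACTORS = {
        "bovine": OffalFactors("bovine", 2.0, 0.05),
        "pig": OffalFactors("pig", 1.5, 0.04),
        "poultry": OffalFactors("poultry", 1.8, 0.06),
    }

    def test_chained_conversion(self):
        assert offal_supply({"bovine": 100.0}, self.FACTORS) == pytest.approx(10.0)

    def test_zero_everywhere(self):
        assert offal_supply({a: 0.0 for a in self.FACTORS}, self.FACTORS) == 0.0

    def test_three_type_sum_matches_hand_total(self):
        carcass = {"bovine": 100.0, "pig": 50.0, "poultry": 20.0}
        hand = 100 * 2.0 * 0.05 + 50 * 1.5 * 0.04 + 20 * 1.8 * 0.06
        assert offal_supply(carcass, self.FACTORS) == pytest.approx(hand)

    def test_missing_factor_names_the_type(self):
        with pytest.raises(KeyError, match="camel"):
            offal_supply({"camel": 1.0}, self.FACTORS)

    def test_factor_invariants_enforced(self):
        with pytest.raises(ValueError):
            OffalFactors("x", -1.0, 0.05)
        with pytest.raises(ValueError):
            OffalFactors("x", 2.0, 1.5)


class TestOneToOneR2:
    def test_perfect_fit(self):
        assert one_to_one_r2([1, 2, 3], [1, 2, 3]) == 1.0

    def test_small_residuals(self):
        # ss_res = 0.01 + 0 + 0.01 = 0.02; ss_tot = 2 * 0.81 = 1.62
        assert one_to_one_r2([1, 2, 3], [1.1, 2.0, 2.9]) == pytest.approx(
            1 - 0.02 / 1.62
        )

    def test_offset_model_can_go_negative(self):
        assert one_to_one_r2([101, 102, 103], [1, 2, 3]) < 0

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            one_to_one_r2([1, 2], [5, 5])


class TestExactRecovery:
    def test_constructed_parents_recovered_to_machine_precision(self, world):
        _, report = stage_disaggregate(world)
        assert len(report) >= 4
        assert (report["r2"] > 1 - 1e-12).all()

    def test_multiplicative_noise_degrades_r2_monotonically(self, world):
        _, report = stage_disaggregate(world)
        rng = np.random.default_rng(0)
        ref = np.exp(rng.uniform(4, 9, size=40))
        means = []
        for sigma in (0.05, 0.2, 0.5):
            r2s = [
                one_to_one_r2(ref * rng.lognormal(0.0, sigma, size=ref.size), ref)
                for _ in range(30)
            ]
            means.append(np.mean(r2s))
        assert means[0] > means[1] > means[2]
        assert means[0] < 1.0
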