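"""Weight-basis conversions, flour split and cheese normalization."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrisupply.edible_processing import (
    EdibleFactors,
    GrainProcessing,
    cheese_to_milk_equivalent,
    edible_table,
    normalize_to_milkfat,
    split_grain,
    to_edible,
    to_retail,
)


class TestRetailAndEdible:
    def test_carcass_to_retail(self):
        assert to_retail(100.0, 0.7) == pytest.approx(70.0)
        assert to_retail(100.0, 1.0) == 100.0

    def test_plant_foods_pass_through(self):
        assert to_retail(42.0, None) == 42.0

    def test_discard_subtraction(self):
        assert to_edible(100.0, 0.28) == pytest.approx(72.0)
        assert to_edible(100.0, 0.0) == 100.0

    @pytest.mark.parametrize("factor", [0.0, -0.1, 1.5])
    def test_retail_factor_range_enforced(self, factor):
        with pytest.raises(ValueError):
            to_retail(1.0, factor)

    @pytest.mark.parametrize("frac", [-0.1, 1.0])
    def test_discard_range_enforced(self, frac):
        with pytest.raises(ValueError):
            to_edible(1.0, frac)

    @given(
        supply=st.floats(min_value=0, max_value=1e5),
        c2r=st.floats(min_value=0.01, max_value=1.0),
        discard=st.floats(min_value=0.0, max_value=0.99),
    )
    @settings(max_examples=50, derandomize=True)
    def test_chain_equals_single_combined_factor_and_never_gains_mass(
        self, supply, c2r, discard
    ):
        edible = to_edible(to_retail(supply, c2r), discard)
        assert edible == pytest.approx(supply * c2r * (1 - discard), rel=1e-12)
        assert edible <= to_retail(supply, c2r) <= supply


class TestGrainSplit:
    def test_flour_and_whole_arithmetic(self):
        gp = GrainProcessing("wheat", "R1", 0.8, 0.78)
        flour, whole = split_grain(100.0, gp)
        assert (flour, whole) == (pytest.approx(62.4), pytest.approx(20.0))

    def test_no_processing_and_lossless_full_processing(self):
        assert split_grain(50.0, GrainProcessing("maize", "R1", 0.0, 0.8)) == (0.0, 50.0)
        assert split_grain(50.0, GrainProcessing("maize", "R1", 1.0, 1.0)) == (50.0, 0.0)

    def test_rice_is_never_split(self):
        with pytest.raises(ValueError, match="rice"):
            GrainProcessing("rice", "R1", 0.5, 0.8)

    @given(
        supply=st.floats(min_value=0, max_value=1e5),
        frac=st.floats(min_value=0, max_value=1),
        ext=st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_mass_bounded_with_equality_iff_full_extraction(self, supply, frac, ext):
        flour, whole = split_grain(supply, GrainProcessing("wheat", "R", frac, ext))
        assert flour + whole <= supply * (1 + 1e-12)
        if ext == 1.0:
            assert flour + whole == pytest.approx(supply, rel=1e-12)


class TestCheese:
    DENSITIES = {"calcium": 720.0, "fat": 30.0, "protein": 25.0}

    def test_milkfat_division(self):
        out = cheese_to_milk_equivalent(self.DENSITIES, 6.0)
        assert out == pytest.approx({"calcium": 120.0, "fat": 5.0, "protein": 25 / 6})

    def test_factor_one_is_identity(self):
        assert cheese_to_milk_equivalent(self.DENSITIES, 1.0) == self.DENSITIES

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            cheese_to_milk_equivalent(self.DENSITIES, 0.0)

    def test_soft_cheese_normalized_to_target_milkfat(self):
        # scale = target_fat / cheese_fat, applied to every nutrient
        out = normalize_to_milkfat(self.DENSITIES, target_fat_per_100g=6.0)
        assert out["fat"] == pytest.approx(6.0)
        assert out["calcium"] == pytest.approx(720.0 * 6.0 / 30.0)


class TestEdibleTable:
    def frame(self):
        return pd.DataFrame(
            {
                "country": ["A"] * 3,
                "year": [2011] * 3,
                "food": ["beef", "wheat", "mango"],
                "amount_g_day": [100.0, 200.0, 50.0],
                "basis": ["primary"] * 3,
            }
        )

    FACTORS = {
        "beef": EdibleFactors("beef", 0.7, 0.2),
        "mango": EdibleFactors("mango", None, 0.3),
    }

    def test_conversion_flour_rows_and_loss_ledger(self):
        gp = {("wheat", "R1"): GrainProcessing("wheat", "R1", 0.5, 0.8)}
        res = edible_table(self.frame(), self.FACTORS, gp, {"A": "R1"})
        out = res.supplies.set_index("food")["amount_g_day"]
        assert out["beef"] == pytest.approx(100 * 0.7 * 0.8)
        assert out["mango"] == pytest.approx(50 * 0.7)
        assert out["wheat"] == pytest.approx(200 * 0.5)  # whole-grain remainder
        assert out["wheat_flour"] == pytest.approx(200 * 0.5 * 0.8)
        assert (res.supplies["basis"] == "edible").all()
        # independent ledger: losses equal input minus surviving edible mass
        total_loss = res.losses["loss_g_day"].sum()
        assert total_loss == pytest.approx(
            (100 - 56) + (50 - 35) + (200 - 100 - 80)
        )

    def test_unknown_basis_rejected(self):
        bad = self.frame().assign(basis="edible")
        with pytest.raises(ValueError, match="primary"):
            edible_table(bad, self.FACTORS)

    def test_factor_invariants(self):
        with pytest.raises(ValueError):
            EdibleFactors("x", 1.2, 0.0)
        with pytest.raises(ValueError):
            EdibleFactors("x", None, 1.0)
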