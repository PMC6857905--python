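import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefbudget.bioerosion import (
    ErosionResult,
    bite_rate,
    bite_volume,
    macroboring_erosion,
    parrotfish_erosion,
    scar_proportion,
    total_erosion,
    urchin_erosion,
    urchin_individual_erosion,
)
from reefbudget.survey import FishRecord, SpeciesTraits, TraitTable, UrchinRecord

from _oracles import (
    oracle_bite_rate,
    oracle_bite_volume,
    oracle_parrotfish,
    oracle_scar_proportion,
    oracle_urchin,
)


class TestBiteVolume:
    @pytest.mark.parametrize(
        "length,expected",
        [(30.0, math.exp(3.12) / 1000.0), (10.0, math.exp(1.92) / 1000.0)],
    )
    def test_hand_computed(self, length, expected):
        assert bite_volume(length) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing(self):
        lengths = [5.0, 10.0, 20.0, 40.0, 60.0]
        vols = [bite_volume(l) for l in lengths]
        assert vols == sorted(vols) and len(set(vols)) == len(vols)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bite_volume(0.0)


class TestScarProportion:
    def test_logistic_midpoint(self):
        assert scar_proportion(2.46 / 0.089) == pytest.approx(0.5, rel=1e-9)

    def test_hand_computed_length_40(self):
        assert scar_proportion(40.0) == pytest.approx(1.0 / (1.0 + math.exp(-1.1)), rel=1e-12)
        assert scar_proportion(40.0) == pytest.approx(0.750, abs=5e-4)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(length=st.floats(min_value=0.1, max_value=200.0))
    def test_bounded_in_unit_interval(self, length):
        assert 0.0 < scar_proportion(length) < 1.0


class TestBiteRate:
    def test_hand_computed(self):
        assert bite_rate(30.0, brc=20.0) == pytest.approx(708.0)

    def test_clamped_at_zero(self):
        # large fish, small brc drives the printed linear form negative
        assert bite_rate(120.0, brc=1.0) == 0.0

    def test_decreasing_in_length(self):
        rates = [bite_rate(l, brc=20.0) for l in (10.0, 20.0, 30.0, 50.0)]
        assert rates == sorted(rates, reverse=True)


class TestParrotfishErosion:
    @pytest.fixture()
    def fish_traits(self):
        return TraitTable([SpeciesTraits("parrotX", brc=20.0)])

    def test_no_fish_is_zero(self, fish_traits):
        assert parrotfish_erosion([], 1.5, fish_traits, 120.0) == 0.0

    def test_hand_computed_single_fish(self, fish_traits):
        fish = [FishRecord("parrotX", 30.0)]
        expected = (
            oracle_bite_volume(30.0)
            * oracle_scar_proportion(30.0)
            * oracle_bite_rate(30.0, 20.0)
            * 1.5
            * 365.0
            * 0.001
            / 120.0
        )
        got = parrotfish_erosion(fish, 1.5, fish_traits, 120.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.0404, abs=1e-4)

    def test_two_identical_fish_double_one(self, fish_traits):
        one = parrotfish_erosion([FishRecord("parrotX", 25.0)], 1.4, fish_traits, 120.0)
        two = parrotfish_erosion([FishRecord("parrotX", 25.0)] * 2, 1.4, fish_traits, 120.0)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_unknown_species_warns_and_uses_default(self, fish_traits):
        with pytest.warns(UserWarning, match="default"):
            got = parrotfish_erosion([FishRecord("mystery", 30.0)], 1.5, fish_traits, 120.0)
        assert got == pytest.approx(
            parrotfish_erosion([FishRecord("parrotX", 30.0)], 1.5, fish_traits, 120.0)
        )


class TestUrchinErosion:
    def test_diadema_hand_computed(self):
        got = urchin_individual_erosion(UrchinRecord("Diadema", 10.0))
        assert got == pytest.approx(1e-6 * 10**3.42 * 0.365 * 0.57, rel=1e-12)
        assert got == pytest.approx(5.47e-4, rel=2e-3)

    def test_echinometra_hand_computed(self):
        got = urchin_individual_erosion(UrchinRecord("Echinometra", 5.0))
        assert got == pytest.approx(0.0004 * 5**1.98 * 0.365 * 0.57, rel=1e-12)
        assert got == pytest.approx(2.02e-3, rel=5e-3)

    def test_empty_list_is_zero(self):
        assert urchin_erosion([], 36.0) == 0.0

    def test_order_invariant(self):
        urchins = [
            UrchinRecord("Diadema", 8.0),
            UrchinRecord("Echinometra", 3.5),
            UrchinRecord("Other", 5.0),
        ]
        assert urchin_erosion(urchins, 36.0) == pytest.approx(
            urchin_erosion(urchins[::-1], 36.0), rel=1e-12
        )


class TestMacroboring:
    @pytest.mark.parametrize("plamc,expected", [(0.0, 0.0), (0.01, 0.1), (1.0, 10.0)])
    def test_values(self, plamc, expected):
        assert macroboring_erosion(plamc) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            macroboring_erosion(1.2)


class TestTotalErosion:
    def test_sum(self):
        res = total_erosion(0.03, 0.01, 0.1)
        assert res.total == pytest.approx(0.14)
        assert (res.parrotfish, res.urchin, res.macroboring) == (0.03, 0.01, 0.1)

    def test_all_zero(self):
        assert total_erosion(0.0, 0.0, 0.0).total == 0.0

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            total_erosion(-0.1, 0.0, 0.0)


class TestOracleEquivalence:
    """Module pipeline vs an independent row-by-row transcription of the
    published erosion equations, on randomly generated record sets."""

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**20))
    def test_random_twenty_record_sites(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        traits = TraitTable(
            [SpeciesTraits(f"p{i}", brc=float(rng.uniform(10, 30))) for i in range(3)]
        )
        fish = [
            FishRecord(f"p{rng.integers(3)}", float(rng.uniform(8, 60)))
            for _ in range(20)
        ]
        urchins = [
            UrchinRecord(
                ["Diadema", "Echinometra", "Other"][rng.integers(3)],
                float(rng.uniform(0.5, 15.0)),
            )
            for _ in range(20)
        ]
        D = float(rng.uniform(1.0, 2.0))
        got_fish = parrotfish_erosion(fish, D, traits, 720.0)
        want_fish = oracle_parrotfish(
            [(f.length, traits[f.species].brc) for f in fish], D, 720.0
        )
        assert got_fish == pytest.approx(want_fish, rel=1e-9)

        got_urch = urchin_erosion(urchins, 36.0)
        want_urch = oracle_urchin([(u.group, u.test_diameter) for u in urchins], 36.0)
        assert got_urch == pytest.approx(want_urch, rel=1e-9)
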