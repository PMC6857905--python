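import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefbudget.acanthaster import (
    AcanthasterParams,
    acanthaster_reduction,
    attack_rate,
    density_threshold,
    ingestion_rate,
    transect_consumption,
)
from reefbudget.survey import SiteCover

from _oracles import oracle_acanthaster_reduction, oracle_attack_rate, oracle_ingestion

from conftest import make_site


def cover_for(R: float, D: float = 1.5) -> SiteCover:
    return SiteCover(
        taxon_cover={},
        live_coral_cover=R,
        pca=0.0,
        plamc=0.0,
        rugosity=1.0,
        mean_coral_density=D,
    )


class TestAttackRate:
    def test_hand_computed_at_90_percent_cover(self):
        # inter-coral distance 1 m -> search circle radius 0.5 m
        expected = 12.0 / (0.5**2 * math.pi) / 504.0
        assert attack_rate(90.0) == pytest.approx(expected, rel=1e-6)
        assert attack_rate(90.0) == pytest.approx(0.03032, rel=1e-3)

    def test_strictly_increasing_in_cover(self):
        grid = np.linspace(0.0, 100.0, 201)
        vals = [attack_rate(float(r)) for r in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_full_cover_finite_and_large(self):
        a = attack_rate(100.0)
        assert math.isfinite(a)
        assert a > attack_rate(99.9) > 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            attack_rate(101.0)
        with pytest.raises(ValueError):
            attack_rate(-1.0)


class TestIngestionRate:
    def test_zero_resource_is_zero(self):
        assert ingestion_rate(0.0, 0.05) == 0.0

    def test_hand_computed(self):
        a = 0.03032
        got = ingestion_rate(90.0, a)
        want = (a * 90.0 / (1.0 + a * 3.5 * 90.0)) * 4.53
        assert got == pytest.approx(want, rel=1e-12)
        assert got == pytest.approx(1.172, abs=2e-3)

    def test_type_two_saturation_bound(self):
        p = AcanthasterParams()
        bound = p.rescale / p.handling_time
        for R in (10.0, 50.0, 100.0, 1e6):
            assert ingestion_rate(R, 0.5) < bound

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ingestion_rate(-1.0, 0.1)


class TestTransectConsumption:
    def test_zero_count_is_zero(self):
        assert transect_consumption(0, 6, 1.5) == 0.0

    def test_hand_computed(self):
        # A.sp = 2 per transect, con = 0.01, D = 1.5
        assert transect_consumption(12, 6, 1.5) == pytest.approx(2 * 0.01 * 1.5 * 10 * 365)
        assert transect_consumption(12, 6, 1.5) == pytest.approx(109.5)

    def test_linear_in_count(self):
        one = transect_consumption(3, 6, 1.2)
        assert transect_consumption(6, 6, 1.2) == pytest.approx(2 * one)

    def test_zero_transects_rejected(self):
        with pytest.raises(ValueError):
            transect_consumption(1, 0, 1.5)


class TestReduction:
    def test_hand_computed_raw_reduction(self):
        site = make_site([("sand", 1000.0)], acanthaster_count=12)
        impact = acanthaster_reduction(site, cover_for(90.0, 1.5), gross=100.0)
        a = attack_rate(90.0)
        ri = ingestion_rate(90.0, a)
        assert impact.raw_reduction == pytest.approx(109.5 * ri / 50.0, rel=1e-9)
        assert impact.raw_reduction == pytest.approx(2.566, abs=5e-3)

    def test_clamped_at_gross(self):
        site = make_site([("sand", 1000.0)], acanthaster_count=60)
        impact = acanthaster_reduction(site, cover_for(90.0, 1.8), gross=2.0)
        assert impact.raw_reduction > 2.0
        assert impact.reduction == pytest.approx(2.0)

    def test_no_sea_stars(self):
        site = make_site([("sand", 1000.0)], acanthaster_count=0)
        impact = acanthaster_reduction(site, cover_for(50.0), gross=5.0)
        assert impact.reduction == 0.0
        assert not impact.outbreak_flag

    def test_outbreak_flag_uses_total_belt_area(self):
        # 1 sea star over 300 m^2 is 33 ha^-1, just above the 30 ha^-1 convention
        site = make_site([("sand", 1000.0)], acanthaster_count=1)
        impact = acanthaster_reduction(site, cover_for(50.0), gross=5.0)
        assert impact.density_per_300m2 == pytest.approx(1.0)
        assert impact.outbreak_flag

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        count=st.integers(0, 40),
        R=st.floats(min_value=0.0, max_value=100.0),
        D=st.floats(min_value=0.5, max_value=2.5),
        gross=st.floats(min_value=0.0, max_value=25.0),
    )
    def test_oracle_equivalence_and_clamp(self, count, R, D, gross):
        site = make_site([("sand", 1000.0)], acanthaster_count=count)
        impact = acanthaster_reduction(site, cover_for(R, D), gross=gross)
        want, want_raw = oracle_acanthaster_reduction(count, 6, R, D, gross)
        assert impact.raw_reduction == pytest.approx(want_raw, rel=1e-9, abs=1e-12)
        assert impact.reduction == pytest.approx(want, rel=1e-9, abs=1e-12)
        assert 0.0 <= impact.reduction <= gross + 1e-12
        assert impact.reduction <= impact.raw_reduction + 1e-12

    def test_monotone_in_count_and_cover(self):
        grid_R = np.linspace(1.0, 100.0, 34)
        for count_a, count_b in [(0, 3), (3, 9), (9, 30)]:
            for R in grid_R:
                sa = make_site([("sand", 1000.0)], acanthaster_count=count_a)
                sb = make_site([("sand", 1000.0)], acanthaster_count=count_b)
                ra = acanthaster_reduction(sa, cover_for(float(R)), gross=50.0)
                rb = acanthaster_reduction(sb, cover_for(float(R)), gross=50.0)
                assert rb.reduction >= ra.reduction
        site = make_site([("sand", 1000.0)], acanthaster_count=6)
        vals = [
            acanthaster_reduction(site, cover_for(float(R)), gross=50.0).reduction
            for R in grid_R
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestDensityThreshold:
    def test_bracketing_by_brute_force(self):
        for R, gross, D in [(30.0, 6.0, 1.4), (80.0, 10.0, 1.6), (15.0, 2.0, 1.2)]:
            thr = density_threshold(R, gross, D)
            site_n = make_site([("sand", 1000.0)], acanthaster_count=thr.count)
            red_n = acanthaster_reduction(site_n, cover_for(R, D), gross=gross * 10).reduction
            assert red_n >= gross - 1e-9
            if thr.count > 0:
                site_m = make_site([("sand", 1000.0)], acanthaster_count=thr.count - 1)
                red_m = acanthaster_reduction(
                    site_m, cover_for(R, D), gross=gross * 10
                ).reduction
                assert red_m < gross

    def test_doubling_gross_roughly_doubles_count(self):
        a = density_threshold(40.0, 5.0, 1.5)
        b = density_threshold(40.0, 10.0, 1.5)
        # exact linear inversion up to integer rounding
        assert abs(b.count - 2 * a.count) <= 1

    def test_percent_form_consistent(self):
        thr = density_threshold(30.0, 6.0, 1.4)
        assert thr.percent_of_cover == pytest.approx(
            100.0 * thr.count_per_100m2 / 30.0, rel=1e-12
        )

    def test_degenerate_inputs_warn_and_return_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            thr = density_threshold(0.0, 5.0, 1.5)
        assert thr.count == 0
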