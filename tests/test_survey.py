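import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefbudget.survey import (
    SiteSurvey,
    SurveySchemaError,
    SurveyValidationError,
    Transect,
    TransectSegment,
    TraitTable,
    read_survey,
    site_cover,
    write_survey,
)
from reefbudget.synthetic import generate_survey, paper_like_config

from conftest import make_site, make_transect


class TestInvariants:
    def test_planar_longer_than_contour_rejected(self):
        with pytest.raises(SurveyValidationError, match="rugosity"):
            Transect(
                segments=[TransectSegment("sand", 1000.0)],
                contour_length=1000.0,
                planar_length=1200.0,
            )

    def test_negative_segment_rejected(self):
        with pytest.raises(SurveyValidationError):
            TransectSegment("Porites_rus", -5.0)

    def test_unknown_habitat_rejected(self):
        with pytest.raises(SurveyValidationError, match="habitat"):
            make_site([("sand", 1000.0)], habitat="lagoon")

    def test_segments_must_sum_to_contour(self):
        with pytest.raises(SurveyValidationError, match="sum"):
            Transect(
                segments=[TransectSegment("sand", 400.0)],
                contour_length=1000.0,
                planar_length=900.0,
            )


class TestSiteCover:
    def test_single_taxon_proportion(self, traits):
        site = make_site([("Porites_rus", 200.0)])
        cov = site_cover(site, traits)
        assert cov.taxon_cover["Porites_rus"] == pytest.approx(20.0)
        assert cov.live_coral_cover == pytest.approx(20.0)

    def test_rugosity_ratio(self, traits):
        site = make_site([("sand", 1000.0)], rugosity=1.25)
        assert site_cover(site, traits).rugosity == pytest.approx(1.25)

    def test_density_is_cover_weighted_mean(self, traits):
        # two corals at 10% each with d = 1.2 and 1.8 -> D = 1.5
        site = make_site([("Porites_cylindrica", 100.0), ("Acropora_hyacinthus", 100.0)])
        d1 = traits["Porites_cylindrica"].density_d  # 1.22
        d2 = traits["Acropora_hyacinthus"].density_d  # 1.60
        cov = site_cover(site, traits)
        assert cov.mean_coral_density == pytest.approx((d1 + d2) / 2)

    def test_zero_coral_gives_zero_density(self, traits):
        cov = site_cover(make_site([("sand", 1000.0)]), traits)
        assert cov.live_coral_cover == 0.0
        assert cov.mean_coral_density == 0.0

    def test_unmatched_taxon_lists_names(self, traits):
        site = make_site([("Atlantis_coral", 100.0)])
        with pytest.raises(SurveyValidationError, match="Atlantis_coral"):
            site_cover(site, traits)

    def test_ca_and_macroborer_returned_as_proportions(self, traits):
        site = make_site([("coralline_algae", 120.0), ("macroborer", 30.0)])
        cov = site_cover(site, traits)
        assert cov.pca == pytest.approx(0.12)
        assert cov.plamc == pytest.approx(0.03)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        lengths=st.lists(
            st.floats(min_value=1.0, max_value=300.0), min_size=1, max_size=6
        ),
        seed=st.integers(0, 2**16),
    )
    def test_cover_invariant_under_segment_permutation(self, traits, lengths, seed):
        import random

        taxa = ["Porites_rus", "Porites_lobata", "sand"]
        pairs = [(taxa[i % 3], l) for i, l in enumerate(lengths)]
        site_a = make_site(pairs)
        random.Random(seed).shuffle(pairs)
        site_b = make_site(pairs)
        ca, cb = site_cover(site_a, traits), site_cover(site_b, traits)
        assert ca.taxon_cover == pytest.approx(cb.taxon_cover)
        assert ca.live_coral_cover == pytest.approx(cb.live_coral_cover)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_cover_invariant_under_length_rescaling(self, traits, scale):
        base = [("Porites_rus", 150.0), ("coralline_algae", 50.0)]
        site = make_site(base)
        scaled = SiteSurvey(
            site_id="S2",
            island="Pohnpei",
            habitat="inner",
            transects=[
                Transect(
                    segments=[
                        TransectSegment(s.taxon, s.intercept_length * scale)
                        for s in tr.segments
                    ],
                    contour_length=tr.contour_length * scale,
                    planar_length=tr.planar_length * scale,
                )
                for tr in site.transects
            ],
        )
        a, b = site_cover(site, traits), site_cover(scaled, traits)
        assert a.taxon_cover == pytest.approx(b.taxon_cover)
        assert a.rugosity == pytest.approx(b.rugosity)

    def test_bounds_on_any_valid_survey(self, traits):
        surveys, _ = generate_survey(paper_like_config(seed=5), traits)
        for s in surveys:
            cov = site_cover(s, traits)
            assert 0.0 <= cov.live_coral_cover <= 100.0
            assert cov.rugosity >= 1.0
            assert sum(cov.taxon_cover.values()) == pytest.approx(100.0, abs=0.5)


class TestIO:
    def _write_fixture(self, tmp_path, surveys):
        paths = (tmp_path / "benthic.csv", tmp_path / "mobile.csv", tmp_path / "fish.csv")
        write_survey(surveys, *paths)
        return paths

    def test_two_site_round_trip(self, tmp_path, traits):
        from reefbudget.survey import FishRecord, UrchinRecord

        s1 = make_site(
            [("Porites_rus", 200.0)],
            site_id="A",
            urchins=[UrchinRecord("Echinometra", 3.5)],
            fish=[FishRecord("Chlorurus_spilurus", 24.0)],
            acanthaster_count=2,
        )
        s2 = make_site(
            [("sand", 1000.0)], site_id="B", sediment_regime="high_terrigenous"
        )
        paths = self._write_fixture(tmp_path, [s1, s2])
        back = read_survey(*paths)
        assert len(back) == 2
        assert all(len(s.transects) == 6 for s in back)
        by_id = {s.site_id: s for s in back}
        assert by_id["A"].acanthaster_count == 2
        assert by_id["A"].urchins == s1.urchins
        assert by_id["A"].fish == s1.fish
        assert by_id["B"].sediment_regime == "high_terrigenous"

    def test_synthetic_survey_round_trip_identical(self, tmp_path, traits):
        surveys, _ = generate_survey(paper_like_config(seed=2), traits)
        paths = self._write_fixture(tmp_path, surveys)
        back = {s.site_id: s for s in read_survey(*paths)}
        assert len(back) == len(surveys) == 48
        for s in surveys:
            r = back[s.site_id]
            assert r.habitat == s.habitat and r.island == s.island
            assert r.acanthaster_count == s.acanthaster_count
            assert r.sediment_regime == s.sediment_regime
            assert len(r.transects) == len(s.transects)
            for ta, tb in zip(s.transects, r.transects):
                assert tb.contour_length == pytest.approx(ta.contour_length)
                assert tb.planar_length == pytest.approx(ta.planar_length)
                assert sorted((x.taxon, x.intercept_length) for x in tb.segments) == sorted(
                    (x.taxon, x.intercept_length) for x in ta.segments
                )
            assert sorted(r.urchins, key=str) == sorted(s.urchins, key=str)
            assert sorted(r.fish, key=str) == sorted(s.fish, key=str)

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "benthic.csv"
        p.write_text("site_id,island,habitat,transect_no,taxon,intercept_cm\nA,P,inner,1,sand,100\n")
        with pytest.raises(SurveySchemaError, match="contour_cm"):
            read_survey(p)

    def test_negative_length_reports_row(self, tmp_path):
        p = tmp_path / "benthic.csv"
        p.write_text(
            "site_id,island,habitat,transect_no,taxon,intercept_cm,contour_cm,planar_cm,sediment_regime\n"
            "A,P,inner,1,sand,-100,1000,900,normal\n"
        )
        with pytest.raises(SurveyValidationError, match="row 1"):
            read_survey(p)

    def test_unknown_habitat_label_rejected_on_read(self, tmp_path):
        p = tmp_path / "benthic.csv"
        p.write_text(
            "site_id,island,habitat,transect_no,taxon,intercept_cm,contour_cm,planar_cm,sediment_regime\n"
            "A,P,abyss,1,sand,1000,1000,900,normal\n"
        )
        with pytest.raises(SurveyValidationError, match="habitat"):
            read_survey(p)


class TestTraitTable:
    def test_default_table_has_corals_and_parrotfish(self, traits):
        assert len(traits.coral_taxa) >= 5
        assert traits["Chlorurus_spilurus"].brc is not None
        assert not traits["Chlorurus_spilurus"].is_coral

    def test_round_trip(self, tmp_path, traits):
        p = tmp_path / "traits.csv"
        traits.to_csv(p)
        back = TraitTable.from_csv(p)
        assert len(back) == len(traits)
        assert back["Porites_rus"].density_d == traits["Porites_rus"].density_d
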