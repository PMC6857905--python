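import pytest

from reefbudget import TraitTable
from reefbudget.survey import SiteSurvey, Transect, TransectSegment


@pytest.fixture(scope="session")
def traits() -> TraitTable:
    return TraitTable.default()


def make_transect(segments, contour=1000.0, planar=None, rugosity=None):
    """Build a transect from (taxon, length) pairs, padding with 'other'."""
    total = sum(length for _, length in segments)
    segs = [TransectSegment(t, l) for t, l in segments]
    if total < contour:
        segs.append(TransectSegment("other", contour - total))
    if planar is None:
        planar = contour / rugosity if rugosity else contour
    return Transect(segments=segs, contour_length=contour, planar_length=planar)


def make_site(
    segments,
    *,
    site_id="S1",
    island="Pohnpei",
    habitat="inner",
    n_transects=6,
    rugosity=1.0,
    urchins=(),
    fish=(),
    acanthaster_count=0,
    sediment_regime="normal",
):
    """A site with ``n_transects`` identical transects built from segment pairs."""
    return SiteSurvey(
        site_id=site_id,
        island=island,
        habitat=habitat,
        transects=[
            make_transect(list(segments), rugosity=rugosity) for _ in range(n_transects)
        ],
        urchins=list(urchins),
        fish=list(fish),
        acanthaster_count=acanthaster_count,
        sediment_regime=sediment_regime,
    )
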