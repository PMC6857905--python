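"""Field-survey domain model: transects, mobile invertebrates, fish, and sites.

A census-based carbonate budget starts from four kinds of field records taken
at each site:

* six 10 m line-intercept transects laid along the substrate, recording the
  benthic taxon under every centimetre of tape, together with the planar
  length of a second tape spanning the same stretch horizontally (rugosity);
* urchin counts and test diameters within a 0.6 m x 10 m belt per transect;
* crown-of-thorns sea star (*Acanthaster solaris*) counts within a
  5 m x 10 m belt per transect;
* parrotfish species and lengths on six 30 m x 4 m fish transects.

This module defines those records, reads and writes them as plain CSV, and
derives the site-level summaries (percent cover, rugosity, mean skeletal
density) that the production and erosion equations consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SurveySchemaError",
    "SurveyValidationError",
    "TransectSegment",
    "Transect",
    "UrchinRecord",
    "FishRecord",
    "SiteSurvey",
    "SpeciesTraits",
    "TraitTable",
    "SiteCover",
    "HABITATS",
    "URCHIN_GROUPS",
    "SEDIMENT_REGIMES",
    "NON_CORAL_LABELS",
    "read_survey",
    "write_survey",
    "site_cover",
]

HABITATS = ("inner", "patch", "outer")
URCHIN_GROUPS = ("Diadema", "Echinometra", "Other")
SEDIMENT_REGIMES = ("normal", "high_terrigenous")

#: Benthic labels that are never looked up in the coral trait table. The
#: first two carry their own terms in the budget (coralline-algae production,
#: macroborer erosion); the rest are abiotic or non-calcifying cover.
NON_CORAL_LABELS = frozenset(
    {
        "coralline_algae",
        "macroborer",
        "sand",
        "rubble",
        "pavement",
        "turf_algae",
        "macroalgae",
        "soft_coral",
        "other",
    }
)

# Default surveyed areas, per transect, in m^2 (overridable in config).
URCHIN_BELT_M2 = 6.0
ACANTHASTER_BELT_M2 = 50.0
FISH_TRANSECT_M2 = 120.0


class SurveySchemaError(ValueError):
    """A survey file is missing a required column or has a malformed header."""


class SurveyValidationError(ValueError):
    """A survey record violates a domain invariant (bad length, label, ...)."""


@dataclass(frozen=True)
class TransectSegment:
    """One run of a single benthic taxon under the line-intercept tape."""

    taxon: str
    intercept_length: float  # cm along the substrate-following tape, > 0

    def __post_init__(self) -> None:
        if not self.taxon:
            raise SurveyValidationError("segment taxon label is empty")
        if not self.intercept_length > 0:
            raise SurveyValidationError(
                f"segment intercept_length must be > 0, got {self.intercept_length}"
            )


@dataclass
class Transect:
    """One 10 m line-intercept transect with its rugosity tape pair.

    ``contour_length`` is the tape following the substrate (nominally
    1000 cm); ``planar_length`` is the horizontal span of the same stretch.
    Their ratio is the transect rugosity, which must be >= 1.
    """

    segments: list[TransectSegment]
    contour_length: float = 1000.0
    planar_length: float = 1000.0

    def __post_init__(self) -> None:
        if not self.planar_length > 0:
            raise SurveyValidationError("planar_length must be > 0")
        if self.contour_length < self.planar_length:
            raise SurveyValidationError(
                f"contour_length ({self.contour_length}) < planar_length "
                f"({self.planar_length}): rugosity would be < 1"
            )
        total = sum(s.intercept_length for s in self.segments)
        if self.segments and abs(total - self.contour_length) > 0.5:
            raise SurveyValidationError(
                f"segment lengths sum to {total:.1f} cm but contour_length is "
                f"{self.contour_length:.1f} cm"
            )

    @property
    def rugosity(self) -> float:
        return self.contour_length / self.planar_length


@dataclass(frozen=True)
class UrchinRecord:
    """One echinoid, assigned to a genus group with its test diameter (cm)."""

    group: str
    test_diameter: float  # cm, recorded to the nearest 0.5

    def __post_init__(self) -> None:
        if self.group not in URCHIN_GROUPS:
            raise SurveyValidationError(
                f"unknown urchin group {self.group!r}; expected one of {URCHIN_GROUPS}"
            )
        if not self.test_diameter > 0:
            raise SurveyValidationError("urchin test_diameter must be > 0")


@dataclass(frozen=True)
class FishRecord:
    """One parrotfish observation: species label and length (cm)."""

    species: str
    length: float

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise SurveyValidationError("fish length must be > 0")


@dataclass
class SiteSurvey:
    """All raw field observations for one site."""

    site_id: str
    island: str
    habitat: str
    transects: list[Transect]
    urchins: list[UrchinRecord] = field(default_factory=list)
    fish: list[FishRecord] = field(default_factory=list)
    acanthaster_count: int = 0
    sediment_regime: str = "normal"
    urchin_area_m2: float | None = None  # total urchin belt area over all transects
    fish_area_m2: float | None = None  # total fish-transect area
    acanthaster_area_m2: float | None = None  # total sea-star belt area

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise SurveyValidationError(
                f"site {self.site_id}: unknown habitat {self.habitat!r}; "
                f"expected one of {HABITATS}"
            )
        if self.sediment_regime not in SEDIMENT_REGIMES:
            raise SurveyValidationError(
                f"site {self.site_id}: unknown sediment regime "
                f"{self.sediment_regime!r}; expected one of {SEDIMENT_REGIMES}"
            )
        if self.acanthaster_count < 0:
            raise SurveyValidationError(
                f"site {self.site_id}: acanthaster_count must be >= 0"
            )
        if not self.transects:
            raise SurveyValidationError(f"site {self.site_id}: no transects")
        n = len(self.transects)
        if self.urchin_area_m2 is None:
            self.urchin_area_m2 = URCHIN_BELT_M2 * n
        if self.fish_area_m2 is None:
            self.fish_area_m2 = FISH_TRANSECT_M2 * n
        if self.acanthaster_area_m2 is None:
            self.acanthaster_area_m2 = ACANTHASTER_BELT_M2 * n
        for name in ("urchin_area_m2", "fish_area_m2", "acanthaster_area_m2"):
            if not getattr(self, name) > 0:
                raise SurveyValidationError(f"site {self.site_id}: {name} must be > 0")

    @property
    def n_transects(self) -> int:
        return len(self.transects)


@dataclass(frozen=True)
class SpeciesTraits:
    """Per-taxon constants of the production model.

    ``morphology_m`` converts planar cover to the growing surface of the
    colony shape (dimensionless, >= 1 for branching forms); ``density_d`` is
    skeletal bulk density (g cm^-3); ``growth_g`` is the vertical extension
    rate (cm yr^-1). ``brc`` is the parrotfish bite-rate constant and is only
    set on fish rows.
    """

    taxon: str
    morphology_m: float | None = None
    density_d: float | None = None
    growth_g: float | None = None
    brc: float | None = None

    def __post_init__(self) -> None:
        if self.morphology_m is not None and not self.morphology_m > 0:
            raise SurveyValidationError(f"{self.taxon}: morphology_m must be > 0")
        if self.density_d is not None and not self.density_d > 0:
            raise SurveyValidationError(f"{self.taxon}: density_d must be > 0")
        if self.growth_g is not None and self.growth_g < 0:
            raise SurveyValidationError(f"{self.taxon}: growth_g must be >= 0")

    @property
    def is_coral(self) -> bool:
        return self.density_d is not None and self.growth_g is not None


class TraitTable:
    """Lookup of :class:`SpeciesTraits` by taxon label."""

    def __init__(self, entries: Iterable[SpeciesTraits]):
        self._entries: dict[str, SpeciesTraits] = {}
        for e in entries:
            if e.taxon in self._entries:
                raise SurveyValidationError(f"duplicate trait entry for {e.taxon!r}")
            self._entries[e.taxon] = e

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._entries

    def __getitem__(self, taxon: str) -> SpeciesTraits:
        try:
            return self._entries[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} not in trait table") from None

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def coral_taxa(self) -> list[str]:
        return [e.taxon for e in self._entries.values() if e.is_coral]

    def coral(self, taxon: str) -> SpeciesTraits:
        e = self[taxon]
        if not e.is_coral:
            raise SurveyValidationError(f"{taxon!r} has no coral traits (d, g)")
        return e

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitTable":
        df = pd.read_csv(path, comment="#")
        required = {"taxon", "morphology_m", "density_d", "growth_g", "brc"}
        missing = required - set(df.columns)
        if missing:
            raise SurveySchemaError(
                f"trait table {path} missing column(s): {sorted(missing)}"
            )

        def opt(v):
            return None if pd.isna(v) else float(v)

        return cls(
            SpeciesTraits(
                taxon=str(row.taxon),
                morphology_m=opt(row.morphology_m),
                density_d=opt(row.density_d),
                growth_g=opt(row.growth_g),
                brc=opt(row.brc),
            )
            for row in df.itertuples(index=False)
        )

    @classmethod
    def default(cls) -> "TraitTable":
        """Packaged default trait table.

        These are synthetic defaults: representative values assembled from the
        coral-trait literature for the taxa that dominate Micronesian shallow
        reefs, not measurements from any particular study. Replace with your
        own table for real analyses.
        """
        with resources.as_file(
            resources.files("reefbudget.data").joinpath("traits_default.csv")
        ) as p:
            return cls.from_csv(p)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "taxon": e.taxon,
                "morphology_m": e.morphology_m,
                "density_d": e.density_d,
                "growth_g": e.growth_g,
                "brc": e.brc,
            }
            for e in self
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class SiteCover:
    """Site-level cover summary derived from the six transects.

    ``taxon_cover`` maps every observed taxon to its planar percent cover
    (0-100), averaged across transects. ``live_coral_cover`` (R) is the sum
    over coral taxa. ``pca`` and ``plamc`` are the coralline-algae and
    macroborer covers as proportions (0-1) because their budget terms are
    parameterised that way. ``mean_coral_density`` (D) is the cover-weighted
    mean skeletal density of the live corals, 0 when R = 0.
    """

    taxon_cover: dict[str, float]
    live_coral_cover: float
    pca: float
    plamc: float
    rugosity: float
    mean_coral_density: float

    def coral_cover(self, traits: TraitTable) -> dict[str, float]:
        unmatched = sorted(
            t
            for t in self.taxon_cover
            if t not in NON_CORAL_LABELS and t not in traits
        )
        if unmatched:
            raise SurveyValidationError(
                f"taxa missing from trait table: {unmatched}"
            )
        return {
            t: c
            for t, c in self.taxon_cover.items()
            if t not in NON_CORAL_LABELS and traits[t].is_coral
        }


def site_cover(survey: SiteSurvey, traits: TraitTable) -> SiteCover:
    """Derive percent cover, rugosity and mean coral density for one site.

    Per transect, a taxon's planar percent cover is 100 x (its summed
    intercept / the transect contour length): each intercept's planar extent
    is intercept/rugosity, and dividing that by the planar tape length gives
    the same ratio, so covers sum to 100 within a transect. Covers are then
    averaged across the site's transects (a taxon absent from a transect
    contributes 0 there). The rugosity correction is applied once, in the
    production equation, not per segment.
    """
    taxa: set[str] = set()
    for tr in survey.transects:
        taxa.update(s.taxon for s in tr.segments)

    unmatched = sorted(
        t for t in taxa if t not in NON_CORAL_LABELS and t not in traits
    )
    if unmatched:
        raise SurveyValidationError(
            f"site {survey.site_id}: taxa missing from trait table: {unmatched}"
        )

    n = survey.n_transects
    # sorted so summation order (and hence float rounding) is process-stable
    cover = {t: 0.0 for t in sorted(taxa)}
    for tr in survey.transects:
        per_taxon: dict[str, float] = {}
        for seg in tr.segments:
            per_taxon[seg.taxon] = per_taxon.get(seg.taxon, 0.0) + seg.intercept_length
        for t, length in per_taxon.items():
            cover[t] += 100.0 * length / tr.contour_length / n

    rugosity = sum(tr.rugosity for tr in survey.transects) / n

    coral = {
        t: c for t, c in cover.items() if t not in NON_CORAL_LABELS and traits[t].is_coral
    }
    live = sum(coral.values())
    if live > 0:
        density = sum(c * traits[t].density_d for t, c in coral.items()) / live
    else:
        density = 0.0

    return SiteCover(
        taxon_cover=cover,
        live_coral_cover=live,
        pca=cover.get("coralline_algae", 0.0) / 100.0,
        plamc=cover.get("macroborer", 0.0) / 100.0,
        rugosity=rugosity,
        mean_coral_density=density,
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

BENTHIC_COLUMNS = [
    "site_id",
    "island",
    "habitat",
    "transect_no",
    "taxon",
    "intercept_cm",
    "contour_cm",
    "planar_cm",
    "sediment_regime",
]
MOBILE_COLUMNS = [
    "site_id",
    "transect_no",
    "record_type",
    "group",
    "diameter_cm",
    "count",
]
FISH_COLUMNS = ["site_id", "transect_no", "species", "length_cm"]


def _read_table(path: str | Path, required: Sequence[str], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{label} file not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = set(required) - set(df.columns)
    if missing:
        raise SurveySchemaError(
            f"{label} file {path} missing required column(s): {sorted(missing)}"
        )
    return df


def read_survey(
    benthic_path: str | Path,
    mobile_path: str | Path | None = None,
    fish_path: str | Path | None = None,
    *,
    urchin_belt_m2: float = URCHIN_BELT_M2,
    acanthaster_belt_m2: float = ACANTHASTER_BELT_M2,
    fish_transect_m2: float = FISH_TRANSECT_M2,
) -> list[SiteSurvey]:
    """Read the three survey CSVs into one :class:`SiteSurvey` per site.

    ``benthic.csv`` is required; the mobile-invertebrate and fish files are
    optional (sites then carry empty urchin/fish lists and zero sea stars).
    Validation failures report the offending file row (1-based, excluding the
    header).
    """
    benthic = _read_table(benthic_path, BENTHIC_COLUMNS, "benthic")

    surveys: dict[str, dict] = {}
    transect_rows: dict[tuple[str, int], list] = {}
    for i, row in enumerate(benthic.itertuples(index=False), start=1):
        sid = str(row.site_id)
        try:
            seg = TransectSegment(str(row.taxon), float(row.intercept_cm))
        except SurveyValidationError as e:
            raise SurveyValidationError(f"benthic row {i}: {e}") from None
        meta = surveys.setdefault(
            sid,
            {
                "island": str(row.island),
                "habitat": str(row.habitat),
                "sediment_regime": str(row.sediment_regime),
            },
        )
        if meta["habitat"] != str(row.habitat):
            raise SurveyValidationError(
                f"benthic row {i}: site {sid} has inconsistent habitat labels"
            )
        key = (sid, int(row.transect_no))
        transect_rows.setdefault(
            key, [float(row.contour_cm), float(row.planar_cm), []]
        )[2].append(seg)

    transects: dict[str, list[Transect]] = {sid: [] for sid in surveys}
    for (sid, _no), (contour, planar, segs) in sorted(transect_rows.items()):
        try:
            transects[sid].append(
                Transect(segments=segs, contour_length=contour, planar_length=planar)
            )
        except SurveyValidationError as e:
            raise SurveyValidationError(f"site {sid}, transect {_no}: {e}") from None

    urchins: dict[str, list[UrchinRecord]] = {sid: [] for sid in surveys}
    cots: dict[str, int] = {sid: 0 for sid in surveys}
    if mobile_path is not None:
        mobile = _read_table(mobile_path, MOBILE_COLUMNS, "mobile")
        for i, row in enumerate(mobile.itertuples(index=False), start=1):
            sid = str(row.site_id)
            if sid not in surveys:
                raise SurveyValidationError(
                    f"mobile row {i}: site {sid!r} not present in benthic file"
                )
            rtype = str(row.record_type)
            if rtype == "urchin":
                try:
                    urchins[sid].append(
                        UrchinRecord(str(row.group), float(row.diameter_cm))
                    )
                except SurveyValidationError as e:
                    raise SurveyValidationError(f"mobile row {i}: {e}") from None
            elif rtype == "acanthaster":
                c = int(row.count)
                if c < 0:
                    raise SurveyValidationError(
                        f"mobile row {i}: acanthaster count must be >= 0"
                    )
                cots[sid] += c
            else:
                raise SurveyValidationError(
                    f"mobile row {i}: unknown record_type {rtype!r}"
                )

    fish: dict[str, list[FishRecord]] = {sid: [] for sid in surveys}
    if fish_path is not None:
        fdf = _read_table(fish_path, FISH_COLUMNS, "fish")
        for i, row in enumerate(fdf.itertuples(index=False), start=1):
            sid = str(row.site_id)
            if sid not in surveys:
                raise SurveyValidationError(
                    f"fish row {i}: site {sid!r} not present in benthic file"
                )
            try:
                fish[sid].append(FishRecord(str(row.species), float(row.length_cm)))
            except SurveyValidationError as e:
                raise SurveyValidationError(f"fish row {i}: {e}") from None

    out = []
    for sid, meta in surveys.items():
        n = len(transects[sid])
        out.append(
            SiteSurvey(
                site_id=sid,
                island=meta["island"],
                habitat=meta["habitat"],
                transects=transects[sid],
                urchins=urchins[sid],
                fish=fish[sid],
                acanthaster_count=cots[sid],
                sediment_regime=meta["sediment_regime"],
                urchin_area_m2=urchin_belt_m2 * n,
                fish_area_m2=fish_transect_m2 * n,
                acanthaster_area_m2=acanthaster_belt_m2 * n,
            )
        )
    return out


def write_survey(
    surveys: Sequence[SiteSurvey],
    benthic_path: str | Path,
    mobile_path: str | Path,
    fish_path: str | Path,
    *,
    header_comment: str | None = None,
) -> None:
    """Write surveys back to the three-CSV on-disk layout (read_survey inverse)."""
    b_rows, m_rows, f_rows = [], [], []
    for s in surveys:
        for no, tr in enumerate(s.transects, start=1):
            for seg in tr.segments:
                b_rows.append(
                    dict(
                        site_id=s.site_id,
                        island=s.island,
                        habitat=s.habitat,
                        transect_no=no,
                        taxon=seg.taxon,
                        intercept_cm=seg.intercept_length,
                        contour_cm=tr.contour_length,
                        planar_cm=tr.planar_length,
                        sediment_regime=s.sediment_regime,
                    )
                )
        for u in s.urchins:
            m_rows.append(
                dict(
                    site_id=s.site_id,
                    transect_no=1,
                    record_type="urchin",
                    group=u.group,
                    diameter_cm=u.test_diameter,
                    count=1,
                )
            )
        if s.acanthaster_count:
            m_rows.append(
                dict(
                    site_id=s.site_id,
                    transect_no=1,
                    record_type="acanthaster",
                    group="Acanthaster",
                    diameter_cm="",
                    count=s.acanthaster_count,
                )
            )
        for fr in s.fish:
            f_rows.append(
                dict(
                    site_id=s.site_id,
                    transect_no=1,
                    species=fr.species,
                    length_cm=fr.length,
                )
            )

    for path, rows, cols in (
        (benthic_path, b_rows, BENTHIC_COLUMNS),
        (mobile_path, m_rows, MOBILE_COLUMNS),
        (fish_path, f_rows, FISH_COLUMNS),
    ):
        df = pd.DataFrame(rows, columns=cols)
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False, lineterminator="\n")
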