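"""Gross carbonate production: coral calcification, coralline algae, sediment.

Coral gross production at a site is

    gross_coral = r * sum_j (m_j * x_j / 100) * d_j * g_j * 10

with r the site rugosity, x_j the planar percent cover of coral taxon j,
m_j its morphology coefficient, d_j its skeletal density (g cm^-3), g_j its
vertical extension rate (cm yr^-1), and 10 the unit conversion from
g cm^-2 yr^-1 to kg m^-2 yr^-1. Crustose coralline algae add
0.018 g cm^-2 yr^-1 scaled by their cover proportion, and calcareous
sedimentation contributes a fixed signed term: +0.4 kg m^-2 yr^-1 where the
sediment supply is calcareous, -0.4 where heavy terrigenous sediment
smothers corals.
"""

from __future__ import annotations

from dataclasses import dataclass

from .survey import SEDIMENT_REGIMES, SiteCover, TraitTable

__all__ = [
    "UNIT_SCALE",
    "CA_RATE",
    "SEDIMENTATION_RATE",
    "CalcificationResult",
    "coral_calcification",
    "coralline_algae_production",
    "sedimentation_term",
]

#: g cm^-2 yr^-1 -> kg m^-2 yr^-1
UNIT_SCALE = 10.0
#: gross coralline-algae production at full cover, g cm^-2 yr^-1
CA_RATE = 0.018
#: magnitude of the signed sedimentation term, kg CaCO3 m^-2 yr^-1
SEDIMENTATION_RATE = 0.4


@dataclass
class CalcificationResult:
    """Coral gross production with its per-taxon decomposition (rugosity included)."""

    gross_coral: float  # kg CaCO3 m^-2 yr^-1
    ca_production: float  # kg CaCO3 m^-2 yr^-1, before the rugosity factor
    per_taxon: dict[str, float]


def coral_calcification(
    cover: SiteCover,
    traits: TraitTable,
    *,
    unit_scale: float = UNIT_SCALE,
    ca_rate: float = CA_RATE,
) -> CalcificationResult:
    """Gross carbonate production of the live corals at one site.

    The returned ``per_taxon`` terms include the rugosity factor, so they sum
    to ``gross_coral``. ``ca_production`` is the coralline-algae term before
    rugosity; the budget assembler multiplies it by rugosity when it forms
    the site's gross production, mirroring its position inside the braces of
    the production equation.
    """
    r = cover.rugosity
    per_taxon: dict[str, float] = {}
    for taxon, x in cover.coral_cover(traits).items():
        t = traits.coral(taxon)
        per_taxon[taxon] = r * (t.morphology_m * x / 100.0) * t.density_d * t.growth_g * unit_scale
    return CalcificationResult(
        gross_coral=sum(per_taxon.values()),
        ca_production=coralline_algae_production(
            cover.pca, ca_rate=ca_rate, unit_scale=unit_scale
        ),
        per_taxon=per_taxon,
    )


def coralline_algae_production(
    pca: float, *, ca_rate: float = CA_RATE, unit_scale: float = UNIT_SCALE
) -> float:
    """Gross carbonate production by crustose coralline algae.

    ``pca`` is the planar CCA cover as a proportion (0-1); full cover yields
    ca_rate * 10 = 0.18 kg CaCO3 m^-2 yr^-1.
    """
    if not 0.0 <= pca <= 1.0:
        raise ValueError(f"pca must be a proportion in [0, 1], got {pca}")
    return ca_rate * pca * unit_scale


def sedimentation_term(
    regime: str, *, magnitude: float = SEDIMENTATION_RATE
) -> float:
    """Signed sedimentation contribution (kg CaCO3 m^-2 yr^-1).

    Calcareous sediment supplements reef accretion (+magnitude); heavy
    terrigenous sediment smothers corals and enters with a negative sign.
    """
    if regime == "normal":
        return +magnitude
    if regime == "high_terrigenous":
        return -magnitude
    raise ValueError(
        f"unknown sediment regime {regime!r}; expected one of {SEDIMENT_REGIMES}"
    )
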