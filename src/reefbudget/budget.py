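"""Site carbonate budgets, vertical accretion, and sea-level-rise comparison.

Per site, net carbonate production (kg CaCO3 m^-2 yr^-1) is

    net = gross + signed sedimentation - erosion

with gross = coral calcification + rugosity-scaled coralline-algae
production; a second net subtracts the *Acanthaster* reduction (reported
separately, as in the habitat summary table). Net production converts to
vertical reef accretion (mm yr^-1) via the quadratic

    accretion(Cp) = Cp + Cp * (Cp * alpha),   alpha = -0.01949,

which is then compared against the sea-level-rise rates projected for the
four RCP greenhouse-gas scenarios (5, 6.5, 6.7 and 9 mm yr^-1 by 2100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import bioerosion, calcification
from .acanthaster import AcanthasterImpact, AcanthasterParams, acanthaster_reduction
from .survey import SiteCover, SiteSurvey, TraitTable, site_cover

__all__ = [
    "ACCRETION_ALPHA",
    "SeaLevelScenario",
    "DEFAULT_SCENARIOS",
    "BudgetParams",
    "CarbonateBudget",
    "site_budget",
    "vertical_accretion",
    "keeps_up",
    "habitat_summary",
    "species_contributions",
    "budgets_to_frame",
]

#: curvature of the production -> accretion conversion
ACCRETION_ALPHA = -0.01949


@dataclass(frozen=True)
class SeaLevelScenario:
    """A named greenhouse-gas scenario with its projected sea-level-rise rate."""

    name: str
    rise_rate: float  # mm yr^-1

    def __post_init__(self) -> None:
        if self.rise_rate < 0:
            raise ValueError("rise_rate must be >= 0")


DEFAULT_SCENARIOS: tuple[SeaLevelScenario, ...] = (
    SeaLevelScenario("RCP2.6", 5.0),
    SeaLevelScenario("RCP4.5", 6.5),
    SeaLevelScenario("RCP6.0", 6.7),
    SeaLevelScenario("RCP8.5", 9.0),
)


@dataclass
class BudgetParams:
    """Every named constant of the per-site budget, in one place."""

    sedimentation_rate: float = calcification.SEDIMENTATION_RATE
    ca_rate: float = calcification.CA_RATE
    unit_scale: float = calcification.UNIT_SCALE
    reeftime: float = bioerosion.REEFTIME_HOURS
    mec: float = bioerosion.MACROBORING_CAPACITY
    default_brc: float = bioerosion.DEFAULT_BRC
    accretion_alpha: float = ACCRETION_ALPHA
    #: accretion computed from net after the Acanthaster subtraction by default
    accretion_basis: str = "net_with_acanthaster"
    acanthaster: AcanthasterParams = field(default_factory=AcanthasterParams)

    def __post_init__(self) -> None:
        if self.accretion_basis not in ("net", "net_with_acanthaster"):
            raise ValueError(
                "accretion_basis must be 'net' or 'net_with_acanthaster'"
            )


@dataclass
class CarbonateBudget:
    """Per-site decomposition of the carbonate budget (kg CaCO3 m^-2 yr^-1)."""

    site_id: str
    island: str
    habitat: str
    gross: float  # coral + rugosity-scaled coralline algae
    sedimentation: float  # signed
    erosion: bioerosion.ErosionResult
    acanthaster: AcanthasterImpact
    net: float  # gross + sedimentation - erosion.total (Acanthaster excluded)
    net_with_acanthaster: float
    accretion: float  # mm yr^-1
    cover: SiteCover
    per_taxon_gross: dict[str, float]


def site_budget(
    survey: SiteSurvey,
    traits: TraitTable,
    params: BudgetParams | None = None,
) -> CarbonateBudget:
    """Assemble the full carbonate budget for one site."""
    p = params or BudgetParams()
    cover = site_cover(survey, traits)

    calc = calcification.coral_calcification(
        cover, traits, unit_scale=p.unit_scale, ca_rate=p.ca_rate
    )
    gross = calc.gross_coral + cover.rugosity * calc.ca_production

    sediment = calcification.sedimentation_term(
        survey.sediment_regime, magnitude=p.sedimentation_rate
    )

    erosion = bioerosion.total_erosion(
        parrotfish=bioerosion.parrotfish_erosion(
            survey.fish,
            cover.mean_coral_density,
            traits,
            survey.fish_area_m2,
            reeftime=p.reeftime,
            default_brc=p.default_brc,
        ),
        urchin=bioerosion.urchin_erosion(survey.urchins, survey.urchin_area_m2),
        macroboring=bioerosion.macroboring_erosion(cover.plamc, mec=p.mec),
    )

    impact = acanthaster_reduction(survey, cover, gross, p.acanthaster)

    net = gross + sediment - erosion.total
    net_cots = net - impact.reduction
    basis = net_cots if p.accretion_basis == "net_with_acanthaster" else net

    return CarbonateBudget(
        site_id=survey.site_id,
        island=survey.island,
        habitat=survey.habitat,
        gross=gross,
        sedimentation=sediment,
        erosion=erosion,
        acanthaster=impact,
        net=net,
        net_with_acanthaster=net_cots,
        accretion=vertical_accretion(basis, alpha=p.accretion_alpha),
        cover=cover,
        per_taxon_gross=calc.per_taxon,
    )


def vertical_accretion(Cp: float, alpha: float = ACCRETION_ALPHA) -> float:
    """Convert net carbonate production (kg m^-2 yr^-1) to accretion (mm yr^-1).

    The quadratic Cp + Cp*(Cp*alpha) is concave for alpha < 0 with its
    maximum at Cp = -1/(2*alpha) ~ 25.65 kg m^-2 yr^-1; within the observed
    production range it is monotone increasing.
    """
    return Cp + Cp * (Cp * alpha)


def keeps_up(accretion: float, scenario: SeaLevelScenario) -> bool:
    """Whether a reef accreting at ``accretion`` mm yr^-1 keeps pace with the
    scenario's sea-level rise. Exact equality counts as keeping up."""
    return accretion >= scenario.rise_rate


def budgets_to_frame(budgets: Sequence[CarbonateBudget]) -> pd.DataFrame:
    """Flatten budgets into a tidy per-site table."""
    rows = []
    for b in budgets:
        rows.append(
            {
                "site_id": b.site_id,
                "island": b.island,
                "habitat": b.habitat,
                "live_coral_cover": b.cover.live_coral_cover,
                "rugosity": b.cover.rugosity,
                "mean_coral_density": b.cover.mean_coral_density,
                "gross": b.gross,
                "sedimentation": b.sedimentation,
                "erosion_parrotfish": b.erosion.parrotfish,
                "erosion_urchin": b.erosion.urchin,
                "erosion_macroboring": b.erosion.macroboring,
                "erosion_total": b.erosion.total,
                "acanthaster_reduction": b.acanthaster.reduction,
                "acanthaster_density_300m2": b.acanthaster.density_per_300m2,
                "outbreak": b.acanthaster.outbreak_flag,
                "net": b.net,
                "net_with_acanthaster": b.net_with_acanthaster,
                "accretion_mm_yr": b.accretion,
            }
        )
    return pd.DataFrame(rows)


def habitat_summary(
    budgets: Sequence[CarbonateBudget],
    *,
    include_island_totals: bool = True,
    include_cross_island: bool = True,
) -> pd.DataFrame:
    """Mean +/- sample SD of the budget components per island x habitat group.

    Mirrors the habitat summary table layout: one row per island x habitat,
    optional per-island combined rows and cross-island per-habitat rows.
    Groups with a single site report SD 0 and set ``sd_degenerate``. Empty
    groups are omitted with a warning.
    """
    df = budgets_to_frame(budgets)
    if df.empty:
        warnings.warn("habitat_summary called with no budgets", stacklevel=2)
        return pd.DataFrame()

    cols = ["gross", "erosion_total", "net", "acanthaster_reduction"]

    def summarise(sub: pd.DataFrame, island: str, habitat: str) -> dict:
        row: dict = {"island": island, "habitat": habitat, "n_sites": len(sub)}
        degenerate = len(sub) < 2
        for c in cols:
            row[f"{c}_mean"] = sub[c].mean()
            row[f"{c}_sd"] = 0.0 if degenerate else sub[c].std(ddof=1)
        row["sd_degenerate"] = degenerate
        return row

    rows = []
    for island, idf in df.groupby("island", sort=True):
        if include_island_totals:
            rows.append(summarise(idf, str(island), "combined"))
        for habitat, hdf in idf.groupby("habitat", sort=True):
            rows.append(summarise(hdf, str(island), str(habitat)))
    if include_cross_island and df["island"].nunique() > 1:
        for habitat, hdf in df.groupby("habitat", sort=True):
            if hdf["island"].nunique() > 1:
                rows.append(summarise(hdf, "all", str(habitat)))
    return pd.DataFrame(rows)


def species_contributions(
    budgets: Sequence[CarbonateBudget], *, include_ca: bool = False
) -> pd.DataFrame:
    """Ranked cumulative per-taxon share of summed gross production.

    Returns taxa sorted by their summed contribution with ``share_pct`` and
    ``cumulative_pct`` columns (summing to 100). With ``include_ca`` the
    rugosity-scaled coralline-algae production enters as a pseudo-taxon.
    """
    totals: dict[str, float] = {}
    for b in budgets:
        for taxon, v in b.per_taxon_gross.items():
            totals[taxon] = totals.get(taxon, 0.0) + v
        if include_ca:
            ca = b.gross - sum(b.per_taxon_gross.values())
            totals["coralline_algae"] = totals.get("coralline_algae", 0.0) + ca
    df = pd.DataFrame(
        {"taxon": list(totals), "production": list(totals.values())}
    ).sort_values("production", ascending=False, ignore_index=True)
    grand = df["production"].sum()
    if grand > 0:
        df["share_pct"] = 100.0 * df["production"] / grand
    else:
        df["share_pct"] = 0.0
    df["cumulative_pct"] = df["share_pct"].cumsum()
    return df
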