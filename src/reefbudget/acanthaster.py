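"""Crown-of-thorns sea star (*Acanthaster solaris*) consumption model.

The reduction in gross carbonate production by observed sea stars combines a
Holling type-II functional response with a per-transect consumption rate:

* attack rate  a = active_hours / (pi * ((100 - R + eps)/10 / 2)^2) / speed,
  where R is live coral cover (%): (100-R)/10 approximates the mean distance
  (m) between corals along a 10 m transect, the sea star searches a circle
  with that diameter, and ``speed`` (m d^-1) converts area to encounter rate;
* ingestion rate  RI = a R / (1 + a h R) * rescale, a saturating type-II
  response with handling time h (days per colony) rescaled to match observed
  consumption;
* per-transect consumption  tc = (count / n_transects) * con * D * 10 * 365,
  with con the area consumed per sea star per day (m^2 d^-1) and D the mean
  skeletal density (g cm^-3);
* site reduction = tc * RI / belt_area, clamped so sea stars can at most
  zero the site's gross production.

The quantities are an empirical recipe reproduced exactly as published (the
intermediate units are heterogeneous by construction); every constant is a
parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, Field

from .survey import SiteCover, SiteSurvey

__all__ = [
    "AcanthasterParams",
    "AcanthasterImpact",
    "DensityThreshold",
    "attack_rate",
    "ingestion_rate",
    "transect_consumption",
    "acanthaster_reduction",
    "density_threshold",
]


class AcanthasterParams(BaseModel):
    """Constants of the consumption model (all strictly positive except epsilon)."""

    model_config = ConfigDict(extra="forbid")

    con: float = Field(default=0.01, gt=0, description="m^2 consumed per sea star per day")
    handling_time: float = Field(default=3.5, gt=0, description="days per coral colony")
    speed: float = Field(default=504.0, gt=0, description="movement speed, m per day")
    active_hours: float = Field(default=12.0, gt=0, description="predatory hours per day")
    rescale: float = Field(default=4.53, gt=0, description="ingestion-rate rescaling")
    belt_area: float = Field(default=50.0, gt=0, description="belt area per transect, m^2")
    epsilon: float = Field(default=1e-10, ge=0, description="guard against zero area at R=100")
    outbreak_density_ha: float = Field(
        default=30.0, gt=0, description="sea stars per hectare flagging an outbreak"
    )


@dataclass
class AcanthasterImpact:
    """Site-level effect of the observed sea stars."""

    reduction: float  # kg CaCO3 m^-2 yr^-1, clamped at the site's gross production
    raw_reduction: float  # pre-clamp value
    density_per_300m2: float  # sea stars per 300 m^2 of belt
    density_per_ha: float
    outbreak_flag: bool


def attack_rate(R: float, params: AcanthasterParams | None = None) -> float:
    """Attack rate from live coral cover R (%).

    The mean inter-coral distance (100 - R + eps)/10 m is treated as the
    diameter of the circle a sea star must search; active hours divided by
    that area and by movement speed give the rate. Strictly increasing in R;
    the small epsilon keeps the value finite at R = 100.
    """
    p = params or AcanthasterParams()
    if not 0.0 <= R <= 100.0:
        raise ValueError(f"live coral cover R must be in [0, 100], got {R}")
    radius = ((100.0 - R + p.epsilon) / 10.0) / 2.0
    return p.active_hours / (radius**2 * math.pi) / p.speed


def ingestion_rate(R: float, a: float, params: AcanthasterParams | None = None) -> float:
    """Holling type-II ingestion rate of coral cover R at attack rate a."""
    p = params or AcanthasterParams()
    if R < 0 or a < 0:
        raise ValueError("R and a must be >= 0")
    return (a * R / (1.0 + a * p.handling_time * R)) * p.rescale


def transect_consumption(
    acanthaster_count: int,
    n_transects: int,
    mean_coral_density: float,
    params: AcanthasterParams | None = None,
) -> float:
    """Per-transect consumption rate tc from the site's total sea-star count."""
    p = params or AcanthasterParams()
    if n_transects < 1:
        raise ValueError("n_transects must be >= 1")
    if acanthaster_count < 0:
        raise ValueError("acanthaster_count must be >= 0")
    if mean_coral_density < 0:
        raise ValueError("mean coral density must be >= 0")
    per_transect = acanthaster_count / n_transects
    return per_transect * p.con * mean_coral_density * 10.0 * 365.0


def acanthaster_reduction(
    survey: SiteSurvey,
    cover: SiteCover,
    gross: float,
    params: AcanthasterParams | None = None,
) -> AcanthasterImpact:
    """Reduction in gross production caused by the site's observed sea stars.

    The raw reduction tc * RI / belt_area is clamped at the site's gross
    production: predation can at most net the gross to zero. The outbreak
    flag compares the observed density over the total belt area against the
    conventional outbreak density (30 ha^-1).
    """
    p = params or AcanthasterParams()
    if gross < 0:
        raise ValueError("gross production must be >= 0")
    a = attack_rate(cover.live_coral_cover, p)
    ri = ingestion_rate(cover.live_coral_cover, a, p)
    tc = transect_consumption(
        survey.acanthaster_count, survey.n_transects, cover.mean_coral_density, p
    )
    raw = tc * ri / p.belt_area
    area = survey.acanthaster_area_m2
    density_ha = survey.acanthaster_count / area * 10_000.0
    return AcanthasterImpact(
        reduction=min(raw, gross),
        raw_reduction=raw,
        density_per_300m2=survey.acanthaster_count / area * 300.0,
        density_per_ha=density_ha,
        outbreak_flag=density_ha > p.outbreak_density_ha,
    )


@dataclass
class DensityThreshold:
    """Smallest sea-star load that zeroes a site's gross production."""

    count: int  # total count over the site's belts (n_transects x belt_area)
    count_per_100m2: float
    percent_of_cover: float  # 100 * (count per 100 m^2) / live coral cover R
    reduction_per_individual: float  # kg m^-2 yr^-1 per sea star


def density_threshold(
    R: float,
    gross: float,
    mean_coral_density: float,
    params: AcanthasterParams | None = None,
    *,
    n_transects: int = 6,
) -> DensityThreshold:
    """Smallest integer sea-star count whose reduction reaches gross production.

    The reduction is linear in the count (tc is linear in count; the
    ingestion rate is fixed once R is), so the threshold is the exact
    inversion  count* = ceil(gross / slope)  with
    slope = con * D * 3650 / n_transects * RI / belt_area. Degenerate inputs
    (no coral, no production, zero density) return a zero threshold with a
    warning: such a site has nothing for sea stars to remove.
    """
    p = params or AcanthasterParams()
    if R <= 0 or gross <= 0 or mean_coral_density <= 0:
        warnings.warn(
            "density_threshold on a degenerate site (R, gross or D is 0); "
            "returning a zero threshold",
            stacklevel=2,
        )
        return DensityThreshold(0, 0.0, 0.0, 0.0)
    a = attack_rate(R, p)
    ri = ingestion_rate(R, a, p)
    slope = (p.con * mean_coral_density * 10.0 * 365.0 / n_transects) * ri / p.belt_area
    count = math.ceil(gross / slope - 1e-12)
    total_area = n_transects * p.belt_area
    per_100 = count / total_area * 100.0
    return DensityThreshold(
        count=count,
        count_per_100m2=per_100,
        percent_of_cover=100.0 * per_100 / R,
        reduction_per_individual=slope,
    )
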