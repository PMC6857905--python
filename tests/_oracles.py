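"""Independent spreadsheet-style re-implementations of the budget arithmetic.

These deliberately share no code with the package: plain loops and literals
transcribing the published equations row by row, used to cross-check the
module pipeline.
"""

import math

NON_CORAL = {
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


def oracle_coral_calcification(covers, rugosity, traits):
    """covers: taxon -> percent; traits: TraitTable. Returns kg m^-2 yr^-1."""
    total = 0.0
    for taxon, x in covers.items():
        t = traits[taxon]
        total += (t.morphology_m * x / 100.0) * t.density_d * t.growth_g * 10.0
    return rugosity * total


def oracle_ca(pca):
    return 0.018 * pca * 10.0


def oracle_bite_volume(length):
    return math.exp(1.32 + 0.06 * length) / 1000.0


def oracle_scar_proportion(length):
    return 1.0 / (1.0 + math.exp(-(-2.46 + 0.089 * length)))


def oracle_bite_rate(length, brc, reeftime=9.0):
    raw = 60.0 * ((4.31 + brc - 0.36) - 0.045 * reeftime * length)
    return raw if raw > 0 else 0.0


def oracle_parrotfish(fish_rows, D, area):
    """fish_rows: list of (length, brc)."""
    s = 0.0
    for length, brc in fish_rows:
        s += (
            oracle_bite_volume(length)
            * oracle_scar_proportion(length)
            * oracle_bite_rate(length, brc)
        )
    return s * D * 365.0 * 0.001 / area


def oracle_urchin_individual(group, diameter):
    if group == "Diadema":
        return 0.000001 * diameter**3.42 * 0.365 * 0.57
    if group == "Echinometra":
        return 0.0004 * diameter**1.98 * 0.365 * 0.57
    if group == "Other":
        return 0.0001 * diameter**2.32 * 0.365 * 0.57
    raise ValueError(group)


def oracle_urchin(urchin_rows, area):
    return sum(oracle_urchin_individual(g, d) for g, d in urchin_rows) / area


def oracle_macroboring(plamc):
    return plamc * 10.0


def oracle_attack_rate(R, epsilon=1e-10):
    return 12.0 / ((((100.0 - R + epsilon) / 10.0) / 2.0) ** 2 * math.pi) / 504.0


def oracle_ingestion(R, a, h=3.5):
    return (a * R / (1.0 + a * h * R)) * 4.53


def oracle_tc(count, n_transects, D):
    return (count / n_transects) * 0.01 * D * 10.0 * 365.0


def oracle_acanthaster_reduction(count, n_transects, R, D, gross):
    a = oracle_attack_rate(R)
    ri = oracle_ingestion(R, a)
    raw = oracle_tc(count, n_transects, D) * ri / 50.0
    return min(raw, gross), raw


def oracle_site_cover(survey):
    """taxon -> percent cover averaged across transects; and mean rugosity."""
    n = len(survey.transects)
    cover = {}
    for tr in survey.transects:
        per = {}
        for seg in tr.segments:
            per[seg.taxon] = per.get(seg.taxon, 0.0) + seg.intercept_length
        for t, length in per.items():
            cover[t] = cover.get(t, 0.0) + 100.0 * length / tr.contour_length / n
    rug = sum(tr.contour_length / tr.planar_length for tr in survey.transects) / n
    return cover, rug


def oracle_site_budget(survey, traits):
    """Full per-site budget from scratch. Returns a dict of components."""
    cover, rug = oracle_site_cover(survey)
    coral = {t: x for t, x in cover.items() if t not in NON_CORAL}
    R = sum(coral.values())
    D = (
        sum(x * traits[t].density_d for t, x in coral.items()) / R if R > 0 else 0.0
    )
    pca = cover.get("coralline_algae", 0.0) / 100.0
    plamc = cover.get("macroborer", 0.0) / 100.0

    gross = oracle_coral_calcification(coral, rug, traits) + rug * oracle_ca(pca)
    sediment = 0.4 if survey.sediment_regime == "normal" else -0.4

    fish_rows = []
    for f in survey.fish:
        brc = traits[f.species].brc if f.species in traits else None
        fish_rows.append((f.length, 20.0 if brc is None else brc))
    parrot = oracle_parrotfish(fish_rows, D, survey.fish_area_m2)
    urch = oracle_urchin(
        [(u.group, u.test_diameter) for u in survey.urchins], survey.urchin_area_m2
    )
    macro = oracle_macroboring(plamc)
    erosion = parrot + urch + macro

    reduction, raw = oracle_acanthaster_reduction(
        survey.acanthaster_count, len(survey.transects), R, D, gross
    )
    net = gross + sediment - erosion
    return {
        "gross": gross,
        "sedimentation": sediment,
        "erosion_parrotfish": parrot,
        "erosion_urchin": urch,
        "erosion_macroboring": macro,
        "erosion_total": erosion,
        "acanthaster_reduction": reduction,
        "acanthaster_raw": raw,
        "net": net,
        "net_with_acanthaster": net - reduction,
    }
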