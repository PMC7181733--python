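"""Length–weight biomass construction and reef-year summaries.

Fish counts are converted to mass with the allometry W = a·Lᵇ (g, cm),
summed within each 7 m-radius point count (~154 m²), scaled to kg ha⁻¹
(1 g m⁻² = 10 kg ha⁻¹), and averaged over replicates to one row per
surveyed reef-year. Herbivore biomass pools grazers, scrapers/excavators
and macroalgal browsers; carnivore biomass pools piscivores and mixed-diet
feeders. Richness is the number of distinct species per replicate
(a density of species per ~154 m², not a site-pooled count).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .survey_io import (
    BENTHIC_CATEGORIES,
    CARNIVORE_GROUPS,
    HERBIVORE_GROUPS,
    TROPHIC_GROUPS,
    SurveyTables,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Radius of a replicate point count (m) and derived survey area (m²).
POINT_COUNT_RADIUS_M = 7.0
POINT_COUNT_AREA_M2 = math.pi * POINT_COUNT_RADIUS_M**2  # ~153.94 m²
#: 1 g m⁻² equals 10 kg ha⁻¹.
G_PER_M2_TO_KG_PER_HA = 10.0

GROUP_BIOMASS_COLUMNS = [f"biomass_{g}" for g in TROPHIC_GROUPS]

SUMMARY_COLUMNS = [
    "reef_id",
    "year",
    "n_replicates",
    "total_biomass",
    *GROUP_BIOMASS_COLUMNS,
    "carnivore_biomass",
    "herbivore_biomass",
    "richness",
    *BENTHIC_CATEGORIES,
    "complexity_mean",
]


def length_weight_mass(length_cm, lw_a, lw_b):
    """Mass in grams from total length via W = a·Lᵇ. Vectorized.

    Raises
    ------
    ValueError
        If any length or coefficient ``a`` is non-positive.
    """
    length_cm = np.asarray(length_cm, dtype=float)
    lw_a = np.asarray(lw_a, dtype=float)
    if np.any(length_cm <= 0):
        raise ValueError("length_cm must be > 0")
    if np.any(lw_a <= 0):
        raise ValueError("lw_a must be > 0")
    return lw_a * length_cm ** np.asarray(lw_b, dtype=float)


def _areal(grams: float | np.ndarray, radius_m: float) -> float | np.ndarray:
    area = math.pi * radius_m**2
    return grams / area * G_PER_M2_TO_KG_PER_HA


def replicate_biomass(fish: pd.DataFrame, traits: pd.DataFrame, radius_m: float = POINT_COUNT_RADIUS_M) -> dict[str, float]:
    """Total and per-trophic-group biomass (kg ha⁻¹) of one replicate.

    ``fish`` holds the observations of a single point count. Returns a dict
    with key ``total`` and one key per trophic group; groups partition the
    total. An empty replicate yields zeros.
    """
    out = {"total": 0.0, **{g: 0.0 for g in TROPHIC_GROUPS}}
    if len(fish) == 0:
        return out
    merged = fish.merge(traits, on="species_id", how="left", validate="many_to_one")
    if merged["trophic_group"].isna().any():
        orphans = sorted(set(merged.loc[merged["trophic_group"].isna(), "species_id"]))
        raise ValidationError(f"species without trait rows: {orphans}")
    grams = merged["count"].to_numpy(float) * length_weight_mass(
        merged["length_cm"], merged["lw_a"], merged["lw_b"]
    )
    per_group = pd.Series(grams).groupby(merged["trophic_group"].to_numpy()).sum()
    for g, v in per_group.items():
        out[g] = float(_areal(v, radius_m))
    out["total"] = float(sum(out[g] for g in TROPHIC_GROUPS))
    return out


def replicate_richness(fish: pd.DataFrame) -> int:
    """Number of distinct species observed in one replicate point count."""
    if len(fish) == 0:
        return 0
    return int(fish.loc[fish["count"] >= 1, "species_id"].nunique())


def summarize_reef_years(tables: SurveyTables, radius_m: float = POINT_COUNT_RADIUS_M) -> pd.DataFrame:
    """One row per surveyed reef-year: replicate means of biomass, richness and benthos.

    The replicate registry is the union of replicates present in the fish
    and benthic tables; a replicate with benthic data but no fish counts
    contributes zero biomass and richness. Reef-years with no replicates at
    all are excluded (with a warning).
    """
    fish, benthic, traits = tables.fish, tables.benthic, tables.traits

    merged = fish.merge(traits, on="species_id", how="left", validate="many_to_one")
    if merged["trophic_group"].isna().any():
        orphans = sorted(set(merged.loc[merged["trophic_group"].isna(), "species_id"]))
        raise ValidationError(f"species without trait rows: {orphans}")
    merged["grams"] = merged["count"].to_numpy(float) * length_weight_mass(
        merged["length_cm"], merged["lw_a"], merged["lw_b"]
    )

    keys = ["reef_id", "year", "replicate"]
    registry = pd.concat([fish[keys], benthic[keys]]).drop_duplicates().reset_index(drop=True)

    # replicate-level biomass per trophic group (kg/ha), zero-filled on the registry
    by_group = (
        merged.groupby(keys + ["trophic_group"], observed=True)["grams"].sum().unstack("trophic_group")
    )
    by_group = by_group.reindex(columns=list(TROPHIC_GROUPS), fill_value=0.0)
    by_group = registry.join(by_group, on=keys).fillna(0.0)
    area = math.pi * radius_m**2
    for g in TROPHIC_GROUPS:
        by_group[g] = by_group[g] / area * G_PER_M2_TO_KG_PER_HA
    by_group["total"] = by_group[list(TROPHIC_GROUPS)].sum(axis=1)

    richness = merged.groupby(keys)["species_id"].nunique()
    by_group["richness"] = registry.join(richness.rename("richness"), on=keys)["richness"].fillna(0.0)

    rep_means = by_group.groupby(["reef_id", "year"]).agg(
        n_replicates=("replicate", "size"),
        total_biomass=("total", "mean"),
        **{f"biomass_{g}": (g, "mean") for g in TROPHIC_GROUPS},
        richness=("richness", "mean"),
    )

    benthic_means = benthic.groupby(["reef_id", "year"])[list(BENTHIC_CATEGORIES) + ["complexity"]].mean()
    benthic_means = benthic_means.rename(columns={"complexity": "complexity_mean"})

    out = rep_means.join(benthic_means, how="left").reset_index()
    out["carnivore_biomass"] = sum(out[f"biomass_{g}"] for g in CARNIVORE_GROUPS)
    out["herbivore_biomass"] = sum(out[f"biomass_{g}"] for g in HERBIVORE_GROUPS)
    out = out[SUMMARY_COLUMNS].sort_values(["reef_id", "year"]).reset_index(drop=True)

    surveyed = {(r, y) for r, y in zip(registry["reef_id"], registry["year"])}
    expected = {(r, y) for r in tables.sites["reef_id"] for y in out["year"].unique()}
    missing = expected - surveyed
    if missing:
        logger.warning("reef-years with zero replicates excluded: %s", sorted(missing))
    return out
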