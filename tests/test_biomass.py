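import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefmpa import biomass
from reefmpa.biomass import (
    POINT_COUNT_AREA_M2,
    length_weight_mass,
    replicate_biomass,
    replicate_richness,
    summarize_reef_years,
)
from reefmpa.survey_io import CARNIVORE_GROUPS, HERBIVORE_GROUPS, TROPHIC_GROUPS, SurveyTables


def test_length_weight_cube_law():
    assert length_weight_mass(10.0, 0.01, 3.0) == pytest.approx(10.0)


def test_length_weight_unit_length_returns_a():
    for b in (2.8, 3.0, 3.2):
        assert length_weight_mass(1.0, 0.0234, b) == pytest.approx(0.0234)


def test_length_weight_matches_independent_power_law():
    # oracle: a * exp(b * ln L) evaluated directly
    expected = 0.0137 * math.exp(3.04 * math.log(25.0))
    assert length_weight_mass(25.0, 0.0137, 3.04) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("length,a", [(-1.0, 0.01), (0.0, 0.01), (10.0, -0.5), (10.0, 0.0)])
def test_length_weight_rejects_non_positive_inputs(length, a):
    with pytest.raises(ValueError):
        length_weight_mass(length, a, 3.0)


def _one_fish(mass_g: float):
    """A single fish of exactly `mass_g` grams (L=1 so mass = lw_a)."""
    fish = pd.DataFrame(
        {"reef_id": ["r"], "year": [1994], "replicate": [1], "species_id": ["s"], "count": [1], "length_cm": [1.0]}
    )
    traits = pd.DataFrame(
        {"species_id": ["s"], "family": ["f"], "trophic_group": ["grazer"], "lw_a": [mass_g], "lw_b": [3.0]}
    )
    return fish, traits


def test_one_areal_gram_is_ten_kg_per_hectare():
    fish, traits = _one_fish(math.pi * 49.0)  # 1 g per m^2 over the 7m point count
    out = replicate_biomass(fish, traits)
    assert out["total"] == pytest.approx(10.0)
    assert out["grazer"] == pytest.approx(10.0)


def test_empty_replicate_is_all_zero():
    fish, traits = _one_fish(1.0)
    out = replicate_biomass(fish.iloc[:0], traits)
    assert out["total"] == 0.0
    assert all(out[g] == 0.0 for g in TROPHIC_GROUPS)


def test_groups_partition_total(tables):
    rep = tables.fish[(tables.fish.reef_id == "reef01") & (tables.fish.year == 1994) & (tables.fish.replicate == 1)]
    out = replicate_biomass(rep, tables.traits)
    assert out["total"] == pytest.approx(sum(out[g] for g in TROPHIC_GROUPS), rel=1e-12)


@given(factor=st.integers(min_value=2, max_value=5))
@settings(max_examples=10, deadline=None)
def test_replicate_biomass_is_linear_in_counts(factor):
    fish = pd.DataFrame(
        {
            "reef_id": ["r"] * 3,
            "year": [1994] * 3,
            "replicate": [1] * 3,
            "species_id": ["s1", "s2", "s1"],
            "count": [2, 3, 1],
            "length_cm": [10.0, 20.0, 15.0],
        }
    )
    traits = pd.DataFrame(
        {
            "species_id": ["s1", "s2"],
            "family": ["f", "f"],
            "trophic_group": ["grazer", "piscivore"],
            "lw_a": [0.01, 0.02],
            "lw_b": [3.0, 2.9],
        }
    )
    base = replicate_biomass(fish, traits)
    scaled = replicate_biomass(fish.assign(count=fish["count"] * factor), traits)
    for key in base:
        assert scaled[key] == pytest.approx(factor * base[key], rel=1e-12)


def test_biomass_invariant_to_splitting_count_records():
    fish = pd.DataFrame(
        {"reef_id": ["r"], "year": [1994], "replicate": [1], "species_id": ["s1"], "count": [2], "length_cm": [14.0]}
    )
    split = pd.concat([fish.assign(count=1)] * 2, ignore_index=True)
    traits = pd.DataFrame(
        {"species_id": ["s1"], "family": ["f"], "trophic_group": ["browser"], "lw_a": [0.01], "lw_b": [3.0]}
    )
    assert replicate_biomass(fish, traits) == replicate_biomass(split, traits)


def test_replicate_richness_counts_distinct_species():
    fish = pd.DataFrame(
        {
            "reef_id": ["r"] * 3,
            "year": [1994] * 3,
            "replicate": [1] * 3,
            "species_id": ["A", "B", "A"],
            "count": [2, 1, 3],
            "length_cm": [10.0, 10.0, 12.0],
        }
    )
    assert replicate_richness(fish) == 2
    assert replicate_richness(fish.iloc[:0]) == 0


def test_summarize_matches_brute_force_aggregation(tables, summaries):
    """Independent oracle: per-replicate loop with explicit mass arithmetic."""
    reef, year = "reef03", 2008
    traits = tables.traits.set_index("species_id")
    fish = tables.fish[(tables.fish.reef_id == reef) & (tables.fish.year == year)]
    benthic = tables.benthic[(tables.benthic.reef_id == reef) & (tables.benthic.year == year)]
    totals, richness = [], []
    for rep in sorted(benthic["replicate"].unique()):
        sub = fish[fish.replicate == rep]
        grams = 0.0
        for row in sub.itertuples():
            tr = traits.loc[row.species_id]
            grams += row.count * tr.lw_a * row.length_cm**tr.lw_b
        totals.append(grams / POINT_COUNT_AREA_M2 * 10.0)
        richness.append(sub["species_id"].nunique())
    got = summaries[(summaries.reef_id == reef) & (summaries.year == year)].iloc[0]
    assert got["total_biomass"] == pytest.approx(np.mean(totals), rel=1e-9)
    assert got["richness"] == pytest.approx(np.mean(richness), rel=1e-9)
    assert got["hard_coral"] == pytest.approx(benthic["hard_coral"].mean(), rel=1e-9)
    assert got["n_replicates"] == len(totals)


def test_summary_groups_partition_total_and_pools(summaries):
    total = sum(summaries[f"biomass_{g}"] for g in TROPHIC_GROUPS)
    assert np.allclose(summaries["total_biomass"], total, rtol=1e-9)
    assert np.allclose(
        summaries["carnivore_biomass"], sum(summaries[f"biomass_{g}"] for g in CARNIVORE_GROUPS), rtol=1e-9
    )
    assert np.allclose(
        summaries["herbivore_biomass"], sum(summaries[f"biomass_{g}"] for g in HERBIVORE_GROUPS), rtol=1e-9
    )
    assert (summaries["total_biomass"] >= 0).all()


def test_summaries_invariant_to_row_permutation(tables, summaries):
    shuffled = SurveyTables(
        sites=tables.sites,
        fish=tables.fish.sample(frac=1.0, random_state=7).reset_index(drop=True),
        benthic=tables.benthic.sample(frac=1.0, random_state=8).reset_index(drop=True),
        traits=tables.traits,
    )
    again = summarize_reef_years(shuffled)
    pd.testing.assert_frame_equal(again, summaries)


def test_mean_over_two_replicates():
    fish = pd.DataFrame(
        {
            "reef_id": ["r", "r"],
            "year": [1994, 1994],
            "replicate": [1, 2],
            "species_id": ["s1", "s1"],
            "count": [1, 2],
            "length_cm": [1.0, 1.0],
        }
    )
    grams = 100 * POINT_COUNT_AREA_M2 / 10.0  # each fish worth 100 kg/ha
    traits = pd.DataFrame(
        {"species_id": ["s1"], "family": ["f"], "trophic_group": ["grazer"], "lw_a": [grams], "lw_b": [3.0]}
    )
    benthic = pd.DataFrame(
        {
            "reef_id": ["r", "r"],
            "year": [1994, 1994],
            "replicate": [1, 2],
            "hard_coral": [40.0, 60.0],
            "soft_coral": [0.0, 0.0],
            "macroalgae": [0.0, 0.0],
            "sand": [0.0, 0.0],
            "rubble": [0.0, 0.0],
            "rock": [0.0, 0.0],
            "complexity": [3, 4],
        }
    )
    sites = pd.DataFrame({"reef_id": ["r"], "management": ["fished"], "regime": ["unassigned"]})
    out = summarize_reef_years(SurveyTables(sites=sites, fish=fish, benthic=benthic, traits=traits))
    assert out.loc[0, "total_biomass"] == pytest.approx(150.0)  # mean of 100 and 200
    assert out.loc[0, "hard_coral"] == pytest.approx(50.0)
    assert out.loc[0, "complexity_mean"] == pytest.approx(3.5)
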