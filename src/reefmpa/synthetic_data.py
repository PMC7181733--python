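"""Synthetic UVC survey generator with known ground truth.

Emulates the monitoring design the pipeline targets: 21 reefs (9 protected,
12 fished; 7 fished-recovering / 5 protected-recovering / 5 fished-shifted /
4 protected-shifted), survey years {1994, 2005, 2008, 2011, 2014}, 8–16
replicate 7 m-radius point counts per reef-year, and 134 species in 16
families across seven trophic groups.

The generator is calibrated so that *expected* replicate-level biomass and
richness equal the ground-truth targets exactly:

* each species is present in a replicate with probability p (group-wise),
  and, when present, contributes a count of 1 + an overdispersed
  (gamma-mixed Poisson) extra count, so expected richness is Σ p exactly;
* group presence and conditional count means are solved from the target
  group biomass via each species' exact expected mass under its discrete
  length distribution (richness is water-filled across groups subject to
  the biomass-feasibility cap of each group).

Ground truth defaults follow the study conditions: a 1.75× reserve
multiplier on every trophic group pre-bleaching (75% biomass effect), +10
species per replicate and +15 percentage points of coral cover in
reserves, post-bleaching total-biomass trends of 7/4/2/0% of the
pre-bleaching level per year (reaching +79/52/38/0% by 2014) and richness
trends of 3/2/0.9/−0.2% per year, and regime-specific benthic
trajectories (coral recovery vs. macroalgal takeover).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .biomass import POINT_COUNT_AREA_M2, G_PER_M2_TO_KG_PER_HA
from .survey_io import SurveyTables, TROPHIC_GROUPS, validate_tables

SURVEY_YEARS = (1994, 2005, 2008, 2011, 2014)
POST_YEAR_CENTER = 2009.5  # mean of the post-bleaching survey years

#: species per trophic group (sums to 134) and group-typical lengths (cm)
GROUP_SPECIES = {
    "piscivore": 18,
    "mixed_diet": 30,
    "scraper_excavator": 20,
    "grazer": 24,
    "browser": 8,
    "planktivore": 22,
    "corallivore": 12,
}
GROUP_TYPICAL_LENGTH = {
    "piscivore": 24.0,
    "mixed_diet": 17.0,
    "scraper_excavator": 18.0,
    "grazer": 12.0,
    "browser": 16.0,
    "planktivore": 8.0,
    "corallivore": 7.0,
}

#: pre-bleaching fished-reef group biomass (kg/ha); protected carnivore and
#: herbivore pools then equal 259 and 266 kg/ha under the 1.75 multiplier
PRE_FISHED_BIOMASS = {
    "piscivore": 65.0,
    "mixed_diet": 83.0,
    "scraper_excavator": 75.0,
    "grazer": 57.0,
    "browser": 20.0,
    "planktivore": 25.0,
    "corallivore": 5.0,
}

_DEFAULT_DESIGN = (("fished", "recovering", 7), ("protected", "recovering", 5),
                   ("fished", "regime_shifted", 5), ("protected", "regime_shifted", 4))

_LENGTH_FACTORS = np.array([0.8, 0.9, 1.0, 1.1, 1.2])
_LENGTH_PROBS = np.array([0.1, 0.2, 0.4, 0.2, 0.1])


def _default_post_shares():
    # regime-specific trophic composition post-bleaching (fractions of total)
    return {
        "recovering": {
            "piscivore": 0.10, "mixed_diet": 0.26, "scraper_excavator": 0.32,
            "grazer": 0.18, "browser": 0.10, "planktivore": 0.03, "corallivore": 0.01,
        },
        "regime_shifted": {
            "piscivore": 0.08, "mixed_diet": 0.25, "scraper_excavator": 0.20,
            "grazer": 0.15, "browser": 0.28, "planktivore": 0.03, "corallivore": 0.01,
        },
    }


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a simulated monitoring campaign.

    Biomass trajectories are percent deviations from the reef's
    pre-bleaching level, linear in year with ``slope`` %/yr about the
    post-bleaching midpoint (2009.5); keys are (habitat, management).
    """

    pre_multiplier: dict = field(default_factory=lambda: {g: 1.75 for g in TROPHIC_GROUPS})
    pre_fished_biomass: dict = field(default_factory=lambda: dict(PRE_FISHED_BIOMASS))
    post_shares: dict = field(default_factory=_default_post_shares)
    biomass_slope: dict = field(default_factory=lambda: {
        ("recovering", "fished"): 7.0, ("recovering", "protected"): 4.0,
        ("regime_shifted", "fished"): 2.0, ("regime_shifted", "protected"): 0.0,
    })
    biomass_pct_mid: dict = field(default_factory=lambda: {
        ("recovering", "fished"): 47.5, ("recovering", "protected"): 34.0,
        ("regime_shifted", "fished"): 29.0, ("regime_shifted", "protected"): 0.0,
    })
    richness_pre: dict = field(default_factory=lambda: {"fished": 25.0, "protected": 35.0})
    richness_slope: dict = field(default_factory=lambda: {
        ("recovering", "fished"): 3.0, ("recovering", "protected"): 2.0,
        ("regime_shifted", "fished"): 0.9, ("regime_shifted", "protected"): -0.2,
    })
    richness_pct_mid: dict = field(default_factory=lambda: {
        ("recovering", "fished"): -5.0, ("recovering", "protected"): -12.0,
        ("regime_shifted", "fished"): -25.0, ("regime_shifted", "protected"): -25.0,
    })
    coral_pre: dict = field(default_factory=lambda: {"fished": 28.0, "protected": 43.0})
    replicate_range: tuple = (8, 16)
    overdispersion: float = 0.5
    reef_sigma: float = 0.12
    richness_reef_sigma: float = 0.05
    years: tuple = SURVEY_YEARS
    seed: int | None = None

    @classmethod
    def null(cls) -> "SyntheticTruth":
        """No reserve effect, no trends: every contrast's truth is zero."""
        return cls(
            pre_multiplier={g: 1.0 for g in TROPHIC_GROUPS},
            biomass_slope={k: 0.0 for k in cls().biomass_slope},
            biomass_pct_mid={k: 0.0 for k in cls().biomass_pct_mid},
            richness_pre={"fished": 25.0, "protected": 25.0},
            richness_slope={k: 0.0 for k in cls().richness_slope},
            richness_pct_mid={k: 0.0 for k in cls().richness_pct_mid},
            coral_pre={"fished": 28.0, "protected": 28.0},
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("biomass_slope", "biomass_pct_mid", "richness_slope", "richness_pct_mid"):
            d[key] = {f"{h}:{m}": v for (h, m), v in d[key].items()}
        return d


def generate_traits(n_species: int = 134, n_families: int = 16, seed: int = 0) -> pd.DataFrame:
    """Species trait table: family, trophic group, length–weight coefficients.

    Groups are allocated proportionally to the default group composition
    (all seven represented); lw_a ~ U[0.005, 0.05], lw_b ~ U[2.8, 3.2].
    """
    if n_species < n_families:
        raise ValueError("need at least one species per family")
    rng = np.random.default_rng(seed)
    counts = np.array(list(GROUP_SPECIES.values()), float)
    counts = np.maximum(1, np.round(counts / counts.sum() * n_species).astype(int))
    while counts.sum() > n_species:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_species:
        counts[np.argmin(counts)] += 1
    groups = np.repeat(list(GROUP_SPECIES.keys()), counts)
    families = np.array([f"fam{i + 1:02d}" for i in range(n_families)])
    fam = np.concatenate([families, rng.choice(families, size=n_species - n_families)])
    return pd.DataFrame(
        {
            "species_id": [f"sp{i + 1:03d}" for i in range(n_species)],
            "family": fam,
            "trophic_group": groups,
            "lw_a": np.round(rng.uniform(0.005, 0.05, n_species), 6),
            "lw_b": np.round(rng.uniform(2.8, 3.2, n_species), 4),
        }
    )


def generate_design(counts=_DEFAULT_DESIGN) -> pd.DataFrame:
    """21-reef site table with ground-truth regime labels (7/5/5/4 design)."""
    rows = []
    i = 0
    for management, regime, n in counts:
        for _ in range(n):
            i += 1
            rows.append({"reef_id": f"reef{i:02d}", "management": management, "regime": regime})
    return pd.DataFrame(rows)


def _expected_mass(traits: pd.DataFrame, rng: np.random.Generator):
    """Per-species length grids and exact expected mass (g) per observation."""
    typical = traits["trophic_group"].map(GROUP_TYPICAL_LENGTH).to_numpy(float)
    l_s = np.maximum(3.0, typical * np.exp(rng.normal(0.0, 0.15, len(traits))))
    length_grid = np.maximum(3.0, np.round(l_s[:, None] * _LENGTH_FACTORS[None, :]))
    a = traits["lw_a"].to_numpy(float)[:, None]
    b = traits["lw_b"].to_numpy(float)[:, None]
    e_mass = (_LENGTH_PROBS[None, :] * a * length_grid**b).sum(axis=1)
    return length_grid, e_mass


def _allocate_presence(r_target, grams_target, group_codes, e_mass, n_groups):
    """Water-fill per-group presence probabilities under biomass feasibility."""
    sum_emass = np.bincount(group_codes, weights=e_mass, minlength=n_groups)
    n_g = np.bincount(group_codes, minlength=n_groups).astype(float)
    p_max = np.minimum(0.95, grams_target / np.maximum(sum_emass, 1e-12))
    p = np.minimum(p_max, r_target / n_g.sum())
    for _ in range(25):
        deficit = r_target - float(n_g @ p)
        if deficit <= 1e-9:
            break
        slack = n_g * (p_max - p)
        total_slack = slack.sum()
        if total_slack <= 1e-12:
            break
        p = np.minimum(p_max, p + deficit * (slack / total_slack) / n_g)
    achieved = float(n_g @ p)
    if achieved < r_target * 0.95 - 0.5:
        raise ValueError(
            f"infeasible targets: richness {r_target:.1f} unreachable (max {achieved:.1f}) "
            "given the biomass targets"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_count = np.where(p > 0, grams_target / np.maximum(p * sum_emass, 1e-12), 1.0)
    return p, np.maximum(mean_count, 1.0)


def _reef_year_targets(truth: SyntheticTruth, management: str, regime: str, year: int):
    pre_b = {g: truth.pre_fished_biomass[g] * (truth.pre_multiplier[g] if management == "protected" else 1.0)
             for g in TROPHIC_GROUPS}
    total_pre = sum(pre_b.values())
    r_pre = truth.richness_pre[management]
    if year <= 1998:
        return pre_b, r_pre
    dt = year - POST_YEAR_CENTER
    pct = truth.biomass_pct_mid[(regime, management)] + truth.biomass_slope[(regime, management)] * dt
    total = total_pre * (1.0 + pct / 100.0)
    if total <= 0:
        raise ValueError(f"infeasible: negative expected biomass for {regime}/{management} in {year}")
    shares = truth.post_shares[regime]
    rpct = truth.richness_pct_mid[(regime, management)] + truth.richness_slope[(regime, management)] * dt
    return {g: shares[g] * total for g in TROPHIC_GROUPS}, r_pre * (1.0 + rpct / 100.0)


def _benthic_targets(truth: SyntheticTruth, management: str, regime: str, year: int):
    if year <= 1998:
        return {"hard_coral": truth.coral_pre[management], "soft_coral": 6.0, "macroalgae": 1.2, "complexity": 3.5}
    frac = (year - 2005) / 9.0
    if regime == "recovering":
        return {"hard_coral": 12.0 + 20.0 * frac, "soft_coral": 5.0, "macroalgae": 3.0, "complexity": 3.2}
    return {"hard_coral": 9.0 - 4.0 * frac, "soft_coral": 4.0, "macroalgae": 22.0 + 20.0 * frac, "complexity": 2.2}


def generate_surveys(truth: SyntheticTruth, design: pd.DataFrame, traits: pd.DataFrame, seed: int = 0) -> SurveyTables:
    """Simulate the full fish + benthic survey for a given design and traits.

    Expected replicate biomass and richness match the truth targets exactly;
    realized data carry negative-binomial count noise, discrete length
    variation, and lognormal reef-level heterogeneity.
    """
    ss = np.random.SeedSequence(seed)
    rng_attr, rng_reef, rng_obs = (np.random.default_rng(s) for s in ss.spawn(3))

    length_grid, e_mass = _expected_mass(traits, rng_attr)
    group_list = list(TROPHIC_GROUPS)
    group_codes = traits["trophic_group"].map({g: i for i, g in enumerate(group_list)}).to_numpy(int)
    n_groups = len(group_list)
    n_species = len(traits)
    species_ids = traits["species_id"].to_numpy()
    area_factor = POINT_COUNT_AREA_M2 / G_PER_M2_TO_KG_PER_HA  # kg/ha -> g per replicate

    eps_bio = np.exp(rng_reef.normal(0.0, truth.reef_sigma, len(design)))
    eps_rich = np.exp(rng_reef.normal(0.0, truth.richness_reef_sigma, len(design)))

    fish_rows, benthic_rows = [], []
    d = truth.overdispersion
    for ri, site in enumerate(design.itertuples(index=False)):
        for year in truth.years:
            b_targets, r_target = _reef_year_targets(truth, site.management, site.regime, year)
            grams_g = np.array([b_targets[g] for g in group_list]) * area_factor * eps_bio[ri]
            r_eff = min(r_target * eps_rich[ri], 0.9 * n_species)
            p_g, count_mean_g = _allocate_presence(r_eff, grams_g, group_codes, e_mass, n_groups)
            p_s, cmean_s = p_g[group_codes], count_mean_g[group_codes]

            n_reps = int(rng_obs.integers(truth.replicate_range[0], truth.replicate_range[1] + 1))
            present = rng_obs.random((n_reps, n_species)) < p_s[None, :]
            if d > 0:
                mix = rng_obs.gamma(1.0 / d, d, size=(n_reps, n_species))
            else:
                mix = np.ones((n_reps, n_species))
            counts = 1 + rng_obs.poisson((cmean_s[None, :] - 1.0) * mix)
            f_idx = rng_obs.choice(len(_LENGTH_FACTORS), size=(n_reps, n_species), p=_LENGTH_PROBS)
            reps, sp = np.nonzero(present)
            if len(reps):
                fish_rows.append(
                    pd.DataFrame(
                        {
                            "reef_id": site.reef_id,
                            "year": year,
                            "replicate": reps + 1,
                            "species_id": species_ids[sp],
                            "count": counts[reps, sp],
                            "length_cm": length_grid[sp, f_idx[reps, sp]],
                        }
                    )
                )
            bt = _benthic_targets(truth, site.management, site.regime, year)
            hard = np.clip(rng_obs.normal(bt["hard_coral"], 5.0, n_reps), 0.0, 100.0)
            soft = np.clip(rng_obs.normal(bt["soft_coral"], 2.0, n_reps), 0.0, 100.0)
            ma = np.clip(rng_obs.normal(bt["macroalgae"], 4.0, n_reps), 0.0, 100.0)
            tot3 = hard + soft + ma
            over = tot3 > 85.0
            scale = np.where(over, 85.0 / np.maximum(tot3, 1e-9), 1.0)
            hard, soft, ma = hard * scale, soft * scale, ma * scale
            fill = (100.0 - hard - soft - ma) * rng_obs.uniform(0.85, 0.95, n_reps)
            cx = np.clip(np.round(rng_obs.normal(bt["complexity"], 0.6, n_reps)), 0, 5).astype(int)
            benthic_rows.append(
                pd.DataFrame(
                    {
                        "reef_id": site.reef_id,
                        "year": year,
                        "replicate": np.arange(1, n_reps + 1),
                        "hard_coral": np.round(hard, 2),
                        "soft_coral": np.round(soft, 2),
                        "macroalgae": np.round(ma, 2),
                        "sand": np.round(fill * 0.45, 2),
                        "rubble": np.round(fill * 0.30, 2),
                        "rock": np.round(fill * 0.25, 2),
                        "complexity": cx,
                    }
                )
            )

    fish = pd.concat(fish_rows, ignore_index=True)
    benthic = pd.concat(benthic_rows, ignore_index=True)
    sites = design[["reef_id", "management"]].copy()
    sites["regime"] = "unassigned"
    tables = SurveyTables(sites=sites, fish=fish, benthic=benthic, traits=traits.copy())
    return validate_tables(tables)


def simulate_dataset(seed: int = 0, scenario: str = "study-default", truth: SyntheticTruth | None = None):
    """One-call simulation: returns (SurveyTables, truth metadata dict).

    ``scenario`` is ``"study-default"`` (the study conditions), ``"null"``
    (no effects anywhere) or ``"custom"`` with an explicit ``truth``.
    """
    if truth is None:
        if scenario == "study-default":
            truth = SyntheticTruth()
        elif scenario == "null":
            truth = SyntheticTruth.null()
        else:
            raise ValueError("scenario must be 'study-default', 'null', or pass truth= explicitly")
    truth.seed = seed
    design = generate_design()
    ss = np.random.SeedSequence(seed).spawn(2)
    traits = generate_traits(seed=int(ss[0].generate_state(1)[0] % 2**31))
    tables = generate_surveys(truth, design, traits, seed=int(ss[1].generate_state(1)[0] % 2**31))
    meta = {
        "scenario": scenario,
        "seed": seed,
        "truth": truth.to_dict(),
        "regimes": dict(zip(design["reef_id"], design["regime"])),
    }
    return tables, meta
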