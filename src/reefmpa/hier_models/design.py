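"""Design construction for the recovery and trophic models."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..regime import DISTURBANCE_YEAR

_RESPONSE_COLUMNS = {"biomass": "total_biomass", "richness": "richness"}


def center_years(years) -> np.ndarray:
    """Mean-center survey years (e.g. {2005, 2008, 2011, 2014} → ±4.5, ±1.5)."""
    years = np.asarray(years, float)
    return years - years.mean()


def _merged(summaries: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    df = summaries.merge(sites[["reef_id", "management", "regime"]], on="reef_id", validate="many_to_one")
    if (df["regime"] == "unassigned").any():
        bad = sorted(df.loc[df["regime"] == "unassigned", "reef_id"].unique())
        raise ValueError(f"sites must be regime-labelled before model fitting: {bad}")
    return df


def build_recovery_design(summaries: pd.DataFrame, sites: pd.DataFrame, response: str = "biomass") -> pd.DataFrame:
    """Observations for the Normal recovery model.

    One row per post-bleaching reef-year with:

    * ``y`` — the response minus the reef's own pre-bleaching (1994) value,
    * ``year_c`` — survey year mean-centered over the post-bleaching years
      present,
    * ``habitat`` / ``management`` — regime and protection labels,
    * ``pre_level`` — the reef's 1994 value, kept for percent rescaling.

    Raises if any reef lacks a pre-bleaching baseline.
    """
    col = _RESPONSE_COLUMNS[response]
    df = _merged(summaries, sites)
    pre = df[df["year"] <= DISTURBANCE_YEAR]
    post = df[df["year"] > DISTURBANCE_YEAR]
    baseline = pre.groupby("reef_id")[col].mean().rename("pre_level")
    missing = sorted(set(post["reef_id"]) - set(baseline.index))
    if missing:
        raise ValueError(f"reefs without a pre-bleaching baseline: {missing}")
    out = post.join(baseline, on="reef_id")
    years = np.sort(post["year"].unique())
    centered = dict(zip(years, center_years(years)))
    out = pd.DataFrame(
        {
            "reef_id": out["reef_id"],
            "year": out["year"],
            "year_c": out["year"].map(centered),
            "habitat": out["regime"],
            "management": out["management"],
            "y": out[col] - out["pre_level"],
            "pre_level": out["pre_level"],
        }
    ).reset_index(drop=True)
    if (out["pre_level"] <= 0).any():
        bad = sorted(out.loc[out["pre_level"] <= 0, "reef_id"].unique())
        raise ValueError(f"non-positive pre-bleaching levels for reefs: {bad}")
    return out


def build_trophic_design(summaries: pd.DataFrame, sites: pd.DataFrame, period: str = "pre") -> pd.DataFrame:
    """Long-format observations for the Gamma carnivore/herbivore models.

    One row per (reef-year, functional group) with ``y`` the group biomass
    in kg ha⁻¹ (strictly positive, Gamma support). ``period='pre'`` keeps
    pre-bleaching surveys only (management design); ``period='post'`` keeps
    post-bleaching surveys and adds centered year and habitat covariates.
    """
    if period not in ("pre", "post"):
        raise ValueError("period must be 'pre' or 'post'")
    df = _merged(summaries, sites)
    df = df[df["year"] <= DISTURBANCE_YEAR] if period == "pre" else df[df["year"] > DISTURBANCE_YEAR]
    if df.empty:
        raise ValueError(f"no {period}-bleaching reef-year summaries available")
    years = np.sort(df["year"].unique())
    centered = dict(zip(years, center_years(years)))
    long = df.melt(
        id_vars=["reef_id", "year", "management", "regime"],
        value_vars=["carnivore_biomass", "herbivore_biomass"],
        var_name="fg",
        value_name="y",
    )
    long["fg"] = long["fg"].str.replace("_biomass", "", regex=False)
    long["habitat"] = long["regime"]
    long["year_c"] = long["year"].map(centered) if period == "post" else 0.0
    if (long["y"] <= 0).any():
        bad = long.loc[long["y"] <= 0, ["reef_id", "year", "fg"]].to_records(index=False)
        raise ValueError(f"Gamma likelihood requires positive biomass; zero rows: {list(bad)[:5]}")
    return long[["reef_id", "year", "year_c", "fg", "habitat", "management", "y"]].reset_index(drop=True)
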