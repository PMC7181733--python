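"""Data model, validation and CSV I/O for UVC survey tables.

Four long-format tables describe a monitoring campaign:

``sites``
    one row per reef: ``reef_id, management[, regime]``.
``fish``
    one row per (species, length) observation within a replicate point
    count: ``reef_id, year, replicate, species_id, count, length_cm``.
``benthic``
    one row per replicate point count: percent cover of six substrate
    categories plus an ordinal structural-complexity score (0–5).
``traits``
    one row per species: family, trophic group and length–weight
    coefficients ``a`` (g cm⁻ᵇ) and ``b`` of the allometry W = a·Lᵇ.

All tables are plain :class:`pandas.DataFrame` objects; :class:`SurveyTables`
bundles them and :func:`validate_tables` enforces the invariants below.
CSV interchange is UTF-8 with "." decimals and a fixed column order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANAGEMENT_LEVELS = ("fished", "protected")
REGIME_LEVELS = ("recovering", "regime_shifted", "unassigned")

#: Diet-based functional groups of reef fish.
TROPHIC_GROUPS = (
    "piscivore",
    "mixed_diet",
    "scraper_excavator",
    "grazer",
    "browser",
    "planktivore",
    "corallivore",
)
#: Carnivores = piscivores + mixed-diet invertebrate/fish feeders.
CARNIVORE_GROUPS = ("piscivore", "mixed_diet")
#: Herbivores = grazing, scraping/excavating and macroalgal-browsing species.
HERBIVORE_GROUPS = ("scraper_excavator", "grazer", "browser")

BENTHIC_CATEGORIES = ("hard_coral", "soft_coral", "macroalgae", "sand", "rubble", "rock")

#: Visual cover estimates are coarse: category sums may fall short of 100
#: (unscored substrate) and exceed it slightly through rounding.
COVER_SUM_MAX = 100.5
COMPLEXITY_RANGE = (0, 5)
REPLICATE_RANGE = (1, 16)

SITES_COLUMNS = ["reef_id", "management", "regime"]
FISH_COLUMNS = ["reef_id", "year", "replicate", "species_id", "count", "length_cm"]
BENTHIC_COLUMNS = ["reef_id", "year", "replicate", *BENTHIC_CATEGORIES, "complexity"]
TRAITS_COLUMNS = ["species_id", "family", "trophic_group", "lw_a", "lw_b"]

_FILENAMES = {
    "sites": "sites.csv",
    "fish": "fish.csv",
    "benthic": "benthic.csv",
    "traits": "traits.csv",
}


class SchemaError(ValueError):
    """A CSV file does not match the expected column schema."""


class ValidationError(ValueError):
    """A table violates a data-model invariant; message lists offending rows."""


@dataclass
class SurveyTables:
    """Bundle of the four survey tables, with validation."""

    sites: pd.DataFrame
    fish: pd.DataFrame
    benthic: pd.DataFrame
    traits: pd.DataFrame

    def validate(self) -> "SurveyTables":
        validate_tables(self)
        return self

    def copy(self) -> "SurveyTables":
        return replace(
            self,
            sites=self.sites.copy(),
            fish=self.fish.copy(),
            benthic=self.benthic.copy(),
            traits=self.traits.copy(),
        )


def _require_columns(df: pd.DataFrame, columns: list[str], name: str, optional: tuple[str, ...] = ()) -> None:
    missing = [c for c in columns if c not in df.columns and c not in optional]
    if missing:
        raise SchemaError(f"{name} table is missing column(s): {', '.join(missing)}")


def _bad_rows(mask: pd.Series | np.ndarray, df: pd.DataFrame, what: str, name: str) -> None:
    mask = np.asarray(mask)
    if mask.any():
        idx = [int(i) for i in np.flatnonzero(mask)[:10]]
        raise ValidationError(f"{name} table: {what} at row index(es) {idx}" + (" ..." if mask.sum() > 10 else ""))


def validate_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Validate the site table; fills a missing ``regime`` column with 'unassigned'."""
    _require_columns(sites, SITES_COLUMNS, "sites", optional=("regime",))
    sites = sites.copy()
    if "regime" not in sites.columns:
        sites["regime"] = "unassigned"
    sites["regime"] = sites["regime"].fillna("unassigned")
    if sites["reef_id"].duplicated().any():
        dup = sites.loc[sites["reef_id"].duplicated(), "reef_id"].tolist()
        raise ValidationError(f"sites table: duplicated reef_id(s) {dup}")
    _bad_rows(~sites["management"].isin(MANAGEMENT_LEVELS), sites, "management not in {fished, protected}", "sites")
    _bad_rows(~sites["regime"].isin(REGIME_LEVELS), sites, f"regime not in {REGIME_LEVELS}", "sites")
    return sites[SITES_COLUMNS]


def validate_fish(fish: pd.DataFrame, traits: pd.DataFrame | None = None, sites: pd.DataFrame | None = None) -> pd.DataFrame:
    _require_columns(fish, FISH_COLUMNS, "fish")
    count = pd.to_numeric(fish["count"], errors="coerce")
    _bad_rows(count.isna() | (count < 1) | (count != np.floor(count)), fish, "count must be an integer >= 1", "fish")
    length = pd.to_numeric(fish["length_cm"], errors="coerce")
    _bad_rows(length.isna() | (length <= 0), fish, "length_cm must be > 0", "fish")
    rep = pd.to_numeric(fish["replicate"], errors="coerce")
    _bad_rows(
        rep.isna() | (rep < REPLICATE_RANGE[0]) | (rep > REPLICATE_RANGE[1]) | (rep != np.floor(rep)),
        fish,
        f"replicate must be an integer in {REPLICATE_RANGE}",
        "fish",
    )
    if traits is not None:
        orphans = sorted(set(fish["species_id"]) - set(traits["species_id"]))
        if orphans:
            raise ValidationError(f"fish table: species without a trait row: {orphans[:10]}" + (" ..." if len(orphans) > 10 else ""))
    if sites is not None:
        unknown = sorted(set(fish["reef_id"]) - set(sites["reef_id"]))
        if unknown:
            raise ValidationError(f"fish table: unknown reef_id(s): {unknown[:10]}")
    return fish[FISH_COLUMNS]


def validate_benthic(benthic: pd.DataFrame, sites: pd.DataFrame | None = None) -> pd.DataFrame:
    _require_columns(benthic, BENTHIC_COLUMNS, "benthic")
    covers = benthic[list(BENTHIC_CATEGORIES)].apply(pd.to_numeric, errors="coerce")
    _bad_rows(covers.isna().any(axis=1) | (covers < 0).any(axis=1) | (covers > 100).any(axis=1), benthic, "cover_pct outside [0, 100]", "benthic")
    _bad_rows(covers.sum(axis=1) > COVER_SUM_MAX, benthic, f"cover sum exceeds {COVER_SUM_MAX}", "benthic")
    cx = pd.to_numeric(benthic["complexity"], errors="coerce")
    _bad_rows(
        cx.isna() | (cx < COMPLEXITY_RANGE[0]) | (cx > COMPLEXITY_RANGE[1]) | (cx != np.floor(cx)),
        benthic,
        "complexity must be an integer score in 0..5",
        "benthic",
    )
    if sites is not None:
        unknown = sorted(set(benthic["reef_id"]) - set(sites["reef_id"]))
        if unknown:
            raise ValidationError(f"benthic table: unknown reef_id(s): {unknown[:10]}")
    return benthic[BENTHIC_COLUMNS]


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    _require_columns(traits, TRAITS_COLUMNS, "traits")
    if traits["species_id"].duplicated().any():
        dup = traits.loc[traits["species_id"].duplicated(), "species_id"].tolist()
        raise ValidationError(f"traits table: duplicated species_id(s) {dup[:10]}")
    _bad_rows(~traits["trophic_group"].isin(TROPHIC_GROUPS), traits, f"trophic_group not in {TROPHIC_GROUPS}", "traits")
    a = pd.to_numeric(traits["lw_a"], errors="coerce")
    _bad_rows(a.isna() | (a <= 0), traits, "lw_a must be > 0", "traits")
    b = pd.to_numeric(traits["lw_b"], errors="coerce")
    # allometric exponents far from 3 indicate unit errors, not biology
    _bad_rows(b.isna() | (b < 2) | (b > 4), traits, "lw_b outside sanity bounds [2, 4]", "traits")
    return traits[TRAITS_COLUMNS]


def validate_tables(tables: SurveyTables) -> SurveyTables:
    """Validate all four tables and their cross-references in place."""
    tables.sites = validate_sites(tables.sites)
    tables.traits = validate_traits(tables.traits)
    tables.fish = validate_fish(tables.fish, tables.traits, tables.sites)
    tables.benthic = validate_benthic(tables.benthic, tables.sites)
    return tables


_DTYPES = {
    "reef_id": str,
    "species_id": str,
    "family": str,
    "management": str,
    "regime": str,
    "trophic_group": str,
}


def read_survey_tables(directory: str | Path, *, validate: bool = True) -> SurveyTables:
    """Read ``sites.csv``, ``fish.csv``, ``benthic.csv`` and ``traits.csv``.

    Parameters
    ----------
    directory
        Folder containing the four CSV files.
    validate
        Check all data-model invariants after reading (default).
    """
    directory = Path(directory)
    frames = {}
    for key, fname in _FILENAMES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"expected {fname} in {directory}")
        frames[key] = pd.read_csv(path, dtype=_DTYPES, encoding="utf-8")
        logger.info("read %s: %d rows", fname, len(frames[key]))
    tables = SurveyTables(**frames)
    if validate:
        validate_tables(tables)
    return tables


def write_survey_tables(tables: SurveyTables, directory: str | Path) -> dict[str, Path]:
    """Write the four tables as CSV with the documented column order.

    Returns a mapping table-name -> written path. Round-trips losslessly
    through :func:`read_survey_tables`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    columns = {
        "sites": SITES_COLUMNS,
        "fish": FISH_COLUMNS,
        "benthic": BENTHIC_COLUMNS,
        "traits": TRAITS_COLUMNS,
    }
    paths = {}
    for key, fname in _FILENAMES.items():
        df: pd.DataFrame = getattr(tables, key)
        cols = [c for c in columns[key] if c in df.columns]
        path = directory / fname
        df.to_csv(path, index=False, columns=cols, encoding="utf-8")
        paths[key] = path
        logger.info("wrote %s: %d rows", fname, len(df))
    return paths
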