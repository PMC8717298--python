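"""Community, biomass, covariate and trait tables: reading, validation, filtering.

The cover data are long-format records (site, plot, species, percent cover)
from 1 m² quadrats; cover may sum to more than 100% within a plot because
canopies overlap.  Biomass is recorded per plot strip and functional group
(graminoid / forb / legume / other), covariates per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "read_community",
    "read_biomass",
    "read_covariates",
    "read_traits",
    "filter_sites",
]

FUNCTIONAL_GROUPS = ("graminoid", "forb", "legume", "other")


class ValidationError(ValueError):
    pass


@dataclass
class CommunityTable:
    """Long-format plot×species cover plus optional biomass / covariates / regions.

    Attributes
    ----------
    cover : DataFrame with columns (site, plot, species, cover)
    biomass : DataFrame with columns (site, plot, functional_group, mass) or None
    covariates : DataFrame indexed by site or None
    regions : mapping site → region label, optional
    """

    cover: pd.DataFrame
    biomass: pd.DataFrame | None = None
    covariates: pd.DataFrame | None = None
    regions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cover = _validate_cover(self.cover)
        if self.biomass is not None:
            self.biomass = _validate_biomass(self.biomass)

    @property
    def sites(self) -> list:
        return sorted(self.cover["site"].unique().tolist())

    def site_species(self, site) -> list[str]:
        sub = self.cover[(self.cover["site"] == site) & (self.cover["cover"] > 0)]
        if sub.empty and site not in set(self.cover["site"]):
            raise KeyError(f"unknown site: {site!r}")
        return sorted(sub["species"].unique().tolist())

    def site_plots(self, site) -> list:
        sub = self.cover[self.cover["site"] == site]
        if sub.empty:
            raise KeyError(f"unknown site: {site!r}")
        return sorted(sub["plot"].unique().tolist())

    def all_species(self) -> list[str]:
        return sorted(self.cover.loc[self.cover["cover"] > 0, "species"].unique())

    def graminoid_prevalence(self) -> pd.Series:
        """Per-site graminoid share of total live biomass (0–1)."""
        if self.biomass is None:
            raise ValueError("no biomass table attached")
        tot = self.biomass.groupby("site")["mass"].sum()
        gram = (
            self.biomass[self.biomass["functional_group"] == "graminoid"]
            .groupby("site")["mass"].sum()
        )
        return (gram.reindex(tot.index).fillna(0.0) / tot).rename("graminoid_prevalence")

    def subset_sites(self, sites) -> "CommunityTable":
        sites = set(sites)
        return CommunityTable(
            cover=self.cover[self.cover["site"].isin(sites)].reset_index(drop=True),
            biomass=None if self.biomass is None
            else self.biomass[self.biomass["site"].isin(sites)].reset_index(drop=True),
            covariates=None if self.covariates is None
            else self.covariates.loc[self.covariates.index.isin(sites)],
            regions={s: r for s, r in self.regions.items() if s in sites},
        )


def _validate_cover(df: pd.DataFrame) -> pd.DataFrame:
    required = {"site", "plot", "species", "cover"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"cover table missing columns: {sorted(missing)}")
    df = df.copy()
    df["species"] = df["species"].astype(str).str.strip().str.replace(r"\s+", " ", regex=True)
    if (df["species"] == "").any():
        bad = df.index[df["species"] == ""].tolist()
        raise ValidationError(f"empty species name at rows {bad[:5]}")
    df["cover"] = pd.to_numeric(df["cover"], errors="coerce")
    bad = df.index[df["cover"].isna() | (df["cover"] < 0)].tolist()
    if bad:
        raise ValidationError(f"negative or non-numeric cover at rows {bad[:5]}")
    return df.reset_index(drop=True)


def _validate_biomass(df: pd.DataFrame) -> pd.DataFrame:
    required = {"site", "plot", "functional_group", "mass"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"biomass table missing columns: {sorted(missing)}")
    df = df.copy()
    df["mass"] = pd.to_numeric(df["mass"], errors="coerce")
    bad = df.index[df["mass"].isna() | (df["mass"] < 0)].tolist()
    if bad:
        raise ValidationError(f"negative or non-numeric biomass at rows {bad[:5]}")
    return df.reset_index(drop=True)


def read_community(path, biomass_path=None, covariates_path=None,
                   regions_path=None) -> CommunityTable:
    """Read a long-format cover CSV (columns site,plot,species,cover) and,
    optionally, biomass / covariate / region CSVs, into a CommunityTable."""
    cover = pd.read_csv(path)
    if cover.empty:
        raise ValidationError(f"no records in cover table {path!s}")
    biomass = pd.read_csv(biomass_path) if biomass_path else None
    covariates = read_covariates(covariates_path) if covariates_path else None
    regions = {}
    if regions_path:
        rdf = pd.read_csv(regions_path)
        regions = dict(zip(rdf["site"], rdf["region"]))
    return CommunityTable(cover=cover, biomass=biomass, covariates=covariates,
                          regions=regions)


def read_biomass(path) -> pd.DataFrame:
    return _validate_biomass(pd.read_csv(path))


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "site" not in df.columns:
        raise ValidationError("covariates table needs a 'site' column")
    return df.set_index("site")


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValidationError("trait table needs a 'species' column")
    return df.set_index("species")


def filter_sites(
    table: CommunityTable,
    min_plots: int = 30,
    min_species: int = 0,
    min_graminoids: int = 0,
    graminoid_species=None,
    require_same_year_biomass: bool = False,
) -> tuple[CommunityTable, pd.DataFrame]:
    """Apply the site inclusion rules and return (filtered table, exclusion report).

    A site is retained when it has at least ``min_plots`` plots, at least
    ``min_species`` species with positive cover, at least ``min_graminoids``
    graminoid species (``graminoid_species``: iterable of species names), and —
    when ``require_same_year_biomass`` — a biomass record whose ``year`` matches
    the cover ``year`` (columns optional; rule skipped if either is absent).
    The report lists each excluded site with the first failing rule.
    """
    gram = set(graminoid_species) if graminoid_species is not None else None
    rows = []
    keep = []
    for site in table.sites:
        species = table.site_species(site)
        n_plots = len(table.site_plots(site))
        reason = None
        if n_plots < min_plots:
            reason = f"plots<{min_plots}"
        elif len(species) < min_species:
            reason = f"species<{min_species}"
        elif gram is not None and sum(1 for s in species if s in gram) < min_graminoids:
            reason = f"graminoids<{min_graminoids}"
        elif require_same_year_biomass:
            ok = _same_year_biomass(table, site)
            if not ok:
                reason = "biomass-year-mismatch"
        if reason is None:
            keep.append(site)
        else:
            rows.append({"site": site, "reason": reason})
    report = pd.DataFrame(rows, columns=["site", "reason"])
    return table.subset_sites(keep), report


def _same_year_biomass(table: CommunityTable, site) -> bool:
    if table.biomass is None:
        return False
    if "year" not in table.cover.columns or "year" not in table.biomass.columns:
        return True
    cover_years = set(table.cover.loc[table.cover["site"] == site, "year"])
    biom_years = set(table.biomass.loc[table.biomass["site"] == site, "year"])
    return bool(cover_years & biom_years)
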