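"""Site x taxon incidence matrices, taxonomy rollups, and accumulation curves.

Sites here are bio-subregions: broad biogeographic mapping units whose
rainforest communities are compared.  The incidence matrix records which
taxa occur in which subregion (presence/absence; any value > 0 counts as
presence).  A taxonomy map rolls taxa up to families, giving per-site
family richness and the site x family abundance matrix used for
family-composition dissimilarity.  Per-site attribute tables carry areas
(hectares), rainforest percentages, regional-ecosystem counts and
protection percentages; missing entries are representable and excluded
pairwise from any correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix",
    "TaxonomyMap",
    "SubregionAttributes",
    "load_community",
    "load_taxonomy",
    "load_attributes",
    "richness",
    "family_rollup",
    "accumulation_curve",
]

ATTRIBUTE_COLUMNS = [
    "area_ha",
    "pre_rf_ha",
    "rem_rf_ha",
    "pct_rem_rf",
    "pre_rf_pct_sub",
    "rem_rf_pct_sub",
    "re_count",
    "pct_pa",
    "pct_pa_and_f",
]


class CommunityMatrix:
    """Validated site x taxon matrix of non-negative incidences/counts."""

    def __init__(self, table: pd.DataFrame) -> None:
        if table.shape[0] < 1 or table.shape[1] < 1:
            raise ValueError("community matrix needs at least one site and one taxon")
        if table.index.duplicated().any():
            dup = sorted(table.index[table.index.duplicated()].unique())
            raise ValueError(f"duplicate site IDs: {dup}")
        if table.columns.duplicated().any():
            dup = sorted(table.columns[table.columns.duplicated()].unique())
            raise ValueError(f"duplicate taxon IDs: {dup}")
        values = table.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("non-numeric or non-finite cell in community matrix")
        if (values < 0).any():
            raise ValueError("negative cell in community matrix")
        self.table = table.astype(float)
        empty = self.table.sum(axis=1) == 0
        if empty.any():
            logger.warning(
                "community matrix has empty sites: %s",
                ", ".join(map(str, self.table.index[empty])),
            )

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.table.index]

    @property
    def taxa(self) -> list[str]:
        return [str(t) for t in self.table.columns]

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence view (any value > 0 is presence)."""
        return self.table > 0

    def site_taxa(self, site: str) -> set[str]:
        row = self.table.loc[site]
        return set(row.index[row > 0])

    def pool(self) -> list[str]:
        """Taxa occurring in at least one site (the sample pool)."""
        present = self.presence().any(axis=0)
        return [str(t) for t in self.table.columns[present]]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "site"
        out.to_csv(path)

    def __repr__(self) -> str:
        return f"CommunityMatrix({len(self.sites)} sites x {len(self.taxa)} taxa)"


def load_community(path_or_buffer) -> CommunityMatrix:
    """Read a sites-as-rows incidence CSV (first column: site IDs)."""
    df = pd.read_csv(path_or_buffer, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("empty community table")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in community table: {exc}") from exc
    return CommunityMatrix(df)


@dataclass
class TaxonomyMap:
    """taxon ID -> family name."""

    mapping: Mapping[str, str]

    def family_of(self, taxon: str) -> str:
        return self.mapping[taxon]

    def check_covers(self, taxa: Iterable[str]) -> None:
        missing = sorted(set(taxa) - set(self.mapping))
        if missing:
            raise ValueError(f"taxa without a family mapping: {missing}")

    @property
    def families(self) -> list[str]:
        return sorted(set(self.mapping.values()))


def load_taxonomy(path_or_buffer) -> TaxonomyMap:
    df = pd.read_csv(path_or_buffer, dtype=str)
    if not {"taxon", "family"} <= set(df.columns):
        raise ValueError("taxonomy CSV needs columns: taxon,family")
    if df["taxon"].duplicated().any():
        dup = sorted(df.loc[df["taxon"].duplicated(), "taxon"].unique())
        raise ValueError(f"taxon mapped more than once: {dup}")
    return TaxonomyMap(dict(zip(df["taxon"], df["family"])))


@dataclass
class SubregionAttributes:
    """Per-site attribute table (areas, percentages, protection fields).

    Missing values (printed "na" in the source tables) are NaN and are
    excluded pairwise downstream.  ``validate`` enforces ranges and checks
    that printed percentages agree with percentages recomputed from the
    hectare fields, to 2-dp rounding.
    """

    table: pd.DataFrame
    inconsistent: list[tuple[str, str]] = field(default_factory=list)

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.table.index]

    def validate(self, atol: float = 0.01) -> list[tuple[str, str]]:
        t = self.table
        problems: list[tuple[str, str]] = []
        for col in ("area_ha", "pre_rf_ha", "rem_rf_ha"):
            if col in t and (t[col].dropna() < 0).any():
                raise ValueError(f"negative hectare value in {col}")
        for col in ("pct_rem_rf", "pre_rf_pct_sub", "rem_rf_pct_sub",
                    "pct_pa", "pct_pa_and_f"):
            if col in t:
                v = t[col].dropna()
                if ((v < 0) | (v > 100)).any():
                    raise ValueError(f"percentage out of [0,100] in {col}")
        derived = {
            "pct_rem_rf": ("rem_rf_ha", "pre_rf_ha"),
            "pre_rf_pct_sub": ("pre_rf_ha", "area_ha"),
            "rem_rf_pct_sub": ("rem_rf_ha", "area_ha"),
        }
        for col, (num, den) in derived.items():
            if col not in t or num not in t or den not in t:
                continue
            for site, row in t.iterrows():
                if any(pd.isna(row[c]) for c in (col, num, den)) or row[den] == 0:
                    continue
                recomputed = round(100.0 * row[num] / row[den], 2)
                if abs(recomputed - round(row[col], 2)) > atol:
                    problems.append((str(site), col))
        self.inconsistent = problems
        return problems

    def column(self, name: str) -> pd.Series:
        return self.table[name]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "site"
        out.to_csv(path)


def load_attributes(path_or_buffer, validate: bool = True) -> SubregionAttributes:
    df = pd.read_csv(path_or_buffer, index_col="site", na_values=["na", "NA", ""])
    df.index = df.index.astype(str)
    missing = [c for c in ATTRIBUTE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"attribute CSV missing columns: {missing}")
    attrs = SubregionAttributes(df[ATTRIBUTE_COLUMNS].astype(float))
    if validate:
        # rows with any field missing or a summary "Total" row are the
        # caller's concern; per-site mismatches are recorded, not fatal
        attrs.validate()
    return attrs


def richness(cm: CommunityMatrix) -> pd.Series:
    """Species richness SR per site: number of taxa with incidence > 0."""
    sr = cm.presence().sum(axis=1).astype(int)
    sr.name = "sr"
    return sr


def family_rollup(
    cm: CommunityMatrix, tax: TaxonomyMap
) -> tuple[pd.Series, pd.DataFrame]:
    """Family richness per site and the site x family abundance matrix.

    Abundance cell = number of taxa of that family present at the site
    (this count matrix feeds family-composition Bray-Curtis); Fam = number
    of families with a positive count.
    """
    tax.check_covers(cm.taxa)
    pres = cm.presence().astype(int)
    fams = pd.Series({t: tax.family_of(t) for t in cm.taxa})
    abundance = pres.T.groupby(fams).sum().T
    abundance = abundance[sorted(abundance.columns)]
    fam = (abundance > 0).sum(axis=1).astype(int)
    fam.name = "fam"
    return fam, abundance


def accumulation_curve(cm: CommunityMatrix) -> pd.DataFrame:
    """Species accumulation over sites in decreasing-richness order.

    Starts with the richest site and adds the next richest (ties broken
    lexicographically by site ID), recording cumulative pooled richness.
    The final value equals the pooled richness of all sites.
    """
    pres = cm.presence()
    sr = pres.sum(axis=1)
    order = sorted(cm.sites, key=lambda s: (-sr[s], s))
    seen: set[str] = set()
    rows = []
    for site in order:
        seen |= cm.site_taxa(site)
        rows.append({"site": site, "sr": int(sr[site]), "cumulative_sr": len(seen)})
    return pd.DataFrame(rows)
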