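"""Shared data model for the pipeline.

The analysis links five kinds of observations on a set of biogeographic
units ("sites", e.g. ecoregions): a site x species incidence matrix W,
a species threat-category table (IUCN codes), a phylogeny with unit
branch lengths, and per-site geography / climate / land-use attributes.
Each container validates its invariants on construction so that every
downstream stage can assume a clean, aligned data model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("pcpspath")

#: The seven IUCN Red List categories, from least to most severe.
IUCN_CATEGORIES: tuple[str, ...] = ("LC", "NT", "VU", "EN", "CR", "EW", "EX")

#: Six aggregated anthropogenic-biome ("anthrome") cover classes, in
#: decreasing order of human population density.
ANTHROME_COLUMNS: tuple[str, ...] = (
    "urban", "villages", "croplands", "rangelands", "seminatural", "wild",
)

#: Nine environmental variables; each is summarized per site by its mean
#: and its range (max - min), giving 18 climate columns.
CLIMATE_VARIABLES: tuple[str, ...] = (
    "altitude",
    "annual_mean_temperature",
    "temperature_seasonality",
    "max_temperature_warmest_month",
    "min_temperature_coldest_month",
    "annual_mean_rainfall",
    "rainfall_seasonality",
    "precipitation_wettest_month",
    "precipitation_driest_month",
)

CLIMATE_COLUMNS: tuple[str, ...] = tuple(
    f"{v}_{s}" for v in CLIMATE_VARIABLES for s in ("mean", "range")
)

GEO_COLUMNS: tuple[str, ...] = ("latitude", "longitude", "area")

#: Slack allowed on the sum of the six anthrome proportions.
ANTHROME_SUM_TOL = 1e-6


class ValidationError(ValueError):
    """An input violated a data-model invariant."""


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifiers: {dupes}")


@dataclass(frozen=True)
class CompositionMatrix:
    """Site x taxon composition matrix.

    Holds either an incidence matrix W (entries in {0, 1}) or a
    non-negative weight matrix such as the phylogeny-weighted matrix P.
    Rows are sites, columns taxa; both orders are preserved.
    """

    values: pd.DataFrame

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, *, drop_empty_taxa: bool = True
    ) -> "CompositionMatrix":
        _check_unique(df.index, "site")
        _check_unique(df.columns, "taxon")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at site {df.index[bad[0]]!r}, "
                f"taxon {df.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at site {df.index[bad[0]]!r}, "
                f"taxon {df.columns[bad[1]]!r}"
            )
        if drop_empty_taxa:
            empty = arr.sum(axis=0) == 0
            if empty.any():
                dropped = df.columns[empty].tolist()
                logger.warning(
                    "dropping %d taxa absent from every site: %s",
                    len(dropped), dropped,
                )
                df = df.loc[:, ~empty]
        out = df.astype(float)
        out.index = out.index.astype(str)
        out.columns = out.columns.astype(str)
        return cls(out)

    @property
    def sites(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)

    @property
    def is_incidence(self) -> bool:
        arr = self.values.to_numpy()
        return bool(np.isin(arr, (0.0, 1.0)).all())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def reindex_sites(self, sites) -> "CompositionMatrix":
        missing = set(sites) - set(self.values.index)
        if missing:
            raise ValidationError(f"unknown sites requested: {sorted(missing)}")
        return CompositionMatrix(self.values.loc[list(sites)])


@dataclass(frozen=True)
class ThreatTable:
    """Taxon -> IUCN category lookup (one row per taxon)."""

    categories: pd.Series

    @classmethod
    def from_series(cls, s: pd.Series) -> "ThreatTable":
        _check_unique(s.index, "taxon")
        s = s.astype(str)
        bad = sorted(set(s) - set(IUCN_CATEGORIES))
        if bad:
            raise ValidationError(
                f"unknown IUCN categories {bad}; expected one of {IUCN_CATEGORIES}"
            )
        s.index = s.index.astype(str)
        return cls(s)

    def category_for(self, taxa) -> pd.Series:
        """Categories aligned to ``taxa``; missing taxa default to LC.

        Partial tables are common (not every species is assessed), so
        unlisted taxa are treated as Least Concern with a warning.
        """
        out = self.categories.reindex(taxa)
        n_missing = int(out.isna().sum())
        if n_missing:
            logger.warning(
                "%d taxa missing from threat table; treated as LC", n_missing
            )
            out = out.fillna("LC")
        return out


@dataclass(frozen=True)
class PhylogenyBundle:
    """Rooted phylogeny with all branch lengths set to one.

    Node-count (unit-branch-length patristic) distances are the basis of
    the fuzzy-weighting similarities, so whatever lengths the source tree
    carried are overwritten on construction. ``taxon_to_clade`` maps each
    tip to a genus / higher-clade label used for the clade-axis
    correlation diagnostics.
    """

    tree: dendropy.Tree
    taxon_to_clade: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tree(
        cls, tree: dendropy.Tree, taxon_to_clade: dict[str, str] | None = None
    ) -> "PhylogenyBundle":
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise ValidationError("tree has unlabeled tips")
        _check_unique(labels, "tip")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node:
                edge.length = 1.0
        return cls(tree, dict(taxon_to_clade or {}))

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


@dataclass(frozen=True)
class SiteAttributes:
    """Per-site geography, 18 climate summaries and 6 anthrome covers."""

    table: pd.DataFrame

    REQUIRED: tuple[str, ...] = GEO_COLUMNS + CLIMATE_COLUMNS + ANTHROME_COLUMNS

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SiteAttributes":
        _check_unique(df.index, "site")
        missing = [c for c in cls.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required site-attribute columns: {missing}")
        df = df.loc[:, list(cls.REQUIRED)].astype(float)
        df.index = df.index.astype(str)
        anth = df.loc[:, list(ANTHROME_COLUMNS)].to_numpy()
        if (anth < 0).any() or (anth > 1).any():
            raise ValidationError("anthrome cover proportions must lie in [0, 1]")
        sums = anth.sum(axis=1)
        over = sums > 1 + ANTHROME_SUM_TOL
        if over.any():
            bad = df.index[over][0]
            raise ValidationError(
                f"anthrome covers of site {bad!r} sum to {sums[over][0]:.6f} > 1"
            )
        if (df["area"] <= 0).any():
            bad = df.index[df["area"] <= 0][0]
            raise ValidationError(f"non-positive area for site {bad!r}")
        range_cols = [c for c in CLIMATE_COLUMNS if c.endswith("_range")]
        if (df.loc[:, range_cols].to_numpy() < 0).any():
            raise ValidationError("climate range values must be non-negative")
        return cls(df)

    @property
    def sites(self) -> list[str]:
        return list(self.table.index)

    def aligned_to(self, sites) -> "SiteAttributes":
        missing = set(sites) - set(self.table.index)
        if missing:
            raise ValidationError(f"sites missing from attribute table: {sorted(missing)}")
        return SiteAttributes(self.table.loc[list(sites)])

    @property
    def geography(self) -> pd.DataFrame:
        return self.table.loc[:, list(GEO_COLUMNS)]

    @property
    def climate(self) -> pd.DataFrame:
        return self.table.loc[:, list(CLIMATE_COLUMNS)]

    @property
    def anthromes(self) -> pd.DataFrame:
        return self.table.loc[:, list(ANTHROME_COLUMNS)]
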