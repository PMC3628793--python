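"""Readers and writers for the canonical file formats.

CSV (UTF-8, header row) carries all tabular data; newick carries trees.
Readers validate into the shared data model; writers round-trip exactly.
"""
from __future__ import annotations

import os

import dendropy
import pandas as pd

from .datatypes import (
    CompositionMatrix,
    PhylogenyBundle,
    SiteAttributes,
    ThreatTable,
    ValidationError,
)


def read_composition(path: str | os.PathLike, *, drop_empty_taxa: bool = True) -> CompositionMatrix:
    """Read a site x taxon matrix from CSV (sites as rows, taxa as columns)."""
    df = pd.read_csv(path, index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                row = df.index[coerced.isna()][0]
                raise ValidationError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}"
                ) from exc
        raise
    return CompositionMatrix.from_dataframe(df, drop_empty_taxa=drop_empty_taxa)


def write_composition(W: CompositionMatrix, path: str | os.PathLike) -> None:
    W.values.to_csv(path, index_label="site")


def read_tree(path: str | os.PathLike, taxon_to_clade: dict[str, str] | None = None) -> PhylogenyBundle:
    """Read a newick tree; every branch length is overwritten to 1."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"could not parse newick file {path}: {exc}") from exc
    return PhylogenyBundle.from_tree(tree, taxon_to_clade)


def read_tree_string(newick: str, taxon_to_clade: dict[str, str] | None = None) -> PhylogenyBundle:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValidationError(f"could not parse newick string: {exc}") from exc
    return PhylogenyBundle.from_tree(tree, taxon_to_clade)


def write_tree(phy: PhylogenyBundle, path: str | os.PathLike) -> None:
    phy.tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def read_threats(path: str | os.PathLike) -> ThreatTable:
    """Read a two-column CSV: taxon, category (IUCN code)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    taxon_col = cols.get("taxon", df.columns[0])
    cat_col = cols.get("category", df.columns[1])
    s = pd.Series(df[cat_col].values, index=df[taxon_col].values)
    return ThreatTable.from_series(s)


def write_threats(threats: ThreatTable, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {"taxon": threats.categories.index, "category": threats.categories.values}
    )
    df.to_csv(path, index=False)


def read_site_attributes(path: str | os.PathLike) -> SiteAttributes:
    """Read the per-site attribute table (geography, climate, anthromes)."""
    df = pd.read_csv(path, index_col=0)
    return SiteAttributes.from_dataframe(df)


def write_site_attributes(attrs: SiteAttributes, path: str | os.PathLike) -> None:
    attrs.table.to_csv(path, index_label="site")


def read_clade_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column CSV: taxon, clade."""
    df = pd.read_csv(path)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_clade_map(mapping: dict[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"taxon": list(mapping), "clade": list(mapping.values())}
    ).to_csv(path, index=False)
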