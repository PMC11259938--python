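"""Readers and writers for the tab-separated formats the pipeline consumes.

Associations arrive in a GWAS-Catalog-like TSV layout (one association per
row); ontology edges as a two-column child/parent TSV or an OBO file (is_a
relations); candidate pools and score matrices as TSV with named columns.
Column names are configurable through a name mapping so real exports can be
pointed at directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_ASSOC_COLUMNS = {
    "id": "SNPS",
    "chrom": "CHR_ID",
    "pos": "CHR_POS",
    "term_id": "MAPPED_TRAIT_URI",
    "assoc_p": "P-VALUE",
    "date_added": "DATE ADDED TO CATALOG",
    "functional_class": "CONTEXT",
}

POOL_COLUMNS = ["id", "chrom", "pos", "maf", "dist_tss", "gene_density", "ld_partners", "ld_block"]


def read_associations(path, column_map=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an association TSV into (variants, annotation table).

    ``column_map`` maps internal names to file column names; unmapped
    optional attributes come back as NaN.  Returns one row per unique
    variant in ``variants`` and one (term_id, variant_id) row per
    association.
    """
    colmap = dict(DEFAULT_ASSOC_COLUMNS)
    if column_map:
        colmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype={colmap["chrom"]: str})
    variants = pd.DataFrame(
        {
            "id": raw[colmap["id"]].astype(str),
            "chrom": raw[colmap["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[colmap["pos"]], errors="coerce").astype("Int64"),
        }
    )
    for attr in ("maf", "dist_tss", "gene_density", "ld_partners", "ld_block"):
        col = colmap.get(attr)
        if col and col in raw.columns:
            variants[attr] = pd.to_numeric(raw[col], errors="coerce")
        else:
            variants[attr] = np.nan
    variants["assoc_p"] = pd.to_numeric(raw.get(colmap["assoc_p"]), errors="coerce")
    variants["date_added"] = pd.to_datetime(raw.get(colmap["date_added"]), errors="coerce")
    variants["functional_class"] = raw.get(colmap["functional_class"])
    table = pd.DataFrame(
        {
            "term_id": raw[colmap["term_id"]].astype(str),
            "variant_id": raw[colmap["id"]].astype(str),
        }
    ).drop_duplicates()
    variants = variants.sort_values("assoc_p").drop_duplicates("id", keep="first")
    return variants.reset_index(drop=True), table.reset_index(drop=True)


def read_ontology_edges(path) -> pd.DataFrame:
    """Ontology edges as (child, parent): two-column TSV, or OBO is_a."""
    path = str(path)
    if path.endswith(".obo"):
        import obonet

        graph = obonet.read_obo(path)
        # obonet edges run child -> parent for is_a
        rows = [
            (child, parent)
            for child, parent, key in graph.edges(keys=True)
            if key == "is_a"
        ]
        return pd.DataFrame(rows, columns=["child", "parent"])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("edge file must have two columns (child, parent)")
    df = df.iloc[:, :2]
    df.columns = ["child", "parent"]
    return df


def read_pool(path, column_map=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in POOL_COLUMNS if c not in df.columns and c != "ld_block"]
    if missing:
        raise ValueError(f"pool file lacks required columns: {missing}")
    return df


def write_annotation_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_match_result(result, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)


def read_score_matrix(path) -> pd.DataFrame:
    """Variants x tissues score matrix TSV with variant ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_score_matrix(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(int)
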