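"""Build and structure the disease-variant inventory.

Variants are carried as :class:`pandas.DataFrame` rows with the columns

    id, chrom, pos, maf, dist_tss, gene_density, ld_partners,
    ld_block, assoc_p, date_added, functional_class

(missing attributes are NaN/NaT).  Annotation tables are two-column frames
``(term_id, variant_id)``; ontology edges are two-column frames
``(child, parent)`` describing an is-a DAG over trait terms, with the parent
the more general term.  Propagating variant annotations from specific to
general terms grows the usable variant set per disease term, which is what
makes modelling broad disease phenotypes possible at all.

Coordinates are 1-based inclusive; BED exports elsewhere are 0-based
half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CODING_CLASSES",
    "HLA_INTERVAL",
    "TemporalSplit",
    "filter_noncoding",
    "apply_qc_filters",
    "propagate_annotations",
    "select_terms",
    "assign_ld_blocks",
    "temporal_split",
]

#: Functional-class labels treated as protein-coding and excluded.
DEFAULT_CODING_CLASSES = frozenset(
    {
        "missense_variant",
        "frameshift_variant",
        "stop_gained",
        "stop_lost",
        "synonymous_variant",
        "coding_sequence_variant",
    }
)

#: Extended MHC region on chromosome 6 (hg19), 1-based inclusive.
HLA_INTERVAL = ("6", 28_477_797, 33_448_354)

VARIANT_COLUMNS = [
    "id",
    "chrom",
    "pos",
    "maf",
    "dist_tss",
    "gene_density",
    "ld_partners",
    "ld_block",
    "assoc_p",
    "date_added",
    "functional_class",
]


def filter_noncoding(variants: pd.DataFrame, coding_classes=None) -> pd.DataFrame:
    """Drop variants whose functional class marks protein-coding impact.

    Variants without a functional-class label are presumed non-coding and
    retained with a warning.
    """
    if coding_classes is None:
        coding_classes = DEFAULT_CODING_CLASSES
    if variants.empty:
        return variants.copy()
    labels = variants["functional_class"]
    missing = labels.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} variants lack a functional-class label; "
            "kept as presumed non-coding",
            stacklevel=2,
        )
    keep = ~labels.isin(coding_classes)
    return variants.loc[keep].copy()


def apply_qc_filters(
    variants: pd.DataFrame,
    hla_interval=HLA_INTERVAL,
    maf_min: float | None = 0.01,
) -> pd.DataFrame:
    """Remove variants inside the HLA interval or with MAF below ``maf_min``.

    The MAF filter is a strict "less than": a variant with MAF exactly
    ``maf_min`` survives.  Variants without a MAF cannot be matched to
    controls and are removed with a warning.  ``maf_min=None`` disables the
    MAF filter entirely (for inputs that carry no frequency column).  The
    number of removed variants is recorded in ``result.attrs["n_removed"]``.
    """
    if variants.empty:
        out = variants.copy()
        out.attrs["n_removed"] = 0
        return out
    chrom, start, end = hla_interval
    in_hla = (
        (variants["chrom"].astype(str) == str(chrom))
        & (variants["pos"] >= start)
        & (variants["pos"] <= end)
    )
    if maf_min is None:
        low_maf = pd.Series(False, index=variants.index)
    else:
        maf = variants["maf"]
        no_maf = maf.isna()
        if no_maf.any():
            warnings.warn(
                f"{int(no_maf.sum())} variants lack a MAF and were removed",
                stacklevel=2,
            )
        low_maf = no_maf | (maf < maf_min)
    keep = ~(in_hla | low_maf)
    out = variants.loc[keep].copy()
    out.attrs["n_removed"] = int((~keep).sum())
    return out


def _edges_graph(edges: pd.DataFrame) -> nx.DiGraph:
    g = nx.DiGraph()
    for child, parent in edges.itertuples(index=False):
        g.add_edge(child, parent)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return g
    raise ValueError(f"ontology edges contain a cycle, e.g. {cycle[0][0]} -> {cycle[0][1]}")


def propagate_annotations(table: pd.DataFrame, edges: pd.DataFrame) -> pd.DataFrame:
    """Propagate variant annotations from child terms up to their ancestors.

    After propagation each term's variant set is the union of its own set and
    the sets of all of its descendants (terms reachable against the
    child->parent edge direction).  The operation is monotone and idempotent.
    """
    table = table.drop_duplicates()
    if edges is None or len(edges) == 0:
        return table.reset_index(drop=True)
    g = _edges_graph(edges)
    sets: dict[str, set] = {}
    for term, sub in table.groupby("term_id"):
        sets[term] = set(sub["variant_id"])
    for term in g.nodes:
        sets.setdefault(term, set())
    # children come before parents in a topological order of child->parent edges
    for node in nx.topological_sort(g):
        for parent in g.successors(node):
            sets[parent] |= sets[node]
    records = [
        (term, vid) for term in sorted(sets) for vid in sorted(sets[term])
    ]
    return pd.DataFrame(records, columns=["term_id", "variant_id"])


def select_terms(table: pd.DataFrame, min_snvs: int = 100) -> pd.DataFrame:
    """Terms with at least ``min_snvs`` annotated variants, with counts."""
    counts = (
        table.drop_duplicates()
        .groupby("term_id")["variant_id"]
        .nunique()
        .rename("n_snvs")
        .reset_index()
    )
    return counts.loc[counts["n_snvs"] >= min_snvs].reset_index(drop=True)


def assign_ld_blocks(
    variants: pd.DataFrame,
    ld_pairs,
    r2_min: float = 0.5,
) -> tuple[pd.Series, pd.DataFrame]:
    """Group variants into LD blocks and pick one representative per block.

    Blocks are the connected components of the graph whose edges join
    variant pairs with r² >= ``r2_min``; every variant belongs to exactly one
    block (singletons included).  The representative is the member with the
    smallest association p-value; ties break toward the lexicographically
    smaller id, and variants without a p-value rank last.

    Returns ``(block_of, representatives)`` where ``block_of`` maps variant
    id -> block label (the smallest member id) and ``representatives`` is a
    frame ``(ld_block, representative, assoc_p, n_members)``.
    """
    ids = list(variants["id"])
    known = set(ids)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for a, b, r2 in ld_pairs:
        if a not in known or b not in known:
            warnings.warn(f"LD pair ({a}, {b}) references an unknown variant; ignored", stacklevel=2)
            continue
        if r2 >= r2_min:
            g.add_edge(a, b)
    pvals = variants.set_index("id")["assoc_p"]
    block_of = {}
    rep_rows = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        label = members[0]
        for m in members:
            block_of[m] = label
        rep = min(
            members,
            key=lambda m: (
                pvals.get(m) if pd.notna(pvals.get(m)) else np.inf,
                m,
            ),
        )
        rep_rows.append((label, rep, pvals.get(rep), len(members)))
    reps = pd.DataFrame(
        rep_rows, columns=["ld_block", "representative", "assoc_p", "n_members"]
    ).sort_values("ld_block").reset_index(drop=True)
    return pd.Series(block_of, name="ld_block"), reps


@dataclass
class TemporalSplit:
    """Train/test annotation tables split at a reporting-date cutoff.

    Test variants postdate the cutoff and sit at least ``exclusion_radius_bp``
    away from every training variant on the same chromosome, so the test set
    cannot be contaminated by LD with training positions.
    """

    train: pd.DataFrame
    test: pd.DataFrame
    cutoff_date: pd.Timestamp
    exclusion_radius_bp: int = 1000
    retained_terms: list = field(default_factory=list)
    train_variants: pd.DataFrame | None = None
    test_variants: pd.DataFrame | None = None


def temporal_split(
    table: pd.DataFrame,
    variants: pd.DataFrame,
    cutoff_date,
    min_train: int = 20,
    min_test: int = 50,
    exclusion_bp: int = 1000,
) -> TemporalSplit:
    """Split variants into pre-/post-cutoff sets with a proximity exclusion.

    Variants dated on or before ``cutoff_date`` (or undated, conservatively)
    form the training pool; later variants enter the test pool unless they
    lie within ``exclusion_bp`` of a training variant on the same chromosome.
    Terms are retained only when they keep at least ``min_train`` training
    and ``min_test`` test variants.
    """
    cutoff = pd.Timestamp(cutoff_date)
    dates = pd.to_datetime(variants["date_added"])
    undated = dates.isna()
    if undated.any():
        warnings.warn(
            f"{int(undated.sum())} variants lack a date; assigned to the training side",
            stacklevel=2,
        )
    is_train = undated | (dates <= cutoff)
    train_v = variants.loc[is_train]
    cand_v = variants.loc[~is_train]

    keep_rows = []
    train_pos = {
        str(c): np.sort(sub["pos"].to_numpy())
        for c, sub in train_v.groupby(variants["chrom"].astype(str))
    }
    for row in cand_v.itertuples(index=False):
        positions = train_pos.get(str(row.chrom))
        if positions is None or positions.size == 0:
            keep_rows.append(True)
            continue
        j = np.searchsorted(positions, row.pos)
        near = False
        if j < positions.size and positions[j] - row.pos < exclusion_bp:
            near = True
        if j > 0 and row.pos - positions[j - 1] < exclusion_bp:
            near = True
        keep_rows.append(not near)
    test_v = cand_v.loc[np.asarray(keep_rows, dtype=bool)] if len(cand_v) else cand_v

    table = table.drop_duplicates()
    train_ids = set(train_v["id"])
    test_ids = set(test_v["id"])
    train_tab = table.loc[table["variant_id"].isin(train_ids)]
    test_tab = table.loc[table["variant_id"].isin(test_ids)]
    tr_counts = train_tab.groupby("term_id")["variant_id"].nunique()
    te_counts = test_tab.groupby("term_id")["variant_id"].nunique()
    retained = sorted(
        t
        for t in set(tr_counts.index) & set(te_counts.index)
        if tr_counts[t] >= min_train and te_counts[t] >= min_test
    )
    return TemporalSplit(
        train=train_tab.loc[train_tab["term_id"].isin(retained)].reset_index(drop=True),
        test=test_tab.loc[test_tab["term_id"].isin(retained)].reset_index(drop=True),
        cutoff_date=cutoff,
        exclusion_radius_bp=exclusion_bp,
        retained_terms=retained,
        train_variants=train_v.reset_index(drop=True),
        test_variants=test_v.reset_index(drop=True),
    )
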