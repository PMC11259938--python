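"""Matched-control selection for disease-associated variants.

Every disease-associated (positive) variant receives up to ``n_controls``
control variants drawn from a pool of common non-coding variants, under one
of four strategies:

``random``
    uniform draws from the pool;
``tss``
    draws from the positive's TSS-distance quantile bin (the pool is sorted
    by distance to the nearest protein-coding TSS and split into equal-count
    bins);
``snpsnap``
    draws from candidates matching the positive on MAF, gene density,
    TSS distance and LD-partner count within per-attribute relative
    tolerances (defaults 5%, 50%, 20%, 50%);
``snpsnap_tss``
    as ``snpsnap`` but only the TSS-distance tolerance binds (the other
    three are set to 100, i.e. 10,000%, effectively unconstrained).

Controls are globally unique across the whole result: a control claimed for
one positive is never reused for another, and pool variants that appear in
the association catalog are excluded up front.  Positives with no eligible
candidate are dropped and recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MatchConfig",
    "MatchResult",
    "SNPSNAP_TOLERANCES",
    "SNPSNAP_TSS_TOLERANCES",
    "bin_by_tss_distance",
    "match_controls",
]

MATCH_ATTRIBUTES = ("maf", "gene_density", "dist_tss", "ld_partners")

#: Maximum allowable relative deviation per attribute for SNPsnap matching.
SNPSNAP_TOLERANCES = {
    "maf": 0.05,
    "gene_density": 0.50,
    "dist_tss": 0.20,
    "ld_partners": 0.50,
}

#: Only the TSS distance binds; 100 encodes the "10,000%" unconstrained case.
SNPSNAP_TSS_TOLERANCES = {
    "maf": 100.0,
    "gene_density": 100.0,
    "dist_tss": 0.20,
    "ld_partners": 100.0,
}

STRATEGIES = ("random", "tss", "snpsnap", "snpsnap_tss")


@dataclass
class MatchConfig:
    strategy: str = "snpsnap"
    n_controls: int = 10
    tolerances: dict | None = None
    n_bins: int = 50
    rng_seed: int = 0

    def resolved_tolerances(self) -> dict:
        if self.tolerances is not None:
            tol = dict(self.tolerances)
        elif self.strategy == "snpsnap_tss":
            tol = dict(SNPSNAP_TSS_TOLERANCES)
        else:
            tol = dict(SNPSNAP_TOLERANCES)
        if any(v <= 0 for v in tol.values()):
            raise ValueError("tolerances must be positive")
        return tol

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")


@dataclass
class MatchResult:
    """Mapping positive -> controls plus an audit of attribute deviations."""

    matches: dict = field(default_factory=dict)
    dropped_positives: list = field(default_factory=list)
    audit: pd.DataFrame | None = None
    strategy: str = "snpsnap"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (pos, ctrl, rank + 1)
            for pos, ctrls in self.matches.items()
            for rank, ctrl in enumerate(ctrls)
        ]
        return pd.DataFrame(rows, columns=["positive_id", "control_id", "rank"])


def bin_by_tss_distance(pool: pd.DataFrame, n_bins: int) -> pd.Series:
    """Equal-count TSS-distance bins over the pool.

    The pool is sorted by ``(dist_tss, id)`` and cut into ``n_bins``
    contiguous bins whose sizes differ by at most one (the first
    ``n % n_bins`` bins take the extra variant).  Returns the bin index
    aligned to the pool's index.
    """
    n = len(pool)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds pool size {n}")
    order = pool.sort_values(["dist_tss", "id"], kind="mergesort").index
    base, extra = divmod(n, n_bins)
    sizes = [base + 1] * extra + [base] * (n_bins - extra)
    labels = np.repeat(np.arange(n_bins), sizes)
    return pd.Series(labels, index=order, name="tss_bin").reindex(pool.index)


def _relative_deviation(ctrl_values: np.ndarray, pos_value: float) -> np.ndarray:
    """|a_ctrl - a_pos| / a_pos, with an exact-equality fallback at a_pos = 0."""
    if pos_value == 0:
        return np.where(ctrl_values == 0, 0.0, np.inf)
    return np.abs(ctrl_values - pos_value) / abs(pos_value)


def match_controls(
    positives: pd.DataFrame,
    pool: pd.DataFrame,
    catalog_ids=(),
    config: MatchConfig | None = None,
) -> MatchResult:
    """Select matched controls for each positive under ``config.strategy``.

    Global uniqueness of controls is enforced greedily: positives are
    visited in a seeded random order and claim candidates first-come.  The
    audit table records, for every returned (positive, control) pair and
    attribute, the positive and control values, the relative deviation, and
    the tolerance in force (infinite for strategies that do not constrain
    the attribute).
    """
    config = config or MatchConfig()
    rng = np.random.default_rng(config.rng_seed)
    result = MatchResult(strategy=config.strategy)

    if positives.empty:
        result.audit = _empty_audit()
        return result

    catalog_ids = set(catalog_ids) | set(positives["id"])
    pool = pool.loc[~pool["id"].isin(catalog_ids)].reset_index(drop=True)
    if pool.empty:
        warnings.warn("control pool is empty after catalog exclusion", stacklevel=2)
        result.dropped_positives = list(positives["id"])
        result.audit = _empty_audit()
        return result

    pool_ids = pool["id"].to_numpy()
    attrs = {a: pool[a].to_numpy(dtype=float) for a in MATCH_ATTRIBUTES}

    tol = None
    bins = bin_edges = None
    if config.strategy in ("snpsnap", "snpsnap_tss"):
        tol = config.resolved_tolerances()
    elif config.strategy == "tss":
        bins = bin_by_tss_distance(pool, config.n_bins).to_numpy()
        # upper edge of each bin in sorted dist_tss order locates a positive's bin
        sorted_d = np.sort(pool["dist_tss"].to_numpy(dtype=float))
        sizes = np.bincount(bins, minlength=config.n_bins)
        bin_edges = np.cumsum(sizes)[:-1]  # split points into the sorted pool

    claimed = np.zeros(len(pool), dtype=bool)
    audit_rows = []

    order = rng.permutation(len(positives))
    for idx in order:
        prow = positives.iloc[idx]
        if config.strategy == "random":
            eligible = ~claimed
        elif config.strategy == "tss":
            j = np.searchsorted(sorted_d, float(prow["dist_tss"]), side="right")
            pos_bin = np.searchsorted(bin_edges, j, side="right")
            pos_bin = min(pos_bin, config.n_bins - 1)
            eligible = (bins == pos_bin) & ~claimed
        else:
            eligible = ~claimed
            for a in MATCH_ATTRIBUTES:
                dev = _relative_deviation(attrs[a], float(prow[a]))
                eligible &= dev <= tol[a]
        cand = np.flatnonzero(eligible)
        if cand.size == 0:
            result.dropped_positives.append(prow["id"])
            continue
        take = min(config.n_controls, cand.size)
        if cand.size < config.n_controls:
            warnings.warn(
                f"positive {prow['id']}: only {cand.size} eligible controls "
                f"(requested {config.n_controls})",
                stacklevel=2,
            )
        chosen = rng.choice(cand, size=take, replace=False)
        claimed[chosen] = True
        result.matches[prow["id"]] = [pool_ids[c] for c in chosen]
        for c in chosen:
            for a in MATCH_ATTRIBUTES:
                pv = float(prow[a])
                cv = float(attrs[a][c])
                audit_rows.append(
                    (
                        prow["id"],
                        pool_ids[c],
                        a,
                        pv,
                        cv,
                        float(_relative_deviation(np.array([cv]), pv)[0]),
                        tol[a] if tol is not None else np.inf,
                    )
                )

    # report in the original positive order
    ordered = {
        pid: result.matches[pid] for pid in positives["id"] if pid in result.matches
    }
    result.matches = ordered
    result.dropped_positives = [
        pid for pid in positives["id"] if pid in set(result.dropped_positives)
    ]
    result.audit = pd.DataFrame(audit_rows, columns=_AUDIT_COLUMNS)
    return result


_AUDIT_COLUMNS = [
    "positive_id",
    "control_id",
    "attribute",
    "positive_value",
    "control_value",
    "deviation",
    "tolerance",
]


def _empty_audit() -> pd.DataFrame:
    return pd.DataFrame(columns=_AUDIT_COLUMNS)
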