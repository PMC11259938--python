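"""Coefficient-based disease-disease similarity and downstream analyses.

Two diseases are similar when the same tissues drive variant prioritization
for both.  The similarity s_m between diseases i and j is the signed squared
weighted Pearson correlation of their tissue-coefficient vectors, with
per-tissue weights w_k = 1 / (s_k^i s_k^j) built from shrunken coefficient
standard deviations

    s_k = mix * gamma_k + (1 - mix) * m,

where gamma_k is the repeated-CV SD of coefficient k and m is a pooled floor
(by default the 25% quantile of all SDs across diseases and tissues).  The
shrinkage keeps precisely estimated coefficients influential without letting
near-zero SDs blow up the weights.  With constant weights s_m reduces to
sign(r) * r^2 of the plain Pearson correlation.

Also here: size-weighted combination of per-study genetic correlations into
one value per disease pair, coefficient normalization for heatmaps,
hierarchical clustering of the similarity matrix, and rank-sum tests for
cluster-specific tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

__all__ = [
    "ShrinkageConfig",
    "SimilarityResult",
    "GeneticCorrEstimate",
    "shrink_sds",
    "disease_similarity",
    "similarity_matrix",
    "combine_genetic_correlation",
    "normalize_coefficients",
    "cluster_diseases",
    "cluster_specific_tissues",
    "assign_tissue_cluster",
]


@dataclass
class ShrinkageConfig:
    mix: float = 0.75
    floor_quantile: float = 0.25

    def __post_init__(self):
        if not 0 <= self.mix <= 1:
            raise ValueError("mix must be in [0, 1]")
        if not 0 < self.floor_quantile < 1:
            raise ValueError("floor_quantile must be in (0, 1)")


def shrink_sds(gamma, config: ShrinkageConfig | None = None):
    """Shrink coefficient SDs toward a pooled floor.

    ``m`` is the ``floor_quantile`` quantile (linear interpolation) of all
    entries of ``gamma`` pooled across diseases and tissues.
    """
    config = config or ShrinkageConfig()
    arr = np.asarray(gamma, dtype=float)
    if (arr < 0).any():
        raise ValueError("coefficient SDs must be non-negative")
    m = float(np.quantile(arr, config.floor_quantile))
    if m == 0 and config.mix < 1:
        raise ValueError(
            "pooled SD floor is zero (degenerate SDs); supply a positive floor"
        )
    shrunk = config.mix * arr + (1 - config.mix) * m
    if isinstance(gamma, pd.DataFrame):
        return pd.DataFrame(shrunk, index=gamma.index, columns=gamma.columns)
    return shrunk


@dataclass
class SimilarityResult:
    s_m: float
    r_squared: float
    slope_sign: int
    weights: np.ndarray
    degenerate: bool = False


def _weighted_corr(x, y, w):
    wsum = w.sum()
    mx = np.sum(w * x) / wsum
    my = np.sum(w * y) / wsum
    cov = np.sum(w * (x - mx) * (y - my)) / wsum
    vx = np.sum(w * (x - mx) ** 2) / wsum
    vy = np.sum(w * (y - my) ** 2) / wsum
    if vx <= 0 or vy <= 0:
        return None
    return cov / np.sqrt(vx * vy)


def disease_similarity(beta_i, beta_j, s_i, s_j) -> SimilarityResult:
    """Signed squared weighted correlation of two coefficient vectors.

    Equivalent to the r-squared of the weighted regression of one vector on
    the other, signed by the slope; symmetric in (i, j) because the weights
    w_k = 1/(s_k^i s_k^j) are.
    """
    x = np.asarray(beta_i, dtype=float)
    y = np.asarray(beta_j, dtype=float)
    s_i = np.asarray(s_i, dtype=float)
    s_j = np.asarray(s_j, dtype=float)
    if not (x.size == y.size == s_i.size == s_j.size) or x.size < 3:
        raise ValueError("coefficient vectors must share length >= 3")
    if (s_i <= 0).any() or (s_j <= 0).any():
        raise ValueError("shrunken SDs must be strictly positive")
    w = 1.0 / (s_i * s_j)
    r = _weighted_corr(x, y, w)
    if r is None:
        return SimilarityResult(s_m=0.0, r_squared=0.0, slope_sign=0, weights=w, degenerate=True)
    sign = int(np.sign(r))
    return SimilarityResult(s_m=sign * r * r, r_squared=r * r, slope_sign=sign, weights=w)


def similarity_matrix(estimates, config: ShrinkageConfig | None = None) -> pd.DataFrame:
    """Symmetric disease x disease similarity matrix with unit diagonal.

    ``estimates`` maps disease name -> CoefficientEstimate (or any object
    with ``beta_mean`` and ``beta_sd``).  The SD floor m is pooled once
    across all diseases and tissues.
    """
    config = config or ShrinkageConfig()
    names = list(estimates)
    betas, gammas = [], []
    d = None
    for name in names:
        est = estimates[name]
        bm = np.asarray(est.beta_mean, dtype=float)
        sd = np.asarray(est.beta_sd, dtype=float)
        if d is None:
            d = bm.size
        elif bm.size != d:
            raise ValueError("all diseases must share the tissue axis")
        betas.append(bm)
        gammas.append(sd)
    gam = np.asarray(gammas)
    s = np.asarray(shrink_sds(gam, config))
    n = len(names)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            res = disease_similarity(betas[i], betas[j], s[i], s[j])
            M[i, j] = M[j, i] = res.s_m
    return pd.DataFrame(M, index=names, columns=names)


@dataclass
class GeneticCorrEstimate:
    s_g: float
    weights: pd.DataFrame  # (study_a, study_b, w, rg)
    marginal_a: pd.Series
    marginal_b: pd.Series


def combine_genetic_correlation(rg_table: pd.DataFrame, sizes_a, sizes_b) -> GeneticCorrEstimate:
    """Size-weighted combination of per-study genetic correlations.

    ``rg_table`` holds one row per study pair with columns
    ``(study_a, study_b, rg)``; ``sizes_a``/``sizes_b`` map each disease's
    studies to their sample sizes.  Study weights are proportional to sample
    size within each disease; pair weights are products of the marginals.
    Pairs with missing rg are excluded and the weights renormalized.
    """
    sizes_a = pd.Series(sizes_a, dtype=float)
    sizes_b = pd.Series(sizes_b, dtype=float)
    if (sizes_a <= 0).any() or (sizes_b <= 0).any():
        raise ValueError("study sample sizes must be positive")
    wa = sizes_a / sizes_a.sum()
    wb = sizes_b / sizes_b.sum()
    rows = []
    for sa in wa.index:
        for sb in wb.index:
            match = rg_table.loc[
                (rg_table["study_a"] == sa) & (rg_table["study_b"] == sb), "rg"
            ]
            rg = float(match.iloc[0]) if len(match) and pd.notna(match.iloc[0]) else np.nan
            rows.append((sa, sb, wa[sa] * wb[sb], rg))
    df = pd.DataFrame(rows, columns=["study_a", "study_b", "w", "rg"])
    missing = df["rg"].isna()
    if missing.all():
        raise ValueError("no genetic-correlation value available for any study pair")
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} study pairs lack an rg value; weights renormalized",
            stacklevel=2,
        )
        df = df.loc[~missing].copy()
        df["w"] /= df["w"].sum()
    s_g = float(np.sum(df["w"] * df["rg"]))
    return GeneticCorrEstimate(s_g=s_g, weights=df, marginal_a=wa, marginal_b=wb)


def normalize_coefficients(beta) -> np.ndarray:
    """Map a disease's coefficients into [0, 1] for heatmap display.

    x~ = (x - x_min) / x_95 for x <= x_95 and 1 above, clamped to [0, 1],
    where x_95 is the 95% quantile (linear interpolation) of the vector.
    """
    x = np.asarray(beta, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two coefficients")
    x_min = float(x.min())
    x_95 = float(np.quantile(x, 0.95))
    if x_95 <= 0:
        raise ValueError("95% quantile is non-positive; normalization scale undefined")
    out = np.where(x > x_95, 1.0, (x - x_min) / x_95)
    return np.clip(out, 0.0, 1.0)


def cluster_diseases(sim_matrix: pd.DataFrame, k: int, method: str = "average") -> pd.Series:
    """Agglomerative clustering of diseases on distance 1 - s_m.

    Average linkage by default, cut into ``k`` flat clusters (labels 1..k).
    Deterministic for a given matrix.
    """
    n = sim_matrix.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    M = np.asarray(sim_matrix, dtype=float)
    D = 1.0 - (M + M.T) / 2.0
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=sim_matrix.index, name="cluster")


def cluster_specific_tissues(
    normalized: pd.DataFrame,
    labels: pd.Series,
    top_n: int = 5,
    mode: str = "rest",
) -> pd.DataFrame:
    """Rank tissues most specific to each disease cluster.

    For every cluster and tissue, a one-sided rank-sum test asks whether the
    cluster's normalized coefficients exceed those of the comparison group:
    all other diseases (``mode='rest'``) or, per tissue, the other cluster
    with the highest mean normalized coefficient (``mode='strongest_other'``).
    The ``top_n`` tissues with the smallest p per cluster are reported, ties
    broken by median difference.
    """
    if mode not in ("rest", "strongest_other"):
        raise ValueError("mode must be 'rest' or 'strongest_other'")
    labels = labels.reindex(normalized.index)
    clusters = sorted(labels.dropna().unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    rows = []
    for c in clusters:
        inside = normalized.loc[labels == c]
        if len(inside) < 2:
            warnings.warn(f"cluster {c} has fewer than 2 members; tests skipped", stacklevel=2)
            continue
        for tissue in normalized.columns:
            x = inside[tissue].to_numpy()
            if mode == "rest":
                y = normalized.loc[labels != c, tissue].to_numpy()
            else:
                others = [o for o in clusters if o != c]
                means = {o: normalized.loc[labels == o, tissue].mean() for o in others}
                strongest = max(means, key=means.get)
                y = normalized.loc[labels == strongest, tissue].to_numpy()
            if y.size == 0:
                continue
            stat, p = mannwhitneyu(x, y, alternative="greater")
            rows.append((c, tissue, float(p), float(np.median(x) - np.median(y))))
    df = pd.DataFrame(rows, columns=["cluster", "tissue", "p_value", "effect"])
    out = []
    for c, sub in df.groupby("cluster"):
        sub = sub.sort_values(["p_value", "effect"], ascending=[True, False]).head(top_n)
        sub = sub.assign(rank=np.arange(1, len(sub) + 1))
        out.append(sub)
    return pd.concat(out, ignore_index=True)[["cluster", "rank", "tissue", "p_value", "effect"]]


def assign_tissue_cluster(normalized: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Assign each tissue to the cluster with the highest median coefficient.

    Ties go to the lowest cluster index and are flagged.
    """
    labels = labels.reindex(normalized.index)
    clusters = sorted(labels.dropna().unique())
    medians = pd.DataFrame(
        {c: normalized.loc[labels == c].median(axis=0) for c in clusters}
    )
    rows = []
    for tissue in normalized.columns:
        vals = medians.loc[tissue]
        best = vals.max()
        hits = [c for c in clusters if vals[c] == best]
        rows.append((tissue, hits[0], len(hits) > 1))
    return pd.DataFrame(rows, columns=["tissue", "cluster", "tie"])
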