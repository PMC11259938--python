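"""Synthetic benchmark generators.

Everything the other modules consume can be fabricated here with no
download: tissue-score matrices with planted informative tissues, labeled
variant collections at the 1:10 positive:control design, candidate pools
with matching attributes, ontologies with closed-form propagation counts,
and per-disease collections with shared or disjoint tissue supports.

Scores are bounded non-negative Beta draws.  Labels come from the same
logistic model the package fits: the linear predictor combines the planted
baseline effect on the tissue-mean with the planted per-tissue effects, and
the intercept is calibrated by root finding so the expected positive
fraction equals 1 / (1 + n_ctrl_per_pos).  Under a fixed seed every
generator is a pure function of its configuration.

What this does not emulate: real LD structure (LD attributes are
independent Poisson counts), realistic genomic position clustering, or any
correlation between matching attributes and tissue scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_pool",
    "simulate_disease_collection",
    "simulate_ontology",
]

# rough hg19 chromosome lengths (Mb), used only to draw plausible positions
CHROM_MB = np.array(
    [249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135, 134,
     115, 107, 103, 90, 81, 78, 59, 63, 48, 51],
    dtype=float,
)

NONCODING_CLASSES = np.array(
    ["intron_variant", "intergenic_variant", "regulatory_region_variant",
     "3_prime_UTR_variant", "5_prime_UTR_variant", "splice_region_variant"]
)
NONCODING_PROBS = np.array([0.605, 0.258, 0.06, 0.04, 0.02, 0.017])

TEMPORAL_CUTOFF = pd.Timestamp("2016-05-28")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic disease benchmark.

    ``n_pos`` sets the expected number of positives; the total number of
    variants is ``n_pos * (1 + n_ctrl_per_pos)`` with labels drawn from the
    planted logistic model at calibrated prevalence 1/(1 + n_ctrl_per_pos).
    Planted effects are on the logit scale; score noise is Beta(a, b).
    """

    n_pos: int = 200
    n_ctrl_per_pos: int = 10
    d_tissues: int = 127
    planted_support: tuple = ()
    planted_beta: tuple = ()
    baseline_alpha: float = 1.0
    noise_a: float = 2.0
    noise_b: float = 5.0
    n_chromosomes: int = 22
    seed: int = 0

    def __post_init__(self):
        if self.n_ctrl_per_pos < 1:
            raise ValueError("n_ctrl_per_pos must be >= 1")
        if self.baseline_alpha < 0:
            raise ValueError("baseline_alpha must be >= 0")
        support = tuple(self.planted_support)
        if any(s < 0 or s >= self.d_tissues for s in support):
            raise ValueError("planted_support indices must lie in [0, d_tissues)")
        beta = tuple(np.broadcast_to(self.planted_beta, (len(support),)).astype(float)) if support else ()
        object.__setattr__(self, "planted_support", support)
        object.__setattr__(self, "planted_beta", beta)


@dataclass
class SimulatedDataset:
    scores: pd.DataFrame
    labels: pd.Series
    variants: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)
    intercept: float = np.nan

    def __iter__(self):
        return iter((self.scores, self.labels, self.variants))


def _planted_eta(X: np.ndarray, config: SimulationConfig) -> np.ndarray:
    eta = config.baseline_alpha * X.mean(axis=1)
    if config.planted_support:
        eta = eta + X[:, list(config.planted_support)] @ np.asarray(config.planted_beta)
    return eta


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    def gap(a0):
        return expit(a0 + eta).mean() - target

    return brentq(gap, -60.0, 60.0, xtol=1e-10)


def _variant_frame(n: int, rng: np.random.Generator, labels: np.ndarray, n_chromosomes: int) -> pd.DataFrame:
    chrom_w = CHROM_MB[:n_chromosomes] / CHROM_MB[:n_chromosomes].sum()
    chrom_idx = rng.choice(n_chromosomes, size=n, p=chrom_w)
    pos = (rng.random(n) * CHROM_MB[chrom_idx] * 1e6).astype(np.int64) + 1
    dates = TEMPORAL_CUTOFF + pd.to_timedelta(
        rng.integers(-365 * 5, 365 * 5, size=n), unit="D"
    )
    assoc_p = np.where(labels == 1, 10.0 ** (-rng.uniform(5, 12, size=n)), np.nan)
    return pd.DataFrame(
        {
            "id": [f"rs{i:07d}" for i in range(n)],
            "chrom": (chrom_idx + 1).astype(str),
            "pos": pos,
            "maf": rng.uniform(0.01, 0.5, size=n),
            "dist_tss": np.round(10.0 ** rng.uniform(2, 6, size=n)).astype(np.int64),
            "gene_density": rng.poisson(5.0, size=n),
            "ld_partners": rng.poisson(20.0, size=n),
            "ld_block": pd.array([pd.NA] * n),
            "assoc_p": assoc_p,
            "date_added": dates,
            "functional_class": rng.choice(NONCODING_CLASSES, size=n, p=NONCODING_PROBS),
        }
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Scores, labels and variant metadata for one synthetic disease."""
    rng = np.random.default_rng(config.seed)
    n = config.n_pos * (1 + config.n_ctrl_per_pos)
    target = 1.0 / (1 + config.n_ctrl_per_pos)
    X = rng.beta(config.noise_a, config.noise_b, size=(n, config.d_tissues))
    eta = _planted_eta(X, config)
    a0 = _calibrate_intercept(eta, target)
    y = (rng.random(n) < expit(a0 + eta)).astype(int)
    shift = 0.0
    while y.min() == y.max():  # pragma: no cover - vanishingly rare at defaults
        warnings.warn("planted model produced single-class labels; intercept shifted", stacklevel=2)
        shift += 1.0 if y.max() == 0 else -1.0
        y = (rng.random(n) < expit(a0 + shift + eta)).astype(int)
    variants = _variant_frame(n, rng, y, config.n_chromosomes)
    scores = pd.DataFrame(
        X, index=variants["id"], columns=[f"T{k:03d}" for k in range(config.d_tissues)]
    )
    labels = pd.Series(y, index=variants["id"], name="label")
    return SimulatedDataset(scores=scores, labels=labels, variants=variants, config=config, intercept=a0 + shift)


def simulate_pool(n: int, seed: int = 0, n_chromosomes: int = 22, prefix: str = "pool") -> pd.DataFrame:
    """Candidate-pool table of common variants with matching attributes."""
    rng = np.random.default_rng(seed)
    df = _variant_frame(n, rng, np.zeros(n, dtype=int), n_chromosomes)
    df["id"] = [f"{prefix}{i:07d}" for i in range(n)]
    df["assoc_p"] = np.nan
    return df


def simulate_disease_collection(
    n_diseases: int,
    shared_support_groups,
    config: SimulationConfig,
    support_size: int = 3,
    jitter: float = 0.2,
):
    """Per-disease datasets with group-shared, cross-group-disjoint supports.

    ``shared_support_groups`` partitions range(n_diseases); diseases in the
    same group share planted tissues (effect sizes jittered by a uniform
    factor in [1-jitter, 1+jitter]), while different groups get disjoint
    tissue supports.
    """
    groups = [list(g) for g in shared_support_groups]
    flat = sorted(i for g in groups for i in g)
    if flat != list(range(n_diseases)):
        raise ValueError("shared_support_groups must partition range(n_diseases)")
    if len(groups) * support_size > config.d_tissues:
        raise ValueError("disjoint supports exceed the number of tissues")
    rng = np.random.default_rng(config.seed)
    tissue_perm = rng.permutation(config.d_tissues)
    base_beta = (
        np.broadcast_to(config.planted_beta, (support_size,)).astype(float)
        if config.planted_beta
        else np.full(support_size, 4.0)
    )
    datasets = [None] * n_diseases
    for gi, group in enumerate(groups):
        support = tuple(int(t) for t in tissue_perm[gi * support_size : (gi + 1) * support_size])
        for disease in group:
            factor = rng.uniform(1 - jitter, 1 + jitter, size=support_size)
            cfg = SimulationConfig(
                n_pos=config.n_pos,
                n_ctrl_per_pos=config.n_ctrl_per_pos,
                d_tissues=config.d_tissues,
                planted_support=support,
                planted_beta=tuple(base_beta * factor),
                baseline_alpha=config.baseline_alpha,
                noise_a=config.noise_a,
                noise_b=config.noise_b,
                n_chromosomes=config.n_chromosomes,
                seed=int(rng.integers(2**31)),
            )
            datasets[disease] = simulate_dataset(cfg)
    return datasets


def simulate_ontology(
    depth: int,
    branching: int,
    seed: int = 0,
    variants_per_leaf: int = 10,
    shared_fraction: float = 0.0,
):
    """Balanced term tree with variants annotated at the leaves.

    Returns ``(edges, table)``: edges are (child, parent) rows forming a
    tree of the given depth and branching factor; each leaf is annotated
    with ``variants_per_leaf`` variants, of which a ``shared_fraction`` are
    drawn from a common shared pool (exercising set-union semantics during
    propagation).  With disjoint leaves the root receives exactly
    ``branching**depth * variants_per_leaf`` variants after propagation.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    edges = []
    level = ["term_root"]
    for lv in range(depth):
        nxt = []
        for parent in level:
            for b in range(branching):
                child = f"{parent}.{b}"
                edges.append((child, parent))
                nxt.append(child)
        level = nxt
    leaves = level
    n_shared = int(round(shared_fraction * variants_per_leaf))
    shared_pool = [f"sv{i:05d}" for i in range(max(1, n_shared * 2))]
    rows = []
    counter = 0
    for leaf in leaves:
        for _ in range(variants_per_leaf - n_shared):
            rows.append((leaf, f"v{counter:06d}"))
            counter += 1
        if n_shared:
            for vid in rng.choice(shared_pool, size=n_shared, replace=False):
                rows.append((leaf, vid))
    edges_df = pd.DataFrame(edges, columns=["child", "parent"])
    table = pd.DataFrame(rows, columns=["term_id", "variant_id"]).drop_duplicates()
    return edges_df, table
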