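"""Benchmark metrics and comparison machinery.

Performance on a disease's benchmark set (positives + matched controls) is
measured with AUROC and average precision (area under the precision-recall
curve).  Scores are compared pairwise on repeated/bootstrap performance
vectors using the Wilcoxon signed-rank test: a p-value below ``alpha`` calls
a win for the method with the larger mean paired difference, anything else
is a tie.  A binary program selects chromosome hold-out sets that contain a
target fraction of positives while preserving the positive:control balance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, milp
from scipy.stats import norm
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "PerformanceRecord",
    "ComparisonResult",
    "HoldoutSelection",
    "compute_metrics",
    "stratified_subsample_indices",
    "bootstrap_subsample_performance",
    "signed_rank_test",
    "pairwise_compare",
    "tally_comparisons",
    "winning_percentage",
    "select_holdout_chromosomes",
]


@dataclass
class PerformanceRecord:
    auroc: float
    avg_precision: float
    label: str = ""

    def as_tuple(self):
        return (self.auroc, self.avg_precision)


def compute_metrics(scores, labels, label: str = "") -> PerformanceRecord:
    """AUROC (midrank ties) and step-interpolated average precision."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute metrics")
    return PerformanceRecord(
        auroc=float(roc_auc_score(labels, scores)),
        avg_precision=float(average_precision_score(labels, scores)),
        label=label,
    )


def stratified_subsample_indices(labels, B: int = 30, frac: float = 0.90, seed: int = 0):
    """B stratified without-replacement subsamples, each with ``frac`` of
    the positives and ``frac`` of the controls.

    The returned index sets are meant to be shared across all score methods
    under comparison, so that per-subsample differences are paired.
    """
    labels = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n_pos = max(1, int(round(frac * pos.size)))
    n_neg = max(1, int(round(frac * neg.size)))
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(B):
        take = np.concatenate(
            [rng.choice(pos, n_pos, replace=False), rng.choice(neg, n_neg, replace=False)]
        )
        sets.append(np.sort(take))
    return sets


def bootstrap_subsample_performance(
    scores,
    labels,
    B: int = 30,
    frac: float = 0.90,
    seed: int = 0,
    indices=None,
    label: str = "",
):
    """Performance on B stratified 90% subsamples (paired across methods).

    Pass the same ``indices`` (from :func:`stratified_subsample_indices`) for
    every method being compared; when omitted they are generated from
    ``seed``, which gives identical sets for identical seeds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if indices is None:
        indices = stratified_subsample_indices(labels, B=B, frac=frac, seed=seed)
    records = []
    for b, idx in enumerate(indices):
        sub_y = labels[idx]
        if sub_y.min() == sub_y.max():  # pragma: no cover - stratification prevents this
            warnings.warn(f"subsample {b} collapsed to a single class; resampled", stacklevel=2)
            idx = stratified_subsample_indices(labels, B=1, frac=frac, seed=seed + 7919 + b)[0]
            sub_y = labels[idx]
        records.append(compute_metrics(scores[idx], sub_y, label=f"{label}[{b}]"))
    return records


def _exact_signed_rank_p(ranks2: np.ndarray, w2: int) -> float:
    """Two-sided exact p by enumerating the sign-flip distribution of W+.

    ``ranks2`` are doubled midranks (integers), ``w2`` the observed doubled
    positive-rank sum.  Equivalent to scanning all 2^n sign assignments:
    p = P(|W+ - mu| >= |w_obs - mu|) under the uniform sign-flip null.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    mu2 = total / 2.0
    dev = abs(w2 - mu2)
    support = np.arange(total + 1)
    return float(counts[np.abs(support - mu2) >= dev - 1e-9].sum())


def signed_rank_test(differences, exact_max_n: int = 25) -> tuple[float, float]:
    """Wilcoxon signed-rank statistic W+ and two-sided p-value.

    Zero differences are dropped (Wilcoxon convention); |differences| are
    midranked.  For n <= ``exact_max_n`` the p-value is exact under the
    sign-flip null (ties in ranks handled); beyond that a normal
    approximation with tie and continuity corrections is used.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    absd = np.abs(d)
    order = np.argsort(absd, kind="mergesort")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    r = np.arange(1, n + 1, dtype=float)
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = r[i : j + 1].mean()
        i = j + 1
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        return w_plus, _exact_signed_rank_p(ranks2, w2)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return w_plus, 1.0
    dev = abs(w_plus - mu)
    z = (dev - 0.5) / math.sqrt(var)  # continuity correction
    return w_plus, float(min(1.0, 2.0 * norm.sf(z)))


@dataclass
class ComparisonResult:
    score_a: str
    score_b: str
    p_value: float
    outcome: str  # win_a | win_b | tie
    mean_difference: float
    n: int
    unit: str = "disease"

    @property
    def winner(self):
        return {"win_a": self.score_a, "win_b": self.score_b}.get(self.outcome)


def pairwise_compare(perf_a, perf_b, alpha: float = 0.05, name_a: str = "a", name_b: str = "b", unit: str = "disease") -> ComparisonResult:
    """Paired Wilcoxon comparison of two performance vectors.

    Outcome is a tie when p >= ``alpha``; otherwise the winner is the method
    with the larger mean paired difference.  Antisymmetric by construction.
    """
    a = np.asarray(perf_a, dtype=float)
    b = np.asarray(perf_b, dtype=float)
    if a.size != b.size:
        raise ValueError("performance vectors must be paired (equal length)")
    d = a - b
    _, p = signed_rank_test(d)
    mean_d = float(d.mean())
    if p >= alpha or mean_d == 0:
        outcome = "tie"
    else:
        outcome = "win_a" if mean_d > 0 else "win_b"
    return ComparisonResult(
        score_a=name_a, score_b=name_b, p_value=p, outcome=outcome, mean_difference=mean_d, n=a.size, unit=unit
    )


def winning_percentage(wins: int, losses: int):
    """100 * wins / (wins + losses), rounded to the nearest integer.

    Undefined (None) when there are neither wins nor losses.
    """
    total = wins + losses
    if total == 0:
        return None
    return int(round(100.0 * wins / total))


def tally_comparisons(results) -> pd.DataFrame:
    """Per-method wins/losses/ties and winning percentage over comparisons."""
    tallies: dict[str, dict] = {}

    def bucket(name):
        return tallies.setdefault(name, {"wins": 0, "losses": 0, "ties": 0})

    for res in results:
        a, b = bucket(res.score_a), bucket(res.score_b)
        if res.outcome == "tie":
            a["ties"] += 1
            b["ties"] += 1
        elif res.outcome == "win_a":
            a["wins"] += 1
            b["losses"] += 1
        else:
            a["losses"] += 1
            b["wins"] += 1
    rows = []
    for name, t in tallies.items():
        rows.append(
            (name, t["wins"], t["losses"], t["ties"], winning_percentage(t["wins"], t["losses"]))
        )
    df = pd.DataFrame(rows, columns=["score", "wins", "losses", "ties", "winning_percentage"])
    return df.sort_values(["wins", "score"], ascending=[False, True]).reset_index(drop=True)


@dataclass
class HoldoutSelection:
    selected: np.ndarray  # boolean per chromosome
    objective: float
    coefficients: np.ndarray
    w_plus: np.ndarray
    w_minus: np.ndarray
    budget: float

    @property
    def chromosomes(self):
        return list(np.flatnonzero(self.selected) + 1)

    @property
    def positive_fraction(self) -> float:
        return float(self.w_plus[self.selected].sum())


def select_holdout_chromosomes(w_plus, w_minus, budget: float = 0.20) -> HoldoutSelection:
    """Choose hold-out chromosomes by exact binary linear programming.

    Maximizes sum_i c_i x_i with c_i = w+_i - |w+_i - w-_i| subject to
    sum_i w+_i x_i <= budget and x binary, where w+_i / w-_i are the
    fractions of positive / control variants on chromosome i.  The objective
    rewards covering positives on chromosomes whose class balance mirrors
    the overall 1:n design.
    """
    w_plus = np.asarray(w_plus, dtype=float)
    w_minus = np.asarray(w_minus, dtype=float)
    if budget < 0:
        raise ValueError("budget must be >= 0")
    if (w_plus < 0).any() or (w_minus < 0).any():
        raise ValueError("chromosome fractions must be non-negative")
    c = w_plus - np.abs(w_plus - w_minus)
    n = c.size
    res = milp(
        c=-c,  # milp minimizes
        constraints=[LinearConstraint(w_plus, -np.inf, budget)],
        integrality=np.ones(n),
        bounds=(0, 1),
    )
    if res.status != 0:  # pragma: no cover - feasible by construction (x = 0)
        raise RuntimeError(f"holdout LP failed: {res.message}")
    x = np.round(res.x).astype(bool)
    return HoldoutSelection(
        selected=x,
        objective=float(c[x].sum()),
        coefficients=c,
        w_plus=w_plus,
        w_minus=w_minus,
        budget=budget,
    )
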