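"""Disease-specific tissue weighting via constrained ridge logistic regression.

For one disease term, each variant i carries a vector ``x_i`` of accessibility
scores across ``d`` tissue/cell-type contexts and a binary label ``y_i``
(disease-associated vs. matched control).  The model is

    logit p_i = a0 + a * xbar_i + beta' x_i,      a >= 0,

where ``xbar_i`` is the variant's mean score over all tissues (the
disease-agnostic baseline) and ``beta`` holds the disease-specific tissue
weights.  Fitting minimizes the class-weighted mean negative log-likelihood
plus a ridge penalty ``(lam/2) * ||beta||^2``; the intercept and the baseline
coefficient are never penalized, and the baseline coefficient is bounded
below by zero so that in the strong-regularization limit the model degrades
gracefully to the tissue-mean baseline rather than inverting it.

Features are standardized internally (per-column center/scale) before
penalization; reported coefficients are always on the original score scale.
The regularization strength is chosen by maximizing cross-validated AUROC
over a log-spaced grid, and held-out variant scores come from nested
cross-validation so that no variant influences the fit that scores it.

The statsmodels-style entry points are :class:`TissueWeightedLogit` and
:class:`TissueWeightedLogitResults`; the module-level functions expose the
same operations functionally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConvergenceError",
    "ModelFit",
    "CoefficientEstimate",
    "NestedCVResult",
    "TissueWeightedLogit",
    "TissueWeightedLogitResults",
    "tissue_mean_score",
    "fit_penalized_logistic",
    "default_lambda_grid",
    "select_lambda",
    "nested_cv_scores",
    "repeated_cv_performance",
    "estimate_coefficients",
    "score_positions",
]

GRAD_TOL = 1e-7
BIN_SIZE = 25


class ConvergenceError(RuntimeError):
    """Raised when the penalized fit fails to reach the gradient tolerance."""


def tissue_mean_score(X) -> np.ndarray:
    """Per-variant mean score across tissues: the disease-agnostic baseline."""
    X = np.asarray(X, dtype=float)
    return X.mean(axis=1)


def _class_weights(y: np.ndarray) -> np.ndarray:
    """Per-observation weights n / (2 * n_class); both classes get total n/2."""
    n = y.size
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for fitting")
    w = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w


@dataclass
class ModelFit:
    """A fitted model: (a0, a, beta) on the original feature scale."""

    intercept: float
    baseline_coef: float
    tissue_coefs: np.ndarray
    lam: float
    class_weights: dict
    feature_scaling: dict
    converged: bool = True
    n_iter: int = 0
    grad_norm: float = np.nan
    tissue_ids: list | None = None

    def linear_predictor(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + self.baseline_coef * X.mean(axis=1) + X @ self.tissue_coefs

    def predict_proba(self, X) -> np.ndarray:
        return expit(self.linear_predictor(X))

    def coef_series(self) -> pd.Series:
        idx = self.tissue_ids or [f"t{i}" for i in range(self.tissue_coefs.size)]
        return pd.Series(self.tissue_coefs, index=idx, name="beta")


class _Problem:
    """Standardized design shared by all fits on one (X, y) instance.

    Column layout of the augmented design: [1 | xbar | tissues...], with the
    first two coefficients unpenalized and the baseline bounded at zero.
    """

    def __init__(self, X, y, class_weighted=True, standardize=True):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (variants x tissues)")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite entries")
        n, d = X.shape
        self.n, self.d = n, d
        self.y = y
        self.w = _class_weights(y) if class_weighted else np.ones(n)
        xbar = X.mean(axis=1)
        cols = np.column_stack([xbar, X])
        if standardize:
            self.center = cols.mean(axis=0)
            sd = cols.std(axis=0)
            self.scale = np.where(sd > 0, sd, 1.0)
        else:
            self.center = np.zeros(d + 1)
            self.scale = np.ones(d + 1)
        Z = (cols - self.center) / self.scale
        self.A = np.column_stack([np.ones(n), Z])
        self.penalty_mask = np.zeros(d + 2)
        self.penalty_mask[2:] = 1.0
        self.bounds = [(None, None), (0.0, None)] + [(None, None)] * d

    def objective(self, theta, lam):
        eta = self.A @ theta
        # stable log(1 + e^eta) = log1p(e^-|eta|) + max(eta, 0); one exp call
        t = np.exp(-np.abs(eta))
        nll = np.sum(self.w * (np.log1p(t) + np.maximum(eta, 0.0) - self.y * eta)) / self.n
        pen = 0.5 * lam * np.sum((self.penalty_mask * theta) ** 2)
        p = np.where(eta >= 0, 1.0, t) / (1.0 + t)
        resid = self.w * (p - self.y)
        grad = self.A.T @ resid / self.n + lam * self.penalty_mask * theta
        return nll + pen, grad

    def solve(self, lam, theta0=None, maxiter=1000, gtol=GRAD_TOL):
        if theta0 is None:
            theta0 = np.zeros(self.d + 2)
        res = minimize(
            self.objective,
            theta0,
            args=(lam,),
            method="L-BFGS-B",
            jac=True,
            bounds=self.bounds,
            options={"maxiter": maxiter, "maxfun": 10 * maxiter, "ftol": 1e-14, "gtol": gtol},
        )
        # projected-gradient norm at the solution
        _, g = self.objective(res.x, lam)
        g_proj = g.copy()
        at_bound = (res.x[1] <= 0.0) & (g[1] > 0)
        if at_bound:
            g_proj[1] = 0.0
        gnorm = float(np.max(np.abs(g_proj)))
        if gnorm > max(1e-6, 10 * gtol) and not res.success:
            raise ConvergenceError(
                f"penalized logistic fit did not converge: |grad|={gnorm:.2e}, "
                f"iters={res.nit}, message={res.message}"
            )
        return res.x, res.nit, gnorm

    def to_fit(self, theta, lam, nit, gnorm, tissue_ids=None) -> ModelFit:
        a0_s, rest = theta[0], theta[1:]
        coef_orig = rest / self.scale
        intercept = a0_s - float(np.sum(rest * self.center / self.scale))
        w_pos = float(self.w[self.y == 1][0]) if (self.y == 1).any() else 1.0
        w_neg = float(self.w[self.y == 0][0]) if (self.y == 0).any() else 1.0
        return ModelFit(
            intercept=intercept,
            baseline_coef=float(coef_orig[0]),
            tissue_coefs=coef_orig[1:].copy(),
            lam=float(lam),
            class_weights={1: w_pos, 0: w_neg},
            feature_scaling={"center": self.center.copy(), "scale": self.scale.copy()},
            converged=True,
            n_iter=int(nit),
            grad_norm=gnorm,
            tissue_ids=list(tissue_ids) if tissue_ids is not None else None,
        )

    def lambda_max(self) -> float:
        """Strong-regularization anchor for the grid.

        A ridge penalty never zeroes beta exactly, so the anchor is 100 times
        the largest absolute component of the null-model gradient of the
        unpenalized weighted NLL over the penalized columns, which empirically
        drives ||beta||_inf well below 1e-4 on standardized features.
        """
        ybar = np.sum(self.w * self.y) / np.sum(self.w)
        g = self.A[:, 2:].T @ (self.w * (ybar - self.y)) / self.n
        gmax = float(np.max(np.abs(g)))
        return 100.0 * gmax if gmax > 0 else 1.0

    def path(self, lambdas, theta0=None, gtol=GRAD_TOL):
        """Warm-started fits along a descending lambda path."""
        thetas = np.empty((len(lambdas), self.d + 2))
        theta = np.zeros(self.d + 2) if theta0 is None else theta0.copy()
        for i, lam in enumerate(lambdas):
            theta, _, _ = self.solve(lam, theta, gtol=gtol)
            thetas[i] = theta
        return thetas


def fit_penalized_logistic(
    X,
    y,
    lam: float,
    class_weighted: bool = True,
    standardize: bool = True,
    tissue_ids=None,
) -> ModelFit:
    """Fit the constrained ridge logistic model at a fixed penalty."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    prob = _Problem(X, y, class_weighted=class_weighted, standardize=standardize)
    theta, nit, gnorm = prob.solve(lam)
    if tissue_ids is None and isinstance(X, pd.DataFrame):
        tissue_ids = list(X.columns)
    return prob.to_fit(theta, lam, nit, gnorm, tissue_ids=tissue_ids)


def default_lambda_grid(X, y, n_lambda: int = 100, ratio: float = 1e-4, class_weighted=True, standardize=True):
    prob = _Problem(X, y, class_weighted=class_weighted, standardize=standardize)
    lmax = prob.lambda_max()
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def _rank_auc(y, scores) -> float:
    """AUROC as the midrank statistic; identical to the trapezoidal ROC area."""
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _stratified_kfold(y, folds, seed):
    counts = np.bincount(np.asarray(y, dtype=int), minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"cannot build {folds} stratified folds with class counts {counts.tolist()}"
        )
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))


def select_lambda(
    X_train,
    y_train,
    folds: int = 5,
    lambda_grid=None,
    seed: int = 0,
    n_lambda: int = 100,
    class_weighted: bool = True,
    standardize: bool = True,
    full_output: bool = False,
):
    """Pick the penalty maximizing mean cross-validated AUROC.

    The grid runs from a strong-regularization anchor down by a 1e-4 factor;
    on ties the larger lambda (more parsimonious model) wins.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(
            X_train, y_train, n_lambda=n_lambda, class_weighted=class_weighted, standardize=standardize
        )
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    if lambda_grid.size == 1:
        return (float(lambda_grid[0]), np.ones(1)) if full_output else float(lambda_grid[0])
    skf = _stratified_kfold(y_train, folds, seed)
    aucs = np.zeros((folds, lambda_grid.size))
    for k, (tr, va) in enumerate(skf.split(X_train, y_train)):
        prob = _Problem(X_train[tr], y_train[tr], class_weighted=class_weighted, standardize=standardize)
        # model selection tolerates a looser solve than the final fit
        thetas = prob.path(lambda_grid, gtol=1e-5)
        Xva = X_train[va]
        cols = np.column_stack([Xva.mean(axis=1), Xva])
        Ava = np.column_stack(
            [np.ones(len(va)), (cols - prob.center) / prob.scale]
        )
        etas = Ava @ thetas.T
        yva = y_train[va]
        for j in range(lambda_grid.size):
            aucs[k, j] = _rank_auc(yva, etas[:, j])
    means = aucs.mean(axis=0)
    best = int(np.flatnonzero(means == means.max())[0])  # grid descending: tie -> larger lam
    lam = float(lambda_grid[best])
    if full_output:
        return lam, means
    return lam


@dataclass
class NestedCVResult:
    scores: np.ndarray
    fold_of: np.ndarray
    fits: list
    lams: list

    def __iter__(self):  # convenience unpacking: scores, fits
        return iter((self.scores, self.fits))


def nested_cv_scores(
    X,
    y,
    outer_folds: int = 5,
    inner_folds: int = 5,
    seed: int = 0,
    lambda_grid=None,
    n_lambda: int = 100,
    class_weighted: bool = True,
    standardize: bool = True,
) -> NestedCVResult:
    """Held-out predicted probabilities from nested stratified CV.

    The inner loop picks the penalty on each outer training split; the outer
    model is then fit at that penalty and scores only its own held-out fold,
    so every variant receives exactly one score it never influenced.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = _stratified_kfold(y, outer_folds, seed)
    scores = np.full(y.size, np.nan)
    fold_of = np.full(y.size, -1)
    fits, lams = [], []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        lam = select_lambda(
            X[tr],
            y[tr],
            folds=inner_folds,
            lambda_grid=lambda_grid,
            seed=seed + 1000 * (k + 1),
            n_lambda=n_lambda,
            class_weighted=class_weighted,
            standardize=standardize,
        )
        fit = fit_penalized_logistic(
            X[tr], y[tr], lam, class_weighted=class_weighted, standardize=standardize
        )
        scores[te] = fit.predict_proba(X[te])
        fold_of[te] = k
        fits.append(fit)
        lams.append(lam)
    return NestedCVResult(scores=scores, fold_of=fold_of, fits=fits, lams=lams)


def repeated_cv_performance(
    X,
    y,
    repeats: int = 30,
    seed: int = 0,
    **cv_kwargs,
):
    """One (AUROC, average precision) record per repeated nested-CV run."""
    from .evaluation import compute_metrics

    records = []
    seeds = _spawn_seeds(seed, repeats)
    for r in range(repeats):
        res = nested_cv_scores(X, y, seed=int(seeds[r]), **cv_kwargs)
        rec = compute_metrics(res.scores, y, label=f"repeat={r}")
        records.append(rec)
    return records


def _spawn_seeds(seed, k):
    return np.random.SeedSequence(seed).generate_state(k) % (2**31)


@dataclass
class CoefficientEstimate:
    """Mean and SD of tissue coefficients over repeated-CV training fits."""

    beta_mean: np.ndarray
    beta_sd: np.ndarray
    n_fits: int
    coefs: pd.DataFrame = field(repr=False)
    baseline_coefs: np.ndarray | None = None
    lams: np.ndarray | None = None
    tissue_ids: list | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.tissue_ids or [f"t{i}" for i in range(self.beta_mean.size)]
        return pd.DataFrame(
            {"beta_mean": self.beta_mean, "beta_sd": self.beta_sd}, index=pd.Index(idx, name="tissue")
        )


def estimate_coefficients(
    X,
    y,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    inner_folds: int = 5,
    lambda_grid=None,
    n_lambda: int = 100,
    class_weighted: bool = True,
    standardize: bool = True,
    tissue_ids=None,
) -> CoefficientEstimate:
    """Coefficient uncertainty from folds x repeats training-split refits.

    Each cross-validation training split (4/5 of the data at defaults) gets
    its own penalty via :func:`select_lambda` and contributes one coefficient
    vector; at the defaults of 5 folds and 10 repeats this yields 50 vectors
    whose elementwise mean and SD summarize the tissue weights.
    """
    if tissue_ids is None and isinstance(X, pd.DataFrame):
        tissue_ids = list(X.columns)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    seeds = _spawn_seeds(seed, repeats)
    archive, alphas, lams = [], [], []
    for r in range(repeats):
        if folds == 1:
            splits = [np.arange(y.size)]  # degenerate mode: full data once
        else:
            skf = _stratified_kfold(y, folds, seeds[r])
            splits = [tr for tr, _ in skf.split(X, y)]
        for tr in splits:
            lam = select_lambda(
                X[tr],
                y[tr],
                folds=inner_folds,
                lambda_grid=lambda_grid,
                seed=int(seeds[r]) + len(lams),
                n_lambda=n_lambda,
                class_weighted=class_weighted,
                standardize=standardize,
            )
            fit = fit_penalized_logistic(
                X[tr], y[tr], lam, class_weighted=class_weighted, standardize=standardize
            )
            archive.append(fit.tissue_coefs)
            alphas.append(fit.baseline_coef)
            lams.append(lam)
    arr = np.asarray(archive)
    beta_mean = arr.mean(axis=0)
    beta_sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    cols = tissue_ids or [f"t{i}" for i in range(arr.shape[1])]
    return CoefficientEstimate(
        beta_mean=beta_mean,
        beta_sd=beta_sd,
        n_fits=arr.shape[0],
        coefs=pd.DataFrame(arr, columns=cols),
        baseline_coefs=np.asarray(alphas),
        lams=np.asarray(lams),
        tissue_ids=list(cols),
    )


def score_positions(fit: ModelFit, tracks, positions: pd.DataFrame, bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Disease scores at genomic positions from fixed-resolution tracks.

    Each 1-based position maps to bin ``(pos - 1) // bin_size``; the model is
    applied to the per-tissue track values of that bin.  Positions outside
    track bounds get NaN with a warning.
    """
    chroms = positions["chrom"].astype(str).to_numpy()
    pos = positions["pos"].to_numpy()
    bins = (pos - 1) // bin_size
    out = np.full(len(positions), np.nan)
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        V = tracks.values(chrom, bins[mask])  # (n, d), NaN out of bounds
        row_ok = np.isfinite(V).all(axis=1)
        sub = np.flatnonzero(mask)
        if (~row_ok).any():
            warnings.warn(
                f"{int((~row_ok).sum())} positions on chromosome {chrom} fall outside "
                "track bounds; scored as NaN",
                stacklevel=2,
            )
        if row_ok.any():
            out[sub[row_ok]] = fit.predict_proba(V[row_ok])
    res = positions[["chrom", "pos"]].copy()
    res["bin"] = bins
    res["score"] = out
    return res


class TissueWeightedLogit:
    """Statsmodels-style front end for the disease-specific tissue model.

    Parameters
    ----------
    y : array-like of {0, 1}
        Disease-association labels (1 = disease-associated, 0 = control).
    X : array-like or DataFrame, shape (n_variants, d_tissues)
        Non-negative tissue/context scores per variant.
    """

    def __init__(self, y, X, tissue_ids=None, variant_ids=None, standardize=True, class_weighted=True):
        if isinstance(X, pd.DataFrame):
            tissue_ids = tissue_ids or list(X.columns)
            variant_ids = variant_ids if variant_ids is not None else list(X.index)
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree on the number of variants")
        self.tissue_ids = tissue_ids or [f"t{i}" for i in range(self.X.shape[1])]
        self.variant_ids = variant_ids
        self.standardize = standardize
        self.class_weighted = class_weighted

    @classmethod
    def from_dataframe(cls, scores: pd.DataFrame, labels, **kwargs) -> "TissueWeightedLogit":
        labels = pd.Series(labels)
        if set(labels.index) == set(scores.index) and len(labels) == len(scores):
            labels = labels.reindex(scores.index)
        return cls(labels.to_numpy(), scores, **kwargs)

    def _kw(self):
        return dict(class_weighted=self.class_weighted, standardize=self.standardize)

    def tissue_mean(self) -> np.ndarray:
        return tissue_mean_score(self.X)

    def select_lambda(self, folds=5, lambda_grid=None, seed=0, n_lambda=100, full_output=False):
        return select_lambda(
            self.X, self.y, folds=folds, lambda_grid=lambda_grid, seed=seed,
            n_lambda=n_lambda, full_output=full_output, **self._kw()
        )

    def fit(self, lam=None, folds=5, seed=0, lambda_grid=None, n_lambda=100) -> "TissueWeightedLogitResults":
        """Fit at ``lam``; when ``lam`` is None it is chosen by CV first."""
        if lam is None:
            lam = self.select_lambda(folds=folds, seed=seed, lambda_grid=lambda_grid, n_lambda=n_lambda)
        mf = fit_penalized_logistic(self.X, self.y, lam, tissue_ids=self.tissue_ids, **self._kw())
        return TissueWeightedLogitResults(self, mf)

    def nested_cv(self, outer_folds=5, inner_folds=5, seed=0, lambda_grid=None, n_lambda=100) -> NestedCVResult:
        return nested_cv_scores(
            self.X, self.y, outer_folds=outer_folds, inner_folds=inner_folds,
            seed=seed, lambda_grid=lambda_grid, n_lambda=n_lambda, **self._kw()
        )

    def repeated_cv(self, repeats=30, seed=0, **cv_kwargs):
        return repeated_cv_performance(self.X, self.y, repeats=repeats, seed=seed, **cv_kwargs)

    def estimate_coefficients(self, folds=5, repeats=10, seed=0, **kwargs) -> CoefficientEstimate:
        return estimate_coefficients(
            self.X, self.y, folds=folds, repeats=repeats, seed=seed,
            tissue_ids=self.tissue_ids, **{**self._kw(), **kwargs}
        )


class TissueWeightedLogitResults:
    """Fit results: coefficient estimates, predictions, and a summary table."""

    def __init__(self, model: TissueWeightedLogit, fit: ModelFit):
        self.model = model
        self.fit = fit

    @property
    def params(self) -> pd.Series:
        vals = np.concatenate([[self.fit.intercept, self.fit.baseline_coef], self.fit.tissue_coefs])
        idx = ["intercept", "tissue_mean"] + list(self.model.tissue_ids)
        return pd.Series(vals, index=idx, name="coef")

    @property
    def lam(self) -> float:
        return self.fit.lam

    def predict(self, X=None) -> np.ndarray:
        X = self.model.X if X is None else np.asarray(X, dtype=float)
        return self.fit.predict_proba(X)

    def performance(self):
        from .evaluation import compute_metrics

        return compute_metrics(self.predict(), self.model.y, label="in-sample")

    def summary(self, top: int = 10) -> str:
        n, d = self.model.X.shape
        n_pos = int(self.model.y.sum())
        beta = self.fit.coef_series()
        lines = [
            "Tissue-weighted logistic model",
            "=" * 46,
            f"n variants:        {n} ({n_pos} positive / {n - n_pos} control)",
            f"n tissues:         {d}",
            f"lambda:            {self.fit.lam:.6g}",
            f"intercept (a0):    {self.fit.intercept:+.4f}",
            f"baseline coef (a): {self.fit.baseline_coef:+.4f}  (constrained >= 0)",
            f"||beta||_2:        {np.linalg.norm(self.fit.tissue_coefs):.4f}",
            "-" * 46,
            f"top {min(top, d)} tissues by |coefficient|:",
        ]
        top_beta = beta.reindex(beta.abs().sort_values(ascending=False).index[:top])
        for name, val in top_beta.items():
            lines.append(f"  {name:<20} {val:+.4f}")
        return "\n".join(lines)
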