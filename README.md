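# dscore — disease-specific prioritization of non-coding variants

Most non-coding variant scores are *organism-level*: one number per variant,
regardless of the disease being studied. But disease-associated regulatory
variants tend to act through specific tissues and cell types, so a score that
knows which tissues matter for a disease can separate disease-associated
variants from matched controls better than a disease-agnostic summary.

`dscore` learns that tissue weighting. For one disease term, each variant
*i* carries a vector **x**ᵢ ∈ ℝᵈ of chromatin-accessibility (DNase I
hypersensitivity) scores across *d* tissue/cell-type contexts, and a label
*yᵢ* ∈ {0, 1} (disease-associated vs. matched control). The model is a
constrained ridge logistic regression

    logit p_i = α₀ + α·x̄_i + β′x_i ,   α ≥ 0,

where x̄ᵢ is the variant's mean score across all tissues (the disease-agnostic
baseline) and **β** holds disease-specific tissue weights. The fit minimizes
the class-weighted negative log-likelihood plus (λ/2)‖β‖²; α₀ and α are never
penalized, and the bound α ≥ 0 guarantees that as λ → ∞ the model degrades to
the tissue-mean baseline instead of inverting it. λ is chosen by maximizing
cross-validated AUROC; held-out variant scores come from nested
cross-validation.

Around this core the package provides, for users working with GWAS-catalog
style association tables:

- **inventory** — non-coding/QC filtering (MAF, HLA region), ontology
  propagation of variant annotations from specific to general disease terms,
  LD-block grouping with representative-SNP selection, and temporal
  train/test splits with a 1 kb exclusion radius;
- **matching** — matched-control selection (random, TSS-bin, SNPsnap-style
  attribute matching) with global control uniqueness and a per-pair audit;
- **evaluation** — AUROC / average precision, paired Wilcoxon signed-rank
  win/loss/tie comparisons (exact at small n), stratified 90% subsampling,
  and an exact binary-LP chromosome hold-out selector;
- **similarity** — disease–disease similarity as the signed squared weighted
  correlation of tissue-coefficient vectors (weights from shrunken
  coefficient SDs), genetic-correlation combination across studies,
  hierarchical disease clustering, and cluster-specific tissue tests;
- **synthetic** — generators for every input above, with planted tissue
  supports and the 1:10 positive:control design, so the whole pipeline is
  testable offline.

## Worked example

```python
import numpy as np
from dscore import TissueWeightedLogit, SimulationConfig, simulate_dataset
from dscore.evaluation import compute_metrics
from dscore.model import nested_cv_scores, tissue_mean_score

cfg = SimulationConfig(n_pos=200, n_ctrl_per_pos=10, d_tissues=20,
                       planted_support=(3, 7, 11), planted_beta=(4.0, 4.0, 4.0),
                       seed=1)
ds = simulate_dataset(cfg)

m = TissueWeightedLogit.from_dataframe(ds.scores, ds.labels)
res = m.fit(n_lambda=20, seed=0)          # lambda chosen by 5-fold CV AUROC
print(res.summary(top=5))

cv = nested_cv_scores(ds.scores.to_numpy(), ds.labels.to_numpy(),
                      seed=0, n_lambda=20)
perf = compute_metrics(cv.scores, ds.labels.to_numpy())
base = compute_metrics(tissue_mean_score(ds.scores.to_numpy()),
                       ds.labels.to_numpy())
print(f"held-out  AUROC {perf.auroc:.3f}  AP {perf.avg_precision:.3f}")
print(f"baseline  AUROC {base.auroc:.3f}  AP {base.avg_precision:.3f}")
```

Output:

```
Tissue-weighted logistic model
==============================================
n variants:        2200 (207 positive / 1993 control)
n tissues:         20
lambda:            0.034887
intercept (a0):    -5.4701
baseline coef (a): +17.1530  (constrained >= 0)
||beta||_2:        5.9619
----------------------------------------------
top 5 tissues by |coefficient|:
  T007                 +3.4390
  T011                 +3.0960
  T003                 +2.8329
  T019                 -1.0379
  T005                 -0.9001

held-out  AUROC 0.798  AP 0.308
baseline  AUROC 0.659  AP 0.163
```

The three planted informative tissues (T003, T007, T011) carry the largest
weights, and the held-out average precision of the tissue-weighted score
(0.308) roughly doubles the disease-agnostic tissue-mean baseline (0.163);
a random scorer on this 1:10 design would sit near the prevalence, ≈ 0.09.

A `dscore` command-line tool mirrors the library (`dscore simulate`,
`inventory`, `match`, `fit`, `score`, `evaluate`, `compare`, `holdout`,
`similarity`, `clusters`); run `dscore --help`.

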