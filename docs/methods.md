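# Methods

## The model

For one disease term, variants are observations. Variant *i* has tissue
scores **x**ᵢ ∈ ℝᵈ (non-negative, one per tissue/cell-type context; 127
contexts in the Roadmap-style setting, arbitrary *d* in general), a
tissue-mean x̄ᵢ = (1/d)Σₖ xᵢₖ, and a label yᵢ (1 = disease-associated,
0 = matched control, with controls outnumbering positives ≈ 10:1).

    logit p_i = α₀ + α·x̄_i + β′x_i ,   α ≥ 0.

The tissue-mean column is the disease-agnostic baseline score; giving it its
own unpenalized, sign-constrained coefficient means strong regularization
(λ → ∞) drives β → 0 and the model's ranking collapses onto the tissue-mean
ranking rather than onto noise or an inverted baseline. The fit minimizes

    (1/n) Σ_i w_i [log(1 + e^{η_i}) − y_i η_i] + (λ/2)‖β‖²

with per-observation class weights wᵢ = n/(2·n_class), so both classes carry
total weight n/2. Only β is penalized. A printed ½ factor sometimes attached
to the log-likelihood in this model family is a pure rescaling of λ and is
absorbed into the grid.

### Numerics

- Features (the tissue columns and the x̄ column) are standardized
  internally (center/scale per column); coefficients are reported on the
  original scale. Standardizing before an L2 penalty is the convention of
  the widely used elastic-net solvers and makes λ comparable across tissues.
- The solver is L-BFGS-B with an analytic gradient and the single bound
  α ≥ 0. Final fits require a projected-gradient max-norm ≤ 1e-6 on the
  standardized problem; non-convergence raises with diagnostics. Fits done
  only to rank λ values during model selection use a relaxed 1e-5 tolerance,
  which does not measurably move the selected λ but roughly halves the cost.
- λ grid: ridge never sends β exactly to zero, so the strong end of the grid
  is anchored at 100 × the largest absolute component of the null-model
  gradient over the penalized columns — empirically this drives ‖β‖∞ well
  below 1e-4 — and the grid descends log-uniformly over a 1e-4 ratio
  (100 points by default). Grid resolution is a parameter; large benchmark
  runs in the test suite use 12–20 points, which is visually dense on the
  flat CV-AUROC curves these problems produce.
- λ selection maximizes mean stratified 5-fold CV AUROC along a
  warm-started descending path; exact ties resolve to the larger λ
  (parsimony). Under pure-noise features the CV-AUROC curve is flat to
  within fold noise, so the argmax is driven by that noise — selection is
  then arbitrary but harmless, since all grid points generalize at chance.
- Nested cross-validation (5 outer × 5 inner folds, stratified, shuffled
  with isolated seeds) gives each variant exactly one held-out probability;
  repeated CV (default 30 repeats with distinct fold seeds) summarizes
  performance as the mean over repeats.

### Coefficient uncertainty

Tissue-weight uncertainty comes from refitting on the training side of
5-fold CV repeated 10 times: 50 training splits, each with its own
CV-selected λ, each contributing one coefficient vector. The elementwise
mean β̄ and SD γ over the 50 vectors are the disease's coefficient estimate.
A degenerate mode (folds = 1, repeats = 1) exists for testing and yields a
zero SD.

## Matched controls

Controls are drawn from a pool of common (MAF ≥ 1%) non-coding variants that
do not appear in the association catalog. Four strategies: uniform draws;
TSS-distance quantile bins (pool sorted by distance to the nearest
protein-coding TSS, 50 equal-count bins, draw from the positive's bin); and
attribute matching on MAF, gene density, TSS distance and LD-partner count
with maximum relative deviations (5%, 50%, 20%, 50%), or TSS distance alone
(the other tolerances set to 100, i.e. 10,000%, effectively unconstrained).
Relative deviation is |a_ctrl − a_pos| / a_pos; at a_pos = 0 exact equality
is required (division guard). Controls are globally unique: positives claim
candidates greedily in a seeded random order (the claim order is otherwise
arbitrary, so it is randomized and reproducible). Positives with no
candidate are dropped and recorded; every returned pair carries its
attribute deviations in an audit table.

## Evaluation machinery

AUROC uses midranks; average precision is the step-interpolated area under
the precision–recall curve. Note that AP carries a positive O(1/n_pos)
small-sample bias under a random scorer (one positive among ten controls has
E[AP] = mean reciprocal rank ≈ 0.27, not the prevalence 0.09); at a few
hundred positives the bias is below rounding resolution.

Score comparisons use the two-sided Wilcoxon signed-rank test on paired
performance vectors (repeats or 90% stratified subsamples shared across the
methods being compared). Zeros are dropped, tied magnitudes midranked; for
n ≤ 25 the p-value is exact under the sign-flip null
(p = P(|W⁺ − μ| ≥ |w_obs − μ|), computed by dynamic programming over the
doubled midranks — equivalent to enumerating all 2ⁿ sign assignments);
beyond that, a normal approximation with tie and continuity corrections.
p ≥ 0.05 is a tie, otherwise the method with the larger mean paired
difference wins. Winning percentage is 100·wins/(wins+losses), rounded, and
undefined when there are no decisions.

Chromosome hold-out sets are chosen by an exact binary linear program:
maximize Σ cᵢxᵢ with cᵢ = wᵢ⁺ − |wᵢ⁺ − wᵢ⁻| subject to Σ wᵢ⁺xᵢ ≤ budget
(default 0.20), where wᵢ⁺/wᵢ⁻ are per-chromosome fractions of positives and
controls. A literal budget of zero would force the empty set, so the budget
is an explicit parameter with the 20% default the objective is designed
around. Solved with HiGHS (scipy `milp`); optimality is certified by the
solver status and cross-checked against exhaustive enumeration in tests.

## Disease similarity

For diseases *i*, *j* with coefficient means β⁽ⁱ⁾, β⁽ʲ⁾ and SDs γ⁽ⁱ⁾, γ⁽ʲ⁾,
per-tissue SDs are shrunk toward a pooled floor, sₖ = mix·γₖ + (1 − mix)·m
with mix = 3/4 and m the 25% quantile (linear interpolation) of all SDs
pooled across diseases and tissues; pooling across everything (rather than
per pair) keeps weights comparable across the similarity matrix, and a
per-pair mode is available. The similarity is the signed squared weighted
Pearson correlation with weights wₖ = 1/(sₖⁱsₖʲ). This equals the
r² of the weighted regression of one vector on the other, signed by the
slope, but — because the weights are symmetric in (i, j) — the correlation
form removes the regression direction ambiguity. With constant weights it
reduces to sign(r)·r² of the plain Pearson correlation. Diseases with
degenerate (zero weighted variance) coefficients get similarity 0 with a
flag.

Per-study genetic correlations are combined into one value per disease pair
with weights proportional to study sample sizes within each disease
(pair weight = product of the marginal weights); missing study pairs are
excluded and the weights renormalized.

For display and cluster analyses, a disease's coefficients are normalized as
x̃ = (x − x_min)/x₉₅ below the 95% quantile and 1 above it, clamped to
[0, 1] (the clamp matters when x_min < 0 pushes the ratio above 1 below the
quantile branch). Diseases are clustered by average-linkage agglomeration on
distance 1 − s_m (linkage is configurable; the cut level k is a parameter,
7 in the reference analyses). Cluster-specific tissues come from one-sided
rank-sum tests of a cluster's normalized coefficients against all other
diseases (default) or, alternatively, against the other cluster with the
highest mean coefficient for that tissue — the comparison group is
genuinely ambiguous, so both are implemented and the cluster-vs-rest form
is the default. Each tissue is assigned to the cluster with the highest
median normalized coefficient, ties to the lowest cluster index with a
flag.

## Synthetic benchmarks

The generator emulates the study conditions end to end: tissue scores are
Beta(2, 5) draws on [0, 1]; the linear predictor adds a baseline effect
(default α = 1) on the tissue-mean and planted per-tissue effects (default
4.0 on the logit scale, roughly 0.6 logits per SD of a score column) on a
chosen support; the intercept is calibrated by root finding so the expected
positive fraction is exactly 1/(1 + n_ctrl_per_pos) (1/11 at the 1:10
default), and labels are Bernoulli draws from the resulting probabilities.
Variant metadata uses MAF ~ U(0.01, 0.5), TSS distance log-uniform over
10²–10⁶ bp, gene density ~ Poisson(5), LD partners ~ Poisson(20),
chromosome allocation proportional to physical chromosome lengths, and
reporting dates spread ±5 years around a mid-2016 cutoff so temporal splits
are exercised. Disease collections share planted supports within groups
(effect sizes jittered ±20%) and are disjoint across groups.

What the generator does *not* emulate: LD correlation structure between
variants (attributes are independent), spatial clustering of associations,
correlation between matching attributes and tissue scores, or realistic
tissue–tissue score correlation. Passing tests therefore demonstrate the
statistical machinery — recovery of planted tissue supports, calibration of
the baseline, correctness of the bookkeeping — not performance on real
epigenomes.

## Problem sizes in the test suite

The planted-support recovery check runs at the benchmark scale of 2,000
positives + 20,000 controls and 50 tissues over 10 seeds with a 12-point λ
grid; other simulation-based tests use a few hundred to a few thousand
variants with 4–20 grid points. These sizes are the package's own choices:
dense enough that the flat parts of the CV curves are resolved, small enough
that the full suite runs in minutes.

## Known limitations

- The ridge path is computed by warm-started refitting, not a closed-form
  path; extremely small λ on near-separable data converges slowly.
- Exact signed-rank p-values are limited to n ≤ 25 (the DP is quadratic in
  the doubled rank sum); beyond that the corrected normal approximation is
  used.
- Track access assumes a fixed 25 bp grid; bigWig input is averaged into
  that grid and requires pyBigWig.
- The similarity statistic compares coefficient vectors elementwise; it has
  no notion of related-but-distinct tissues (a blood/blood pair counts no
  more than any other matching pair).
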