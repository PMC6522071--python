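# Methods

## Model

Each bulk sample is modeled as `y = Xβ + τ + ε` with `β ≥ 0`: `X` is the
signature matrix of reference expression for `p` cell types over `n`
marker genes (linear, non-log scale), `τ` a sparse vector whose non-zero
entries mark outlier genes, and `ε` zero-mean noise.  The estimator is
least trimmed squares with the trimming count chosen adaptively, solved by
non-negative least squares (Lawson–Hanson, via `scipy.optimize.nnls`) on
the retained genes.  Because β is an unnormalized regression coefficient,
it tracks absolute cell abundance; relative composition is obtained by
dividing by the total, and is reported as undefined (not NaN) when every
score is zero.

## The adaptive trimming iteration

Residuals are always recomputed over **all** `n` observations from the
current coefficient vector (`r = y − Xβ̂`), and `r_med` is the median of
`|r|` over all `n` — not over the retained subset.  The overestimate
update counts `|rᵢ| > r_med` at the first iteration (no `k` factor) and
`min(#{|rᵢ| > k·r_med}, previous)` afterwards, with strict inequality at
the threshold.  The underestimate starts at `⌈α₁·N̄⌉` and is updated as
`min(⌈α₂·N̲⌉, N̄)`.  The `N̲` observations of largest `|r|` are removed
and the model refit; removal sets are recomputed fresh each iteration, and
ties among equal `|r|` break toward the lowest row index, so the whole
procedure is deterministic.  The loop terminates when the two estimates
meet, which happens within `⌊−log α₁ / log α₂⌋ + 2` iterations; the
implementation also hard-stops at that bound (`converged=False`), a safety
net that the property tests show never triggers.

Degenerate cases:

* if `r_med` falls below `1e-12 · max(1, median|y|)` the fit is declared
  exact and trimming stops — otherwise a perfect fit would flag arbitrary
  observations;
* `N̲` is clamped so at least `p + 1` rows are always retained (a warning
  is logged when the clamp binds); when more than `n − p − 1` observations
  genuinely look outlying, the overestimate may stay above the clamp and
  the fit reports non-convergence rather than an identifiable answer;
* an optional intercept column (for unknown content such as tumor
  transcription) is sign-unconstrained: under NNLS it is encoded as a
  `+1/−1` column pair so only the cell-type coefficients are constrained.

An OLS mode (`nonneg=False`) exists because the trimming theory is stated
for unconstrained least squares; the deconvolution path always uses NNLS.

## Choosing k

`k` is tuned per sample by minimizing
`BIC*(k) = m·log(Σ dᵢ²/m) + b·(log m + 1)` with `m = n − N̂` and
`b = N̂ + p + 1`, over a grid from 1.0 to 10.0 in steps of 0.1.
Cross-validation is deliberately not offered: held-out folds of
contaminated data contain outliers themselves.

Two discrepancy scales are implemented. `log_scale` (the deconvolution
default) takes `dᵢ = log yᵢ − log ŷᵢ`, consistent with log-normally
distributed expression errors; values are clamped at
`ε = 1e-6 × max|data|` before the log because NNLS returns exact zeros.
`raw_scale` takes `dᵢ = yᵢ − ŷᵢ` and is the correct likelihood when errors
are additive on the raw scale — the regression benchmark (below) therefore
scores with it.  An exact fit yields a `−∞` criterion; such ties resolve
toward the fewest parameters.  Remaining exact ties — common, because
neighboring grid points often trim the identical gene set and hence have
identical BIC* — resolve toward the smallest `k`, i.e. the first minimum
met when scanning the grid upward.  Grid points whose fits retain no
observations are skipped rather than raised.

Within one tuning sweep, NNLS solutions are cached by the removed-index
set, since many `k` values follow identical trimming paths; this is purely
an optimization and the tests assert cached and fresh fits agree exactly.

## Pipeline

Gene matching between signature and mixture is exact string match after
case folding; duplicate ids on either side are first collapsed by
arithmetic mean, and row order follows the signature.  Fewer than `2p`
shared genes is a hard error; matching less than 25% of the signature
logs a warning, as does a mixture whose maximum is below 50 (likely
log-transformed input — the model expects linear scale).  Optional
quantile normalization (classic form: each column's sorted values replaced
by across-column means of sorted values, tied ranks receiving averaged
reference values) is computed across all mixture columns **before** gene
intersection, and is off by default; it is intended for microarray-style
mixtures.  Samples are processed independently, so column permutations
permute results and one sample's failure never aborts the rest.

## Synthetic-data generators

**Regression design.** `X = U·Σ^{1/2}` with `U` iid uniform(0, 20) and Σ
the equicorrelation matrix with unit diagonal and off-diagonal ρ = 0.5
(the square root is the symmetric eigendecomposition root, keeping the
`U·Σ^{1/2}` form literal).  Defaults: n = 500, p = 20, β* iid
uniform(0, 1), errors standard normal or t(3) (an `error_scale` switch
permits exact-model checks).  A fraction `f` of responses receives
vertical outliers from a non-central t (df 1, ncp 30, so essentially all
planted outliers are far from zero); 20% of those rows, rounded to the
nearest integer, become leverage points with the whole predictor row
redrawn from N(2·max(X), 1), where max(X) is taken before replacement.

**Signature-based mixtures.** Per-cell-type abundances are iid
uniform(0, 1) — deliberately not summing to one.  The clean mixture
`X·B` receives additive noise `2^z`, `z ~ N(0, (0.1·log₂ s)²)` with `s`
the per-sample clean standard deviation (`|log₂ s|` fallback for `s ≤ 1`);
a fraction `i/50` of each sample's gene entries (`i ∈ 0..25`) is replaced
by `2^w`, `w ~ N(10, (0.3·log₂ s)²)` (median 1024).  Noise is additive by
default with a multiplicative switch for sensitivity checks.  The
unknown-content spike blends `(1−f)·immune + f·tumor` per sample, then
applies the same noise form; `f = 1` is rejected (no immune signal left).

**Synthetic signature.** Since curated references are platform downloads,
tests use a block-marker stand-in: each of `p` cell types gets
`markers_per_type` disjoint genes at high expression (2^N(8, 0.5²))
against a common low background (2^N(3, 1²)).  This emulates the
marker-dominated structure of leukocyte signature matrices but is cleaner
than real references: real marker genes overlap between related subsets
(e.g. naive vs memory T cells), making real designs worse conditioned.
Passing tests on this stand-in therefore demonstrate the algorithm, not
performance on any particular curated signature.

All generators take an integer seed and are bit-reproducible.

## Benchmark and problem sizes

The outlier-recovery benchmark draws 50 replicates per outlier fraction in
{5%, 10%, 20%, 30%} at n = 500, p = 20, tunes `k` per replicate over the
full 0.1-step grid, and averages detection TPR/FPR and the selected `k`.
Under both error models the mean TPR is 1 at every fraction (to three
decimals) and the mean selected `k` decreases monotonically with the
contamination level — heavier contamination demands higher sensitivity.
The whole study runs in well under a minute thanks to the tuning cache.

The mixture sweep in the tests uses a 300-gene, 4-type synthetic
signature with contamination steps `i ∈ {1, 5, 13, 20}` (2%–40% of
entries).  `i = 25` — exactly half the data replaced — is the least
trimmed squares breakdown boundary: on this design some replaced entries
(~2^10) fall inside the clean marker expression range and are formally
unidentifiable, degrading SSE by roughly two orders of magnitude. The
sweep therefore stops below the boundary, which is a property of the
estimator class, not of the implementation.

## Known limitations

* Signature choice and platform matching are the caller's responsibility;
  no curated signature ships with the package and no platform translation
  or batch correction is attempted.
* No significance testing of deconvolution results (permutation p-values)
  and no sparsity penalties on β.
* Above ~50% contamination the trimmed estimator breaks down by
  construction (see above).
* Expression inputs must be linear scale; only a heuristic warning guards
  against log-transformed matrices.
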