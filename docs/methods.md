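# Methods

## Model and assumptions

Every captured mRNA molecule is tagged with a UMI; after exact-match
collapsing on `(cell barcode, UMI, gene)` each molecule carries a read
count ≥ 1.  Ambiguously mapped molecules (multi-gene) are discarded before
any analysis.  The per-gene copies-per-UMI (CU) histogram `h(i)` pools
molecules across all cells in the dataset; the working assumption is that
a gene amplifies similarly in all cells of the population.  This is also
the model's main vulnerability: when a gene's amplification differs
strongly between cell subpopulations, its pooled histogram is a mixture
and the single-distribution fit degrades (the rational-function estimator,
which is distribution-free, degrades more gracefully than the ZTNB there).

Unseen-molecule estimation treats sequencing as incomplete sampling of an
amplified pool: molecules with zero sampled reads exist but are invisible.
All three estimators answer "how many distinct molecules would be observed
if total reads were multiplied by `t + 1`", from `h(i)` alone.

## Zero-truncated negative binomial fit

Read counts per molecule are modeled NB(μ, s) in the mean/size
parameterization, `pmf(0) = (s/(s+μ))^s` (the convention of R's
`dnbinom`).  The zero bin is missing data and is handled by EM:

* E-step: `L = N / (1 − pmf(0; μ, s))`, `z = L·pmf(0; μ, s)`,
  `μ = Σ i·h(i) / L`.
* M-step: maximize `ll(s) = Σ_{i≥0} h(i)·ln pmf(i; μ, s)` over `s` (the
  completed histogram includes `h(0) = z`), with L-BFGS-B and the analytic
  gradient `pd(s) = Σ h(i)·ψ(i+s)/L − ψ(s) + ln s − ln(s+μ)` (ψ the
  digamma function).

Starting values are μ = 0.5, s = 1; iteration stops when the relative
change of `ll` drops below `tol = 1e-4` (default; a loose tolerance trades
a negligible likelihood difference for speed) or after `max_iter = 1000`
iterations.

Two numerical choices matter here.  First, `L` and `μ` are mutually
dependent, so the E-step iterates their update to self-consistency (to
1e-12 relative) before each size update.  Updating `s` against a zero bin
imputed from stale parameters can make the completed histogram look
*under*-dispersed and drives `s` to the Poisson boundary — a spurious
stationary point with strictly worse observed likelihood; the
self-consistent ordering avoids that basin while leaving every formula
unchanged.  Second, because the M-step objective is scaled per molecule
(1/L), its gradients are small and the optimizer's tolerances are
tightened (`ftol = 1e-14`, `gtol = 1e-12`) so it does not stop on its
first evaluation.

After convergence `L` is recomputed from the final (μ, s), which makes
`predict(t)` = `L(1 − pmf(0; μ(t+1), s))` hit the algebraic fixed point
`predict(0) = N` (returned exactly, bypassing one rounding).
Extrapolation assumes the size parameter is depth-invariant and the mean
proportional to reads — exactly true under binomial thinning of NB counts.

Degenerate histograms — fewer than 2 distinct copy levels or fewer than
`min_molecules = 20` molecules — raise an error instead of fitting;
pipeline callers leave such genes uncorrected.  Prediction from lowly
expressed genes is intrinsically unreliable, which also motivates the
100-CPM floor used before dataset comparisons.

## Good–Toulmin and the rational-function estimator

Good–Toulmin predicts `U(t) = −Σ (−t)^i h(i)` new molecules.  It is exact
in expectation under binomial thinning but alternates in sign, so it is
restricted to `t ≤ 1` unless explicitly overridden; when the sum
undershoots, the prediction is clamped at zero distinct molecules and
flagged.

The rational-function estimator truncates the histogram at copy level
`mt` (default 2), forms the series `S(t) = Σ_{j≤mt} (−1)^{j+1} h(j) t^j =
t·P(t)`, and replaces `P` by its Padé approximant (denominator degree
`⌊J/2⌋` first, where `J` is the number of series coefficients).  An
approximant is rejected — and the degree reduced — if its denominator has
a real pole in `(0, t]`, if it produces non-finite or negative values, or
if it is not monotone on a geometric grid up to `t`; exhausting all
degrees raises an error.  For `t` beyond 1e6 the analytic asymptote of
`t·P(t)/Q(t)` replaces naive evaluation (with `mt = 2` the approximant is
`h₁t/(1 + (h₂/h₁)t)` and the asymptote adds `h₁²/h₂` new molecules).
Truncation at 2 discards little: the first two bins carry most of the
unseen-molecule signal, and higher bins mostly add series instability.

## Count-matrix correction and pooling

Per-gene predictions `c_g` (pooled over all cells) become corrected gene
totals `m_g = (T/P)·c_g`, applied by scaling each row of the matrix so its
sum equals `m_g`.  Since `P = Σ c_g`, the corrected grand total equals the
observed `T` exactly — corrected matrices are directly CPM-comparable.
`m_g` is implemented as a corrected row *total* (not a bare multiplier):
that is the only reading under which `Σ m_g = T` holds and CPM values stay
consistent.  Corrected entries are fractional; an optional flag rounds
them for integer-only downstream tools.

Sparse genes can borrow saturation information from other datasets: each
source dataset is summarized per gene by its single- and double-copy
fractions (FSCM = h(1)/N, FDCM = h(2)/N) and UMI count.  Source fractions
are quantile-normalized (all quantiles, linear interpolation) to the
target's distribution to remove depth differences, then pooled as
UMI-weighted means including the target itself.  The pooled values form a
3-bin histogram `{1: FSCM·n, 2: FDCM·n, 3: (1−FSCM−FDCM)·n}` with `n` the
target's gene UMIs, fed to the rational-function estimator with `mt = 2`
(which only ever uses the first two bins — the reason the 3-bin summary
suffices).  The third fraction is floored at zero with renormalization
when normalization pushes FSCM + FDCM above 1.

## Binomial downsampling batch correction

For two datasets with shared amplification but different depth, the deeper
one is thinned analytically: a molecule with `i` reads retains `j` with
probability `Binom(j; i, x)`, so `h′(j) = Σᵢ Binom(j; i, x)·h(i)` and the
expected survivors are `n = Σ_{j≥1} h′(j) = Σᵢ h(i)(1 − (1−x)^i)`.  This
is the expectation of random read subsampling with the noise integrated
out; it conserves reads exactly (`Σ j·h′(j) = x·Σ i·h(i)`) and composes
multiplicatively (`x₁` then `x₂` equals `x₁·x₂`).  Per-gene CPM before and
after thinning give row scale factors `f_g = e_a/e_b` for the deep matrix.
Unlike embedding-based batch correction this removes only the technical,
depth-driven component.

With `x = "auto"`, `x` is scanned over {0.01, …, 1.00} (step 0.01) and the
value maximizing the CCC of the two mean-log₂(CPM+1) profiles is chosen,
smallest `x` on ties.  The scan assumes the pair shares biology; genes
with large true differential expression bias the objective, so a known
depth ratio should be passed directly when available.

## Metrics

Expression profiles are mean counts across cells, CPM-normalized; when an
expression floor is applied, CPM is recomputed over the surviving genes.
Comparisons use `l = log₂(CPM + 1)`.  Lin's concordance correlation
coefficient is computed with population (1/n) moments — fixed here so
tests are exact; sample-moment variants differ by O(1/n).  The
edge case of two identical constant vectors is defined as 1.  AUCs are
Mann–Whitney U statistics normalized by `n₁·n₀`, ties counted ½.

## The simulator

`simulate_gene` draws per-molecule read counts i.i.d. NB(mean, size);
`simulate_dataset` allocates molecules to cells (uniform multinomial by
default), assigns 12-mer UMIs (redrawn on within-group collision; an error
is raised if the collision risk in any (cell, gene) group exceeds 1%), and
thins reads binomially to the requested depth.  Zero-read molecules are
recorded in the ground truth but invisible downstream — precisely the
unseen molecules.

Defaults are this package's choice of a realistic droplet-style regime:
amplification means log-uniform on [0.5, 16] copies per UMI at depth
(spanning near-unsequenced to fully saturated genes), size 1, and for the
differential-expression benchmark 150 gene pairs with true expression
log-uniform on [500, 8000] molecules, fold change 2, DE direction
randomized so CPM totals stay balanced.  The benchmark's batch regime
scales the second gene's amplification by the depth ratio and corrects
with binomial downsampling at that known ratio (the CCC-driven choice of
`x` is exercised by the dataset-level correction, where no true DE
distorts the grid).

What the simulator does *not* emulate: cell-type structure, ambient RNA,
doublets, UMI sequencing errors (error correction is out of scope;
collapsing is exact-match), GC/length-dependent amplification, or
empirical amplification distributions from real datasets — users with
per-gene saturation tables can plug in their own samplers.  Passing tests
therefore show correctness of the estimators and corrections under the
stated amplification model, not robustness to every artifact of real
libraries.

## Problem sizes and tolerances

The validation suite uses 50,000-molecule histograms for parameter
recovery (mean within 5%, size within 10%, library size within 2%),
ten-fold extrapolation from a 10% thinning (within 5% of the realized
full-depth count), 100-gene × 50-cell dataset pairs for batch correction
(CCC must improve; auto-selected `x` within 0.1 of the true ratio 0.5),
and 150-pair benchmarks for the AUC comparisons.  These sizes are large
enough that Monte-Carlo error is well inside each tolerance while the
whole suite stays fast.  Conservation identities are checked to 1e-9
relative; analytic-vs-Monte-Carlo comparisons to 3 standard errors over
50 replicates.

## Known limitations

* Histograms that are mixtures across subpopulations violate the ZTNB
  assumption; predictions for such genes are biased (prefer the
  rational-function estimator, or pool within clusters).
* Library-size estimates from very shallow data (mean copies/UMI ≪ 1) are
  weakly identified; the estimate can deviate tens of percent even when
  the fit is the true maximum-likelihood solution.
* No confidence intervals on predictions.
* Estimation quality scales with molecule count, so correction accuracy
  favors highly expressed genes; downstream analyses should keep the
  uncorrected counts alongside.
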