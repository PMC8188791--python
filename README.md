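# umiseen

Unseen-molecule estimation and amplification-bias correction for UMI-based
single-cell RNA-seq.

## The problem

Unique molecular identifiers (UMIs) let single-cell protocols collapse PCR
duplicates: every distinct `(cell, UMI, gene)` triple counts as one
molecule, however many reads it received.  Collapsing removes duplicate
*reads*, but not the bias that appears when differentially amplified
molecules are pooled into one library and sequenced incompletely.  A gene
whose molecules amplify strongly has almost all of them sequenced at least
once; a gene that amplifies poorly leaves many molecules with zero reads —
invisible after collapsing.  In extreme cases the observed abundances of
two genes *invert* relative to their true molecule counts (the pooled
amplification paradox).  The same mechanism creates batch effects between
datasets sequenced to different depths and can fabricate cell-type marker
genes.

`umiseen` treats this as an unseen-species problem.  The only input per
gene is its copies-per-UMI (CU) histogram `h(i)` — the number of molecules
observed with exactly `i` read copies, pooled over all cells.  It is aimed
at anyone quantifying UMI count matrices: pipeline authors who want
corrected matrices, and methods people who want the estimators themselves.

## Estimators

With `N = Σ h(i)` observed molecules and reads scaled by `t + 1`:

* **Good–Toulmin**: `U(t) = −Σᵢ (−t)ⁱ h(i)` new molecules.
  Distribution-free, accurate for `t ≤ 1`, unstable beyond.
* **Zero-truncated negative binomial (ZTNB)**: read counts per molecule are
  modeled NB(μ, s); the zero bin is missing data.  An EM fit estimates
  the library size `L = N / (1 − pmf(0; μ, s))` and the zero bin
  `z = L·pmf(0)`, updates `μ = Σ i·h(i)/L`, and maximizes the completed
  log-likelihood over `s` with L-BFGS-B.  Extrapolation holds `s` fixed and
  scales the mean: `L (1 − pmf(0; μ(t+1), s))`.
* **Rational-function (Preseq-style, "DS")**: the Good–Toulmin power series
  built from the histogram truncated at copy level `mt` (default 2) is
  stabilized by a Padé approximant, with pole checks and degree back-off.
  Makes no distributional assumption; finite at `t → ∞`.

Count matrices are corrected by scaling each gene's row to
`m_g = (T/P)·c_g` where `c_g` is the predicted molecule count, `T` the
observed grand total and `P = Σ c_g`, so the corrected matrix conserves `T`
and stays CPM-consistent.  For batch correction of a deep/shallow dataset
pair, the deeper dataset's histograms are *binomially downsampled*
analytically — `h′(j) = Σᵢ Binom(j; i, x)·h(i)` — which yields expected
molecule losses without sampling noise; the retained-read fraction `x` can
be scanned to maximize Lin's concordance correlation coefficient (CCC)
between the pair.  A simulator with per-gene negative-binomial
amplification provides ground truth for everything.

## Worked example

```python
import numpy as np
from umiseen import ztnb_fit, ds_predict
from umiseen.simulate import simulate_gene, histogram_from_counts

# a gene with 50,000 true molecules, amplified NB(mean=2, size=1),
# sequenced at one tenth of the reads
full = simulate_gene(50_000, nb_mean=2.0, nb_size=1.0, seed=42)
thinned = np.random.default_rng(0).binomial(full, 0.1)
h = histogram_from_counts("Ubb-like", thinned)

fit = ztnb_fit(h)
print(f"observed molecules  N = {h.n_molecules:.0f}")
print(f"fitted mean         mu = {fit.mu_:.3f}   size s = {fit.size_:.3f}")
print(f"library size        L = {fit.total_molecules_:.0f}  (unseen z = {fit.unseen_:.0f})")
print(f"predicted at 10x    {fit.predict(9.0):.0f}")
print(f"rational function   {ds_predict(h, 9.0).distinct_molecules:.0f}")
print(f"actually seen at full depth: {(full > 0).sum()}")
```

prints

```
observed molecules  N = 8375
fitted mean         mu = 0.235   size s = 1.468
library size        L = 42758  (unseen z = 34383)
predicted at 10x    32248
rational function   33183
actually seen at full depth: 33369
```

From 8,375 observed molecules at one tenth of the reads, both estimators
predict the 33,369 molecules actually seen at full depth to within a few
percent — the 25,000 molecules that UMI collapsing alone would silently
miss.

The same pipeline is available from the shell:

```bash
umiseen simulate --n-genes 50 --n-cells 20 --seed 1 \
    --out-table mol.tsv --out-truth truth.tsv --out-spec spec.txt
umiseen hist --table mol.tsv --out-hist cu.tsv \
    --out-mtx counts.mtx --out-genes genes.tsv --out-barcodes barcodes.tsv
umiseen predict --hist cu.tsv --method ztnb --t 9 --out pred.tsv
umiseen correct --mtx counts.mtx --genes genes.tsv --barcodes barcodes.tsv \
    --predictions pred.tsv --out-mtx corrected.mtx \
    --out-genes genes2.tsv --out-barcodes barcodes2.tsv
```

Other subcommands: `fscm` (saturation metrics), `downsample` (binomial
downsampling batch correction), `compare` (CCC/MSE between matrices).

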