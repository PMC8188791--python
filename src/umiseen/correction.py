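"""Count-matrix correction, histogram pooling, and binomial downsampling.

Two corrections are supported:

* **Unseen-molecule scaling** — per-gene predicted molecule counts ``c_g``
  are turned into corrected gene totals ``m_g = (T/P) c_g`` (``T`` the
  observed grand total, ``P = sum c_g``), so the corrected matrix keeps the
  original grand total and is CPM-consistent.
* **Binomial downsampling** — for batch correction of two datasets with
  shared amplification but different depth, the deeper dataset's histograms
  are analytically thinned (each read survives with probability ``x``),
  giving expected molecule losses without sampling noise; per-gene CPM
  ratios before/after become row scale factors.

Histogram pooling lets sparse genes borrow saturation information
(single-/double-copy fractions) from other datasets, after quantile
normalization to the target's saturation distribution.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import binom, rankdata

from .estimators import ds_predict, good_toulmin, ztnb_fit, ztnb_predict
from .exceptions import DegenerateHistogramError, EstimatorUnstableError
from .histograms import saturation_metrics
from .metrics import ccc, mean_expression_profile, to_cpm
from .types import (
    CountMatrix,
    CUHistogram,
    CorrectionResult,
    DownsampleCorrection,
    DSConfig,
    GenePrediction,
    PooledHistogramSource,
)

log = logging.getLogger(__name__)

_METHOD_ALIASES = {
    "gt": "good_toulmin",
    "good_toulmin": "good_toulmin",
    "ztnb": "ztnb",
    "ds": "ds",
}


# ---------------------------------------------------------------------------
# unseen-molecule correction (m_g scaling)
# ---------------------------------------------------------------------------

def predict_gene_counts(
    hists: Mapping[str, CUHistogram],
    method: str = "ztnb",
    t: float = 0.0,
    mt: int = 2,
    allow_extrapolation: bool = True,
) -> Dict[str, GenePrediction]:
    """Predict molecule counts for every gene, pooled across all cells.

    Genes whose histogram is degenerate (or for which no stable rational
    approximant exists) fall back to their observed count and are flagged
    ``applied=False``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    try:
        method = _METHOD_ALIASES[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; use gt, ztnb or ds") from None

    out: Dict[str, GenePrediction] = {}
    for gene, h in hists.items():
        try:
            if method == "good_toulmin":
                res = good_toulmin(h, t, allow_extrapolation=allow_extrapolation)
            elif method == "ztnb":
                res = ztnb_predict(ztnb_fit(h), t)
            else:
                res = ds_predict(h, t, DSConfig(mt=mt))
            out[gene] = GenePrediction(c=res.distinct_molecules, applied=True)
        except (DegenerateHistogramError, EstimatorUnstableError):
            out[gene] = GenePrediction(c=h.n_molecules, applied=False)
    return out


def apply_correction(
    matrix: CountMatrix,
    predictions: Mapping[str, Union[float, GenePrediction]],
    method: str = "",
    t: Optional[float] = None,
) -> Tuple[CountMatrix, CorrectionResult]:
    """Rescale each gene row so its total equals ``m_g = (T/P) c_g``.

    Every gene in the matrix must have a prediction (uncorrected genes
    contribute their observed count).  The corrected grand total equals the
    observed total ``T`` exactly, so downstream CPM values are directly
    comparable.  A prediction below the observed count signals a caller bug
    and is warned about, but the factor is still applied.
    """
    preds: Dict[str, GenePrediction] = {}
    for g, v in predictions.items():
        preds[g] = v if isinstance(v, GenePrediction) else GenePrediction(float(v), True)
    missing = [g for g in matrix.gene_ids if g not in preds]
    if missing:
        raise ValueError(f"no prediction for gene(s): {missing[:5]} ...")

    T = matrix.total_umis
    c = np.array([preds[g].c for g in matrix.gene_ids])
    P = float(c.sum())
    m = (T / P) * c if P > 0 else np.zeros_like(c)

    row_totals = matrix.gene_totals().to_numpy()
    low = c < row_totals * (1 - 1e-12)
    if low.any():
        warnings.warn(
            f"{int(low.sum())} gene(s) predicted below their observed count; "
            "estimators only add molecules — check the caller",
            stacklevel=2,
        )
    factors = np.ones_like(m)
    nz = row_totals > 0
    factors[nz] = m[nz] / row_totals[nz]
    corrected = CountMatrix(
        sp.diags(factors) @ matrix.values, matrix.gene_ids, matrix.cell_barcodes
    )
    per_gene = pd.DataFrame(
        {
            "c": c,
            "m": m,
            "applied": [preds[g].applied for g in matrix.gene_ids],
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    return corrected, CorrectionResult(per_gene=per_gene, T=T, P=P, method=method, t=t)


# ---------------------------------------------------------------------------
# pooled histograms from other datasets
# ---------------------------------------------------------------------------

def make_pool_source(
    dataset_id: str, hists: Mapping[str, CUHistogram]
) -> PooledHistogramSource:
    """Summarize a dataset's histograms into per-gene (fscm, fdcm, n_umis)."""
    rows = {}
    for gene, h in hists.items():
        if h.n_molecules == 0:
            continue
        m = saturation_metrics(h)
        rows[gene] = (m.fscm, m.fdcm, m.n_umis)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["fscm", "fdcm", "n_umis"]
    )
    df.index.name = "gene"
    return PooledHistogramSource(dataset_id=dataset_id, per_gene=df)


def quantile_normalize(source, target) -> np.ndarray:
    """Map values through the source ECDF to the target quantile function.

    Each source value keeps its rank; its magnitude is replaced by the
    target's empirical quantile at that rank (linear interpolation between
    order statistics).  With equal lengths the output's order statistics
    equal the target's.
    """
    source = np.asarray(source, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if source.size == 0 or target.size == 0:
        raise ValueError("source and target must be nonempty")
    ranks = rankdata(source, method="average") - 1.0
    p = ranks / max(source.size - 1, 1)
    return np.quantile(target, p)


def normalize_source_to_target(
    source: PooledHistogramSource, target: PooledHistogramSource
) -> PooledHistogramSource:
    """Quantile-normalize a source's saturation fractions toward the target.

    Datasets sequenced to different saturation have shifted FSCM/FDCM
    distributions; normalization makes the source's fractions comparable to
    the target's before pooling.
    """
    df = source.per_gene.copy()
    for col in ("fscm", "fdcm"):
        df[col] = quantile_normalize(df[col].to_numpy(), target.per_gene[col].to_numpy())
    return PooledHistogramSource(source.dataset_id, df, normalized=True)


def pool_histograms(
    target: PooledHistogramSource,
    sources: Iterable[PooledHistogramSource],
) -> Dict[str, CUHistogram]:
    """Pool saturation fractions into 3-bin histograms for the target's genes.

    Pooled FSCM/FDCM are UMI-weighted means over the target and all sources
    carrying the gene (sources are quantile-normalized to the target first
    if they are not already).  The third bin stands for "more than two
    copies": FMCM = 1 - FSCM - FDCM, floored at 0 with renormalization.
    The output histogram is ``{1: fscm*n, 2: fdcm*n, 3: fmcm*n}`` with
    ``n`` the gene's UMI count in the target, ready for the
    rational-function estimator at mt=2.
    """
    normed: List[PooledHistogramSource] = []
    for s in sources:
        normed.append(s if s.normalized else normalize_source_to_target(s, target))

    frames = [target.per_gene] + [s.per_gene for s in normed]
    stacked = pd.concat(frames, keys=range(len(frames)))
    weights = stacked["n_umis"]
    wsum = weights.groupby(level=1).sum()
    fscm = (stacked["fscm"] * weights).groupby(level=1).sum() / wsum
    fdcm = (stacked["fdcm"] * weights).groupby(level=1).sum() / wsum

    out: Dict[str, CUHistogram] = {}
    for gene in target.per_gene.index:
        f, d = float(fscm.loc[gene]), float(fdcm.loc[gene])
        f, d = max(f, 0.0), max(d, 0.0)
        m = 1.0 - f - d
        if m < 0:  # normalization can push fscm+fdcm above 1
            total = f + d
            f, d, m = f / total, d / total, 0.0
        n = float(target.per_gene.loc[gene, "n_umis"])
        out[gene] = CUHistogram(gene, {1: f * n, 2: d * n, 3: m * n})
    return out


# ---------------------------------------------------------------------------
# binomial downsampling
# ---------------------------------------------------------------------------

def binomial_downsample_hist(
    h: CUHistogram, x: float
) -> Tuple[CUHistogram, float]:
    """Analytically thin a histogram: each read survives with probability x.

    ``h'(j) = sum_i Binom(j; i, x) h(i)``; molecules landing at j=0 are the
    expected loss.  Returns the (fractional) surviving histogram and the
    surviving molecule count ``n = sum_{j>=1} h'(j)``.  Reads are conserved
    in expectation: ``sum j h'(j) = x sum i h(i)``.
    """
    if not 0 < x <= 1:
        raise ValueError("x must be in (0, 1]")
    copies, counts = h.as_arrays()
    if copies.size == 0:
        return CUHistogram(h.gene, {}), 0.0
    j_max = int(copies.max())
    j = np.arange(1, j_max + 1)
    # pmf matrix: rows j, columns i
    pmf = binom.pmf(j[:, None], copies[None, :], x)
    h_new = pmf @ counts
    counts_new = {int(jj): float(v) for jj, v in zip(j, h_new) if v > 0}
    return CUHistogram(h.gene, counts_new), float(h_new.sum())


def expected_survivors(hists: Mapping[str, CUHistogram], x: float) -> pd.Series:
    """Expected surviving molecules per gene at retained-read fraction x.

    Closed form ``n(x) = sum_i h(i) (1 - (1-x)^i)`` — the j>=1 mass of the
    thinned histogram without materializing it.
    """
    if not 0 < x <= 1:
        raise ValueError("x must be in (0, 1]")
    out = {}
    for gene, h in hists.items():
        copies, counts = h.as_arrays()
        out[gene] = float(np.sum(counts * (1.0 - (1.0 - x) ** copies)))
    return pd.Series(out, dtype=float)


def batch_correct(
    matrix_deep: CountMatrix,
    hists_deep: Mapping[str, CUHistogram],
    matrix_shallow: CountMatrix,
    x: Union[float, str] = "auto",
    grid: Optional[np.ndarray] = None,
) -> Tuple[CountMatrix, DownsampleCorrection]:
    """Batch-correct a deep/shallow dataset pair by binomial downsampling.

    The deeper dataset (more reads per UMI) is analytically downsampled to
    the retained-read fraction ``x``; per-gene CPM before (``e_b``) and
    after (``e_a``) give scale factors ``f_g = e_a / e_b`` applied to the
    deep matrix rows.  With ``x="auto"`` the fraction is scanned over a
    0.01-step grid and the value maximizing the concordance (CCC) of the
    mean log2(CPM+1) profiles between the corrected pair is chosen
    (smallest x on ties).
    """
    shared = [g for g in matrix_deep.gene_ids if g in set(matrix_shallow.gene_ids)]
    deep_totals = matrix_deep.gene_totals()

    def factors_at(xv: float) -> pd.DataFrame:
        n_x = expected_survivors(hists_deep, xv)
        after = deep_totals.copy()
        common = after.index.intersection(n_x.index)
        after.loc[common] = n_x.loc[common]
        e_b = to_cpm(deep_totals).values
        e_a = to_cpm(after).values
        f = pd.Series(1.0, index=e_b.index)
        nzb = e_b > 0
        f[nzb] = e_a[nzb] / e_b[nzb]
        return pd.DataFrame({"e_b": e_b, "e_a": e_a, "f": f})

    chosen_by = "fixed"
    ccc_grid = None
    if isinstance(x, str):
        if x.lower() != "auto":
            raise ValueError(f"x must be a fraction in (0,1] or 'auto', got {x!r}")
        if len(shared) < 2:
            raise ValueError("AUTO requires at least 2 shared genes")
        if grid is None:
            grid = np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 2)
        shallow_prof = np.log2(
            to_cpm(matrix_shallow.gene_totals()).values.loc[shared] + 1.0
        )
        scores = {}
        best_x, best_ccc = None, -np.inf
        for xv in grid:
            pg = factors_at(float(xv))
            deep_prof = np.log2(to_cpm(deep_totals * pg["f"]).values.loc[shared] + 1.0)
            score = ccc(deep_prof, shallow_prof)
            scores[float(xv)] = score
            if score > best_ccc:  # strict: ties keep the smallest x
                best_x, best_ccc = float(xv), score
        x = best_x
        chosen_by = "ccc-grid"
        ccc_grid = pd.Series(scores, name="ccc")
    else:
        if not 0 < x <= 1:
            raise ValueError("x must be in (0, 1]")
        x = float(x)

    per_gene = factors_at(x)
    f = per_gene["f"].to_numpy()
    corrected = CountMatrix(
        sp.diags(f) @ matrix_deep.values,
        matrix_deep.gene_ids,
        matrix_deep.cell_barcodes,
    )
    return corrected, DownsampleCorrection(
        x=x, per_gene=per_gene, chosen_by=chosen_by, ccc_grid=ccc_grid
    )
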