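"""Expression transforms and comparison statistics.

Gene expression vectors are compared on the log scale ``l = log2(CPM + 1)``
using Lin's concordance correlation coefficient (CCC) — which penalizes
both decorrelation and departure of the points from the 45-degree identity
line — together with the mean squared error.  Benchmark discrimination is
summarized with the Mann-Whitney AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .exceptions import UndefinedMetricError
from .types import CountMatrix


@dataclass
class ExpressionVector:
    """Per-gene expression values with an explicit scale tag.

    ``scale`` is ``"cpm"`` (values sum to 1e6 over included genes) or
    ``"log2cpm1"`` (obtained only via ``log2(cpm + 1)``).
    """

    values: pd.Series
    scale: str = "cpm"

    def to_log(self) -> "ExpressionVector":
        if self.scale == "log2cpm1":
            return self
        if self.scale != "cpm":
            raise ValueError(f"cannot log-transform scale {self.scale!r}")
        return ExpressionVector(np.log2(self.values + 1.0), scale="log2cpm1")


def to_cpm(
    gene_totals, include_genes: Optional[Iterable[str]] = None
) -> ExpressionVector:
    """Scale gene totals to counts per million over the included genes.

    When genes are excluded (e.g. after an expression floor), CPM is
    recomputed over the remaining genes only, so the output always sums to
    1e6.
    """
    totals = pd.Series(gene_totals, dtype=float)
    if include_genes is not None:
        include = list(include_genes)
        if not include:
            raise UndefinedMetricError("empty gene inclusion set")
        totals = totals.loc[include]
    grand = totals.sum()
    if grand <= 0:
        raise UndefinedMetricError("cannot CPM-normalize a zero-total vector")
    return ExpressionVector(totals * (1e6 / grand), scale="cpm")


def mean_expression_profile(
    matrix: CountMatrix, cpm_floor: Optional[float] = None
) -> ExpressionVector:
    """Mean-across-cells expression of each gene, CPM-normalized.

    Dataset-level expression is the mean of per-cell counts, scaled to CPM.
    With ``cpm_floor``, genes below the floor are dropped and CPM is
    recomputed over the surviving genes (the floor guards against genes too
    lowly expressed for reliable prediction).
    """
    means = matrix.gene_totals() / max(len(matrix.cell_barcodes), 1)
    vec = to_cpm(means)
    if cpm_floor is not None:
        keep = vec.values.index[vec.values >= cpm_floor]
        vec = to_cpm(means, include_genes=keep)
    return vec


def _check_pair(a, b) -> tuple:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 values")
    return a, b


def ccc(a, b) -> float:
    """Lin's concordance correlation coefficient, population (1/n) moments.

    ``ccc = 2 cov(a,b) / (var(a) + var(b) + (mean(a) - mean(b))^2)``.
    Equals 1 iff the points lie exactly on the identity line.  When both
    vectors are constant the value is 1 for equal means (identical
    constants) and 0 otherwise.
    """
    a, b = _check_pair(a, b)
    va = np.var(a)
    vb = np.var(b)
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    denom = va + vb + (a.mean() - b.mean()) ** 2
    if denom == 0:
        return 1.0
    return float(2.0 * cov / denom)


def mse(a, b) -> float:
    """Mean squared error between two equally scaled vectors."""
    a, b = _check_pair(a, b)
    return float(np.mean((a - b) ** 2))


def mw_auc(scores, labels) -> float:
    """Mann-Whitney AUC of ``scores`` for the binary ``labels``.

    ``AUC = U / (n1 n0)`` with tied scores counted 1/2.  Equivalently the
    probability that a random positive outranks a random negative.  Both
    classes must be present.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(bool).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both label classes must be present")
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))
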