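"""Histogram construction, quality filters, and saturation metrics.

Per-gene copies-per-UMI (CU) histograms are built by pooling molecules from
all cells: the histogram value ``h(i)`` for a gene is the number of its
molecules observed with exactly ``i`` read copies.  The same pass produces
the genes x cells UMI count matrix (distinct molecules per gene and cell).
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import UndefinedMetricError
from .types import CountMatrix, CUHistogram, MoleculeTable, SaturationMetrics

log = logging.getLogger(__name__)


def build_cu_histograms(
    table: MoleculeTable, min_cell_umis: Optional[int] = None
) -> Tuple[Dict[str, CUHistogram], CountMatrix]:
    """Build per-gene CU histograms and the UMI count matrix.

    Multi-gene (ambiguous) molecules are discarded first.  When
    ``min_cell_umis`` is given, cells with fewer distinct molecules are
    removed and the histograms are built from the surviving cells only, so
    that histogram totals always match count-matrix row sums.

    Returns
    -------
    (hists, matrix)
        ``hists`` maps gene id to its :class:`CUHistogram`; ``matrix`` entry
        ``(g, c)`` is the number of distinct molecules of gene ``g`` in cell
        ``c``.
    """
    df = table.drop_ambiguous().records
    if min_cell_umis is not None:
        per_cell = df.groupby("barcode").size()
        keep = set(per_cell.index[per_cell >= min_cell_umis])
        df = df[df["barcode"].isin(keep)].reset_index(drop=True)
    if df.empty:
        log.warning("no molecules left after filtering; returning empty outputs")
        empty = CountMatrix(sp.csr_matrix((0, 0)), [], [])
        return {}, empty

    gene_ids = sorted(df["gene"].unique())
    barcodes = sorted(df["barcode"].unique())
    gi = pd.Categorical(df["gene"], categories=gene_ids).codes
    ci = pd.Categorical(df["barcode"], categories=barcodes).codes
    values = sp.coo_matrix(
        (np.ones(len(df)), (gi, ci)), shape=(len(gene_ids), len(barcodes))
    ).tocsr()
    matrix = CountMatrix(values, gene_ids, barcodes)

    hists = {
        gene: CUHistogram.from_read_counts(gene, sub.to_numpy())
        for gene, sub in df.groupby("gene", sort=True)["reads"]
    }
    return hists, matrix


def filter_cells(matrix: CountMatrix, min_umis: int = 200) -> CountMatrix:
    """Drop cells with fewer than ``min_umis`` total UMIs (boundary kept)."""
    if min_umis < 1:
        raise ValueError("min_umis must be >= 1")
    totals = matrix.cell_totals().to_numpy()
    keep = np.flatnonzero(totals >= min_umis)
    if keep.size == 0:
        log.warning("cell filter removed every cell (min_umis=%d)", min_umis)
    return CountMatrix(
        matrix.values[:, keep],
        matrix.gene_ids,
        [matrix.cell_barcodes[j] for j in keep],
    )


def filter_genes_by_molecules(
    hists: Dict[str, CUHistogram], min_molecules: int
) -> Dict[str, CUHistogram]:
    """Keep genes whose histogram holds at least ``min_molecules`` molecules.

    200 is the threshold for cross-dataset saturation comparisons; 30 for
    saturation distributions over many genes.
    """
    return {g: h for g, h in hists.items() if h.n_molecules >= min_molecules}


def saturation_metrics(h: CUHistogram) -> SaturationMetrics:
    """Fractions of single-copy, double-copy and multi-copy molecules.

    FSCM = h(1)/N summarizes amplification bias: a high value means most
    molecules were sequenced once, so many molecules likely remain unseen.
    """
    n = h.n_molecules
    if n == 0:
        raise UndefinedMetricError(f"saturation metrics undefined: gene {h.gene} has N=0")
    fscm = h.counts.get(1, 0.0) / n
    fdcm = h.counts.get(2, 0.0) / n
    return SaturationMetrics(fscm=fscm, fdcm=fdcm, fmcm=1.0 - fscm - fdcm, n_umis=n)
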