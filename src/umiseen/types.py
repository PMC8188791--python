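"""Core in-memory containers.

Three primary types flow through the pipeline:

* :class:`MoleculeTable` — one record per UMI-collapsed molecule (cell
  barcode, UMI, gene, read count), the direct product of UMI collapsing.
* :class:`CUHistogram` — a per-gene histogram of copies (reads) per
  molecule, ``h(i)``; the sole input to all unseen-molecule estimators.
* :class:`CountMatrix` — a sparse genes x cells UMI count matrix with
  ordered labels.

Result containers (:class:`PredictionResult`, :class:`CorrectionResult`,
:class:`DownsampleCorrection`, ...) are plain dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import FormatError

#: Gene token marking a molecule whose reads mapped to more than one gene.
#: Such molecules are discarded before histogram construction.
AMBIGUOUS = "-"

MOLECULE_COLUMNS = ("barcode", "umi", "gene", "reads")


@dataclass
class MoleculeTable:
    """UMI-collapsed molecule records.

    Parameters
    ----------
    records
        DataFrame with columns ``barcode``, ``umi``, ``gene``, ``reads``.
        ``reads`` must be >= 1 for every record and the
        ``(barcode, umi, gene)`` triples must be unique (the table is
        post-collapsing).  Multi-gene molecules carry the gene token
        :data:`AMBIGUOUS`.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in MOLECULE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"molecule table missing column(s): {missing}")
        df = df.loc[:, list(MOLECULE_COLUMNS)].reset_index(drop=True)
        if len(df) and df["reads"].min() < 1:
            raise FormatError("molecule table contains reads < 1")
        if df.duplicated(subset=["barcode", "umi", "gene"]).any():
            raise FormatError(
                "duplicate (barcode, umi, gene) triples: table is not UMI-collapsed"
            )
        df["reads"] = df["reads"].astype(np.int64)
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def drop_ambiguous(self) -> "MoleculeTable":
        """Return a copy without multi-gene (ambiguous) molecules."""
        keep = self.records["gene"] != AMBIGUOUS
        return MoleculeTable(self.records.loc[keep].reset_index(drop=True))

    def total_reads(self) -> int:
        return int(self.records["reads"].sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MoleculeTable):
            return NotImplemented
        a = self.records.sort_values(["barcode", "umi", "gene"]).reset_index(drop=True)
        b = other.records.sort_values(["barcode", "umi", "gene"]).reset_index(drop=True)
        return a.equals(b)


@dataclass
class CUHistogram:
    """Copies-per-UMI histogram for one gene.

    ``counts[i]`` is the number of molecules observed with exactly ``i``
    read copies (``h(i)``).  Keys are positive integers; values are
    nonnegative and may be fractional (analytic downsampling and pooled
    histograms produce expected, not integer, molecule counts).
    """

    gene: str
    counts: Dict[int, float]

    def __post_init__(self) -> None:
        clean: Dict[int, float] = {}
        for i, h in self.counts.items():
            i = int(i)
            if i < 1:
                raise FormatError(f"histogram copy level {i} < 1 (gene {self.gene})")
            h = float(h)
            if h < 0:
                raise FormatError(f"negative molecule count at copies={i}")
            clean[i] = h
        self.counts = dict(sorted(clean.items()))

    @classmethod
    def from_read_counts(cls, gene: str, reads: np.ndarray) -> "CUHistogram":
        """Tally a histogram from per-molecule read counts (zeros dropped)."""
        reads = np.asarray(reads)
        reads = reads[reads > 0]
        levels, tallies = np.unique(reads, return_counts=True)
        return cls(gene, {int(i): int(c) for i, c in zip(levels, tallies)})

    def as_arrays(self) -> tuple:
        """Return ``(copies, molecules)`` as sorted aligned arrays."""
        i = np.fromiter(self.counts.keys(), dtype=np.int64, count=len(self.counts))
        h = np.fromiter(self.counts.values(), dtype=np.float64, count=len(self.counts))
        return i, h

    @property
    def n_molecules(self) -> float:
        """Total observed molecules N = sum h(i)."""
        return float(sum(self.counts.values()))

    @property
    def total_reads(self) -> float:
        """Total reads = sum i * h(i)."""
        return float(sum(i * h for i, h in self.counts.items()))

    def truncate(self, mt: int) -> "CUHistogram":
        """Histogram restricted to copy levels <= ``mt``."""
        return CUHistogram(self.gene, {i: h for i, h in self.counts.items() if i <= mt})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CUHistogram):
            return NotImplemented
        return self.gene == other.gene and self.counts == other.counts


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with ordered labels.

    Entries may become fractional after correction.  The total UMI count is
    always recomputed from the entries, never taken from file metadata.
    """

    values: sp.csr_matrix
    gene_ids: List[str]
    cell_barcodes: List[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.gene_ids = list(self.gene_ids)
        self.cell_barcodes = list(self.cell_barcodes)
        if self.values.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match labels "
                f"({len(self.gene_ids)} genes, {len(self.cell_barcodes)} barcodes)"
            )
        if len(self.values.data) and self.values.data.min() < 0:
            raise FormatError("count matrix contains negative entries")

    @property
    def total_umis(self) -> float:
        """Grand total of all entries (T), recomputed on access."""
        return float(self.values.sum())

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def gene_totals(self) -> pd.Series:
        """Per-gene totals across all cells."""
        return pd.Series(
            np.asarray(self.values.sum(axis=1)).ravel(), index=self.gene_ids
        )

    def cell_totals(self) -> pd.Series:
        """Per-cell totals across all genes."""
        return pd.Series(
            np.asarray(self.values.sum(axis=0)).ravel(), index=self.cell_barcodes
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_barcodes == other.cell_barcodes
            and (self.values != other.values).nnz == 0
        )


@dataclass(frozen=True)
class SaturationMetrics:
    """Per-gene saturation summary.

    ``fscm``/``fdcm``/``fmcm`` are the fractions of molecules seen with
    exactly one, exactly two, and more than two read copies; they sum to 1.
    """

    fscm: float
    fdcm: float
    fmcm: float
    n_umis: float


@dataclass(frozen=True)
class PredictionResult:
    """Output of a single-gene unseen-molecule prediction.

    ``t`` is the extrapolation factor: total reads are scaled by ``t + 1``.
    ``distinct_molecules`` is the predicted number of molecules with at
    least one copy at the new depth; ``new_molecules`` is the gain over the
    observed count N.
    """

    method: str
    t: float
    distinct_molecules: float
    new_molecules: float
    mt: Optional[int] = None
    clamped: bool = False


@dataclass(frozen=True)
class GenePrediction:
    """Predicted molecule count for one gene plus whether a model was applied.

    ``applied`` is False when the histogram was degenerate and the observed
    count was kept.
    """

    c: float
    applied: bool


@dataclass
class CorrectionResult:
    """Bookkeeping for an m_g count-matrix correction.

    ``per_gene`` maps each gene to ``(c_g, m_g, applied)`` where ``c_g`` is
    the predicted molecule count and ``m_g = (T/P) c_g`` the corrected gene
    total.  When every gene is corrected, sum m_g equals T.
    """

    per_gene: pd.DataFrame  # index gene; columns c, m, applied
    T: float
    P: float
    method: str = ""
    t: Optional[float] = None


@dataclass
class DownsampleCorrection:
    """Bookkeeping for a binomial-downsampling batch correction.

    ``x`` is the retained-read fraction applied to the deeper dataset;
    ``per_gene`` holds CPM before (``e_b``), after (``e_a``), and the scale
    factor ``f = e_a / e_b`` applied to the matrix rows.
    """

    x: float
    per_gene: pd.DataFrame  # index gene; columns e_b, e_a, f
    chosen_by: str  # "fixed" or "ccc-grid"
    ccc_grid: Optional[pd.Series] = None


@dataclass
class PooledHistogramSource:
    """Per-gene saturation fractions of one dataset, for histogram pooling.

    ``per_gene`` is indexed by gene with columns ``fscm``, ``fdcm``,
    ``n_umis``.  ``normalized`` records whether the fractions have been
    quantile-normalized toward the target dataset.
    """

    dataset_id: str
    per_gene: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        need = {"fscm", "fdcm", "n_umis"}
        if not need.issubset(self.per_gene.columns):
            raise FormatError(f"pool source needs columns {sorted(need)}")


@dataclass(frozen=True)
class DSConfig:
    """Configuration for the rational-function (Preseq-style) estimator.

    ``mt`` truncates the histogram to copy levels <= mt before the series is
    built (default 2); ``max_degree`` optionally caps the denominator degree
    of the rational approximant.
    """

    mt: int = 2
    max_degree: Optional[int] = None
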