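"""Readers and writers for the three text formats.

* molecule tables — TSV with header ``barcode  umi  gene  reads``
* count matrices — MatrixMarket coordinate (``.mtx``) plus one-per-line
  ``genes.tsv`` / ``barcodes.tsv`` label files
* copies-per-UMI histograms — long-format TSV ``gene  copies  molecules``

All outputs are UTF-8, tab-separated, LF-terminated.  Plain and ``.gz``
paths are supported.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .exceptions import FormatError
from .types import MOLECULE_COLUMNS, CountMatrix, CUHistogram, MoleculeTable

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="utf-8", newline="")
    return open(path, mode, encoding="utf-8", newline="")


# ---------------------------------------------------------------------------
# molecule tables
# ---------------------------------------------------------------------------

def read_molecule_table(path: PathLike) -> MoleculeTable:
    """Read a UMI-collapsed molecule table from TSV.

    Raises :class:`FormatError` when a header column is missing, a row is
    malformed, or any record has ``reads < 1``.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "umi": str, "gene": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"malformed molecule table {path}: {exc}") from exc
    missing = [c for c in MOLECULE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df["reads"].isna().any() or df[["barcode", "umi", "gene"]].isna().any().any():
        raise FormatError(f"{path}: empty fields in molecule table")
    reads = pd.to_numeric(df["reads"], errors="coerce")
    if reads.isna().any() or (reads != reads.astype(np.int64)).any():
        raise FormatError(f"{path}: non-integer reads value")
    df["reads"] = reads.astype(np.int64)
    return MoleculeTable(df)


def write_molecule_table(table: MoleculeTable, path: PathLike) -> None:
    with _open_text(path, "w") as fh:
        table.records.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def _read_labels(path: PathLike) -> list:
    with _open_text(path, "r") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_count_matrix(mtx: PathLike, genes: PathLike, barcodes: PathLike) -> CountMatrix:
    """Read a genes x cells matrix from MatrixMarket plus label files.

    The total UMI count is recomputed from the entries on load.  A mismatch
    between matrix dimensions and label counts raises :class:`FormatError`.
    """
    try:
        values = sp.csr_matrix(scipy.io.mmread(str(mtx)))
    except ValueError as exc:
        raise FormatError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
    gene_ids = _read_labels(genes)
    cell_barcodes = _read_labels(barcodes)
    if values.shape != (len(gene_ids), len(cell_barcodes)):
        raise FormatError(
            f"{mtx}: matrix is {values.shape} but labels give "
            f"{len(gene_ids)} genes x {len(cell_barcodes)} barcodes"
        )
    return CountMatrix(values, gene_ids, cell_barcodes)


def write_count_matrix(
    matrix: CountMatrix, mtx: PathLike, genes: PathLike, barcodes: PathLike
) -> None:
    """Write MatrixMarket (coordinate real general, 1-based) plus labels."""
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(matrix.values), field="real", precision=17)
    with open(mtx, "wb") as fh:
        fh.write(buf.getvalue())
    for labels, path in ((matrix.gene_ids, genes), (matrix.cell_barcodes, barcodes)):
        with _open_text(path, "w") as fh:
            fh.write("".join(f"{lab}\n" for lab in labels))


# ---------------------------------------------------------------------------
# CU histograms
# ---------------------------------------------------------------------------

def read_histograms(path: PathLike) -> Dict[str, CUHistogram]:
    """Read per-gene CU histograms from long-format TSV.

    Columns ``gene``, ``copies``, ``molecules``; ``copies < 1`` raises
    :class:`FormatError`.  Molecule counts may be fractional.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"malformed histogram file {path}: {exc}") from exc
    missing = [c for c in ("gene", "copies", "molecules") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    copies = pd.to_numeric(df["copies"], errors="coerce")
    if copies.isna().any() or (copies < 1).any() or (copies != copies.astype(int)).any():
        raise FormatError(f"{path}: copies must be positive integers")
    hists: Dict[str, CUHistogram] = {}
    for gene, sub in df.groupby("gene", sort=True):
        counts = dict(zip(sub["copies"].astype(int), sub["molecules"].astype(float)))
        hists[str(gene)] = CUHistogram(str(gene), counts)
    return hists


def write_histograms(hists: Dict[str, CUHistogram], path: PathLike) -> None:
    """Write histograms as long TSV; zero-molecule copy levels are omitted."""
    rows = []
    for gene in sorted(hists):
        for i, h in sorted(hists[gene].counts.items()):
            if h == 0:
                continue
            rows.append((gene, i, int(h) if float(h).is_integer() else repr(h)))
    with _open_text(path, "w") as fh:
        fh.write("gene\tcopies\tmolecules\n")
        fh.write("".join(f"{g}\t{i}\t{m}\n" for g, i, m in rows))
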