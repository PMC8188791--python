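"""Synthetic data with known ground truth.

The generator reproduces the statistical structure the correction assumes:
each gene holds a true number of distinct molecules, every molecule is
amplified independently — its read count drawn from a gene-specific
negative binomial — and sequencing observes only a fraction of the reads
(binomial thinning).  Molecules whose observed read count is zero are the
unseen molecules the estimators must recover.

Defaults (NB amplification means log-uniform on [0.5, 16], size 1, uniform
cell allocation, 12-mer UMIs) are this package's choices of a realistic
droplet-style regime, not values taken from any particular dataset; users
with empirical per-gene saturation tables can supply their own samplers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .correction import expected_survivors
from .estimators import ds_predict, ztnb_fit
from .exceptions import DegenerateHistogramError, EstimatorUnstableError
from .metrics import ccc, to_cpm
from .types import CUHistogram, DSConfig, MoleculeTable

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneSpec:
    """True state of one simulated gene.

    ``n_molecules`` distinct molecules, each amplified to a read count
    drawn from NB(mean=``nb_mean``, size=``nb_size``); ``cell_weights``
    optionally biases the multinomial allocation of molecules to cells.
    """

    gene_id: str
    n_molecules: int
    nb_mean: float
    nb_size: float = 1.0
    cell_weights: Optional[Sequence[float]] = None


@dataclass
class SimSpec:
    """Full description of a simulated dataset."""

    genes: List[GeneSpec]
    n_cells: int = 1
    read_fraction: float = 1.0
    seed: int = 0
    umi_length: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.read_fraction <= 1:
            raise ValueError("read_fraction must be in (0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class GroundTruth:
    """Generator bookkeeping for a simulated dataset.

    ``per_gene`` is indexed by gene with the true distinct-molecule count,
    total pre-thinning reads, and observed (nonzero-read) molecules;
    ``prethin_reads`` keeps the per-molecule read counts before thinning.
    """

    per_gene: pd.DataFrame
    prethin_reads: Dict[str, np.ndarray] = field(default_factory=dict)


def simulate_gene(
    n_molecules: int,
    nb_mean: float,
    nb_size: float,
    seed: Union[int, np.random.Generator],
) -> np.ndarray:
    """Per-molecule read counts for one gene: i.i.d. NB(mean, size) draws.

    Zero-read molecules are included in the output (they are the ground
    truth invisible to observation).
    """
    if n_molecules < 0 or nb_mean <= 0 or nb_size <= 0:
        raise ValueError("n_molecules >= 0 and nb_mean, nb_size > 0 required")
    rng = np.random.default_rng(seed)
    p = nb_size / (nb_size + nb_mean)
    return rng.negative_binomial(nb_size, p, size=n_molecules)


def histogram_from_counts(gene: str, reads: np.ndarray) -> CUHistogram:
    """CU histogram of the nonzero read counts (observed molecules only)."""
    return CUHistogram.from_read_counts(gene, reads)


def _umi_strings(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, length))
    return np.array(["".join(row) for row in _BASES[codes]])


def _unique_umis(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """UMI strings unique within one (cell, gene) group; duplicates redrawn."""
    umis = _umi_strings(rng, n, length)
    for _ in range(50):
        _, first = np.unique(umis, return_index=True)
        dup = np.setdiff1d(np.arange(n), first)
        if dup.size == 0:
            return umis
        umis[dup] = _umi_strings(rng, dup.size, length)
    raise RuntimeError("could not draw unique UMIs; increase umi_length")


def collision_risk(group_size: int, umi_length: int) -> float:
    """Birthday-problem probability of any UMI collision in one group."""
    k = 4.0 ** umi_length
    return 1.0 - math.exp(-group_size * (group_size - 1) / (2.0 * k))


def simulate_dataset(spec: SimSpec) -> Tuple[MoleculeTable, GroundTruth]:
    """Generate a molecule table with full ground-truth bookkeeping.

    Molecules are allocated to cells (uniform multinomial unless a gene
    carries weights), amplified per gene, and thinned to ``read_fraction``
    by per-molecule binomial sampling.  Molecules with zero surviving reads
    are absent from the table but counted in the ground truth.  If the UMI
    collision risk within any (cell, gene) group exceeds 1%, an error
    advises longer UMIs.
    """
    rng = np.random.default_rng(spec.seed)
    barcodes = np.array([f"C{i:05d}" for i in range(spec.n_cells)])

    frames = []
    truth_rows = {}
    prethin: Dict[str, np.ndarray] = {}
    for gene in spec.genes:
        reads_full = simulate_gene(gene.n_molecules, gene.nb_mean, gene.nb_size, rng)
        prethin[gene.gene_id] = reads_full
        if spec.read_fraction < 1.0:
            reads = rng.binomial(reads_full, spec.read_fraction)
        else:
            reads = reads_full
        if gene.cell_weights is not None:
            w = np.asarray(gene.cell_weights, dtype=float)
            w = w / w.sum()
        else:
            w = np.full(spec.n_cells, 1.0 / spec.n_cells)
        cells = rng.choice(spec.n_cells, size=gene.n_molecules, p=w)

        observed = reads > 0
        truth_rows[gene.gene_id] = (
            gene.n_molecules,
            int(reads_full.sum()),
            int(observed.sum()),
        )
        cells_obs = cells[observed]
        reads_obs = reads[observed]
        umis = np.empty(cells_obs.size, dtype=object)
        for c in np.unique(cells_obs):
            idx = np.flatnonzero(cells_obs == c)
            risk = collision_risk(idx.size, spec.umi_length)
            if risk > 0.01:
                raise ValueError(
                    f"UMI collision risk {risk:.1%} for gene {gene.gene_id} in one "
                    f"cell exceeds 1%; use longer UMIs or more cells"
                )
            umis[idx] = _unique_umis(rng, idx.size, spec.umi_length)
        frames.append(
            pd.DataFrame(
                {
                    "barcode": barcodes[cells_obs],
                    "umi": umis.astype(str),
                    "gene": gene.gene_id,
                    "reads": reads_obs.astype(np.int64),
                }
            )
        )

    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["barcode", "umi", "gene", "reads"])
    )
    per_gene = pd.DataFrame.from_dict(
        truth_rows,
        orient="index",
        columns=["n_molecules", "prethin_reads_total", "observed_molecules"],
    )
    per_gene.index.name = "gene"
    return MoleculeTable(records), GroundTruth(per_gene=per_gene, prethin_reads=prethin)


def downsample_reads(
    table: MoleculeTable, fraction: float, seed: Union[int, np.random.Generator]
) -> MoleculeTable:
    """Thin each molecule's reads binomially; zero-read molecules drop out."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return MoleculeTable(table.records.copy())
    rng = np.random.default_rng(seed)
    df = table.records.copy()
    df["reads"] = rng.binomial(df["reads"].to_numpy(), fraction)
    df = df[df["reads"] > 0].reset_index(drop=True)
    return MoleculeTable(df)


# ---------------------------------------------------------------------------
# differential-expression benchmark
# ---------------------------------------------------------------------------

def default_amplification_sampler(rng: np.random.Generator) -> float:
    """NB amplification mean, log-uniform on [0.5, 16]."""
    return float(np.exp(rng.uniform(np.log(0.5), np.log(16.0))))


def _corrected_counts(reads_obs: np.ndarray, gene: str):
    """Observed, ZTNB-extrapolated and rational-function totals for a gene."""
    hist = histogram_from_counts(gene, reads_obs)
    n_obs = hist.n_molecules
    try:
        c_ztnb = ztnb_fit(hist).total_molecules_
    except DegenerateHistogramError:
        c_ztnb = n_obs
    try:
        c_ds = ds_predict(hist, 1e20, DSConfig(mt=2)).distinct_molecules
    except (DegenerateHistogramError, EstimatorUnstableError):
        c_ds = n_obs
    return hist, n_obs, c_ztnb, c_ds


def default_expression_sampler(rng: np.random.Generator) -> int:
    """True distinct molecules per gene, log-uniform on [500, 8000]."""
    return int(round(np.exp(rng.uniform(np.log(500.0), np.log(8000.0)))))


def simulate_de_benchmark(
    n_pairs: int = 150,
    fold_change: float = 2.0,
    amplification_sampler: Callable[[np.random.Generator], float] = None,
    depth_pair: Optional[Tuple[float, float]] = None,
    expression_sampler: Callable[[np.random.Generator], int] = None,
    nb_size: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-pair benchmark for differential-expression detection.

    Half of the ``n_pairs`` pairs are truly differentially expressed (the
    second gene carries ``fold_change`` times the molecules, direction
    random so dataset totals stay balanced).

    True expression levels are drawn per pair (log-uniform by default) and
    amplification means per gene, expressed as copies per UMI at sequencing
    depth.  Two regimes:

    * ``depth_pair=None`` — both genes live in one dataset and each draws an
      independent amplification level: heterogeneous amplification blurs
      observed fold changes.
    * ``depth_pair=(d1, d2)`` — the genes live in two batches sequenced at
      different depths; the second gene's amplification is the first's
      scaled by ``d2/d1`` (pooled amplification acting as a depth batch
      effect).  A binomial-downsampling-corrected column is added, with the
      retained fraction chosen by the CCC grid over the batch profiles.

    Returns a per-pair DataFrame with true labels, amplification levels and
    log2(CPM+1) expression differences ``score_*`` per correction route,
    ready for :func:`umiseen.metrics.mw_auc`.
    """
    if fold_change <= 1:
        raise ValueError("fold_change must be > 1")
    sampler = amplification_sampler or default_amplification_sampler
    expr_sampler = expression_sampler or default_expression_sampler
    rng = np.random.default_rng(seed)

    de = np.zeros(n_pairs, dtype=bool)
    de[: n_pairs // 2] = True
    rng.shuffle(de)
    # random DE direction keeps the two gene sets' totals balanced, so CPM
    # normalization does not shift truly-equal pairs away from zero
    up = rng.random(n_pairs) < 0.5

    batch_mode = depth_pair is not None
    if batch_mode and depth_pair[1] > depth_pair[0]:
        raise ValueError("depth_pair must list the deeper batch first")
    depth_ratio = depth_pair[1] / depth_pair[0] if batch_mode else 1.0

    rows = []
    hists1: Dict[str, CUHistogram] = {}
    for k in range(n_pairs):
        n1 = expr_sampler(rng)
        if de[k]:
            scale = fold_change if up[k] else 1.0 / fold_change
            n2 = int(round(n1 * scale))
        else:
            n2 = n1
        # amplification means are at sequencing depth (copies per UMI)
        amp1 = sampler(rng)
        amp2 = amp1 * depth_ratio if batch_mode else sampler(rng)
        reads1 = simulate_gene(n1, amp1, nb_size, rng)
        reads2 = simulate_gene(n2, amp2, nb_size, rng)
        g1, g2 = f"pair{k:04d}_a", f"pair{k:04d}_b"
        h1, o1, z1, d1 = _corrected_counts(reads1[reads1 > 0], g1)
        h2, o2, z2, d2 = _corrected_counts(reads2[reads2 > 0], g2)
        hists1[g1] = h1
        rows.append(
            dict(
                pair=k, true_de=de[k], n1_true=n1, n2_true=n2,
                amp1=amp1, amp2=amp2,
                obs1=o1, obs2=o2, ztnb1=z1, ztnb2=z2, ds1=d1, ds2=d2,
            )
        )
    df = pd.DataFrame(rows).set_index("pair")

    def scores(col1: str, col2: str) -> pd.Series:
        if batch_mode:
            # the pair members live in different batches: CPM per batch
            e1 = to_cpm(df[col1]).values
            e2 = to_cpm(df[col2]).values
        else:
            # one dataset: both members share the normalization total
            total = df[col1].sum() + df[col2].sum()
            e1 = df[col1] * (1e6 / total)
            e2 = df[col2] * (1e6 / total)
        return np.abs(np.log2(e2 + 1.0) - np.log2(e1 + 1.0))

    df["score_uncorrected"] = scores("obs1", "obs2")
    df["score_ztnb"] = scores("ztnb1", "ztnb2")
    df["score_ds"] = scores("ds1", "ds2")

    if batch_mode:
        # batch 2 is shallower by construction; downsample batch-1 genes at
        # the known depth ratio (a CCC-driven choice of x belongs to the
        # dataset-level batch correction, where no true DE distorts it)
        n_down = expected_survivors(hists1, depth_ratio)
        df["down1"] = n_down.reindex([f"pair{k:04d}_a" for k in df.index]).to_numpy()
        df["score_downsampled"] = scores("down1", "obs2")
        df.attrs["downsample_x"] = depth_ratio
    return df
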