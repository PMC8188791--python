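import numpy as np
import pandas as pd
import pytest

from umiseen import CUHistogram, MoleculeTable
from umiseen.simulate import histogram_from_counts, simulate_gene


@pytest.fixture
def small_table() -> MoleculeTable:
    """Three molecules of gene A (reads 1,1,3) plus one ambiguous molecule."""
    return MoleculeTable(
        pd.DataFrame(
            {
                "barcode": ["c1", "c1", "c2", "c2"],
                "umi": ["AAAA", "CCCC", "GGGG", "TTTT"],
                "gene": ["A", "A", "A", "-"],
                "reads": [1, 1, 3, 5],
            }
        )
    )


@pytest.fixture
def nb_histogram() -> CUHistogram:
    """Histogram of 50,000 molecules amplified NB(mean=2, size=1), seeded."""
    reads = simulate_gene(50000, 2.0, 1.0, seed=42)
    return histogram_from_counts("sim", reads)


def random_molecule_table(rng: np.random.Generator, n: int) -> MoleculeTable:
    """A syntactically valid random molecule table with unique triples."""
    umis = [f"U{i:06d}" for i in rng.choice(10 * n, size=n, replace=False)]
    return MoleculeTable(
        pd.DataFrame(
            {
                "barcode": rng.choice([f"c{j}" for j in range(8)], size=n),
                "umi": umis,
                "gene": rng.choice(["g1", "g2", "g3", "-"], size=n),
                "reads": rng.integers(1, 30, size=n),
            }
        )
    )
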