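import numpy as np
import pytest

from beanld.genotype_io import GenotypeMatrix, build_locus_table
from beanld.synthetic_panel import PanelSpec, simulate_panel


def random_inbred_pair(rng, n):
    """Two polymorphic inbred dosage vectors of length n."""
    while True:
        xa = rng.choice([0, 2], size=n)
        xb = rng.choice([0, 2], size=n)
        if xa.std() > 0 and xb.std() > 0:
            return xa.astype(float), xb.astype(float)


def random_kinship(rng, n):
    """A positive-definite kinship-like matrix in [0, 1] with unit diagonal."""
    B = rng.random((n, n + 3))
    K = B @ B.T
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d)
    return 0.7 * K + 0.3 * np.eye(n)


@pytest.fixture(scope="session")
def small_panel():
    """A noisy two-pool panel small enough for exhaustive checks."""
    spec = PanelSpec(
        lines_per_pool=(25, 10),
        n_ril=3,
        loci_per_chrom=(18,) * 11,
        missing_rate=0.06,
        het_error_rate=0.01,
        seed=11,
    )
    return simulate_panel(spec)


@pytest.fixture()
def toy_matrix():
    """Tiny hand-checkable matrix: 4 lines x 4 loci on one chromosome."""
    values = np.array(
        [
            [0, 0, -1, 0],
            [0, 0, 2, 0],
            [2, 2, 0, 2],
            [0, 0, 2, 2],
        ],
        dtype=np.int8,
    )
    G = GenotypeMatrix(values, ["A", "B", "C", "D"])
    L = build_locus_table(
        ["Pv01"] * 4, [100, 200, 300, 400], ["A"] * 4, ["G"] * 4, values
    )
    return G, L
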