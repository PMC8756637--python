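import numpy as np
import pytest
from scipy import sparse

from pairedvae import JointProfile, SimSpec, simulate_joint, tfidf_transform


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_profile():
    """A small learnable paired profile with TF-IDF precomputed."""
    jp, truth = simulate_joint(SimSpec(n_cells=150, n_genes=40, n_peaks=60,
                                       K_true=3, seed=7))
    jp.atac_tfidf = tfidf_transform(jp.atac_counts)
    return jp, truth


@pytest.fixture()
def toy_profile():
    """Hand-written 3-cell profile used for filtering examples.

    RNA (3 cells x 4 genes): cell3 detects only one gene; gene g4 is detected
    only by cell3.  Peaks: every cell detects >= 2 peaks; peak p3 is detected
    by all three cells.
    """
    rna = np.array([[5, 2, 1, 1],
                    [3, 1, 2, 0],
                    [0, 0, 4, 0]])
    atac = np.array([[1, 0, 1, 1],
                     [0, 2, 1, 1],
                     [1, 1, 1, 0]])
    return JointProfile(
        rna_counts=sparse.csr_matrix(rna),
        atac_counts=sparse.csr_matrix(atac),
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["g1", "g2", "g3", "g4"],
        peak_ids=["p1", "p2", "p3", "p4"],
    )
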