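import numpy as np
import pytest
import scipy.sparse as sp

from keystonex.preprocess import CellMatrix
from keystonex.simulate import keystone_preset


@pytest.fixture(scope="session")
def preset_table():
    """Keystone preset with small control pools (fast, full bookkeeping)."""
    return keystone_preset(n_developmental=60, n_other=120)


def make_cell_matrix(dense, mito_flags=None, normalized=False):
    """CellMatrix from a dense genes x cells array with auto ids."""
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    return CellMatrix(
        counts=sp.csr_matrix(dense),
        gene_ids=[f"g{i:05d}" for i in range(n_genes)],
        cell_ids=[f"c{j:05d}" for j in range(n_cells)],
        mito_flags=np.zeros(n_genes, bool) if mito_flags is None else np.asarray(mito_flags, bool),
        normalized=normalized,
    )
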