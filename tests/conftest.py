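import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from cotransmit.io_qc import CountMatrix, NormalizedMatrix


def make_norm(values, genes=None, scale_factor=1e4) -> NormalizedMatrix:
    """NormalizedMatrix from a dense genes x cells array (test convenience)."""
    values = np.asarray(values, dtype=float)
    if genes is None:
        genes = [f"g{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(
        sparse.csr_matrix(values),
        np.asarray(genes, dtype=object),
        np.asarray([f"c{i}" for i in range(values.shape[1])], dtype=object),
        scale_factor=scale_factor,
    )


def qc_boundary_fixture():
    """Ten hand-built cells with known QC violations (defaults thresholds).

    Survivors: the exact-boundary cell (300 genes, 500 counts, 1% mito) and
    the five clean cells; removed: two low-gene cells, one high-mito cell,
    one doublet.
    """
    n_genes = 6500
    gene_ids = [f"mt-M{i}" for i in range(10)] + [f"G{i}" for i in range(n_genes - 10)]
    cols = {}

    def cell(pairs):
        v = np.zeros(n_genes, dtype=np.int64)
        for idx, count in pairs:
            v[idx] = count
        return v

    # exactly 300 detected genes, total 500, mito exactly 1% (5 of 500)
    boundary = [(0, 5)] + [(10 + i, 2) for i in range(196)] + [(206 + i, 1) for i in range(103)]
    cols["boundary"] = cell(boundary)
    cols["low_genes_1"] = cell([(10 + i, 10) for i in range(100)])  # 100 genes
    cols["low_genes_2"] = cell([(10 + i, 2) for i in range(299)])  # 299 genes
    # 2.5% mito
    cols["high_mito"] = cell([(0, 20)] + [(10 + i, 2) for i in range(390)])
    cols["doublet"] = cell([(10 + i, 2) for i in range(400)])
    for j in range(5):
        cols[f"clean{j}"] = cell([(10 + i, 2) for i in range(350)])

    X = sparse.csr_matrix(np.column_stack(list(cols.values())))
    counts = CountMatrix(X, np.array(gene_ids, dtype=object), np.array(list(cols), dtype=object))
    meta = pd.DataFrame(
        {
            "cell_id": list(cols),
            "sample": "S1",
            "group": "WT_S",
            "doublet": [c == "doublet" for c in cols],
        }
    )
    expected_survivors = ["boundary"] + [f"clean{j}" for j in range(5)]
    return counts, meta, expected_survivors


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
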