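import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from gafa.io_qc import ExpressionMatrix, normalize_log, qc_filter
from gafa.synthetic import SyntheticConfig, generate_dataset


def make_expression_matrix(counts, gene_ids, outcomes=None, samples=None,
                           patients=None, batches=None):
    """Small ExpressionMatrix from a dense array with minimal metadata."""
    counts = np.asarray(counts)
    n = counts.shape[0]
    meta = pd.DataFrame(
        {
            "patient": patients if patients is not None else [f"P{i}" for i in range(n)],
            "sample": samples if samples is not None else [f"S{i}" for i in range(n)],
            "timepoint": ["baseline"] * n,
            "batch": batches if batches is not None else ["B1"] * n,
            "outcome": outcomes if outcomes is not None else ["TFR"] * n,
        }
    )
    return ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=list(gene_ids),
        cell_ids=[f"C{i}" for i in range(n)],
        cell_meta=meta,
    )


@pytest.fixture(scope="session")
def dataset():
    """The default study-conditions dataset (800 cells, 500 genes, seed 1)."""
    cfg = SyntheticConfig(seed=1)
    matrix, truth = generate_dataset(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def normalized(dataset):
    """QC-filtered, log-normalized view plus the index of kept cells."""
    _, matrix, truth = dataset
    filtered = qc_filter(matrix)
    pos = {c: i for i, c in enumerate(matrix.cell_ids)}
    kept = np.array([pos[c] for c in filtered.cell_ids])
    return normalize_log(filtered), kept, truth
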