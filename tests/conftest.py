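import numpy as np
import pytest

from timepatterns.io import ExpressionMatrix, SampleKey


def make_matrix(n_genes=4, conditions=("A", "B"), timepoints=("t1", "t2"),
                replicates=("r1", "r2"), values=None, data_type="rnaseq", seed=0):
    """Small expression matrix with a regular (C, T, R) sample grid."""
    keys = [
        SampleKey(c, t, r if replicates else None)
        for c in conditions for t in timepoints
        for r in (replicates or [None])
    ]
    if values is None:
        rng = np.random.default_rng(seed)
        values = rng.gamma(2.0, 10.0, size=(n_genes, len(keys)))
    gene_ids = [f"g{i}" for i in range(n_genes)]
    return ExpressionMatrix(gene_ids, keys, values, data_type)


@pytest.fixture
def small_matrix():
    return make_matrix()


def write_tsv(path, header, rows):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return path
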