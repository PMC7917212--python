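import numpy as np
import pandas as pd
import pytest

from rgstab import CrtMatrix


def make_crt(values, gene_ids=None, sample_ids=None, tissues=None, donors=None,
             spike_gene=None):
    """Build a CrtMatrix from a plain genes x samples array."""
    arr = np.asarray(values, float)
    g, n = arr.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(g)]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n)]
    meta = pd.DataFrame(
        {
            "donor": donors or [f"d{j + 1}" for j in range(n)],
            "tissue": tissues or ["t1"] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    vals = pd.DataFrame(arr, index=gene_ids, columns=sample_ids)
    return CrtMatrix(vals, meta, spike_gene=spike_gene)


def random_crt(rng, n_genes=5, n_samples=6, spike=False, low=12.0, high=24.0):
    """A random complete Cq matrix (optionally with a spike row)."""
    vals = rng.uniform(low, high, size=(n_genes, n_samples))
    gene_ids = [f"g{i + 1}" for i in range(n_genes)]
    spike_gene = None
    if spike:
        vals = np.vstack([vals, 15.0 + rng.normal(0, 0.5, n_samples)])
        gene_ids.append("spike")
        spike_gene = "spike"
    return make_crt(vals, gene_ids=gene_ids, spike_gene=spike_gene)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_matrix(rng):
    return random_crt(rng, n_genes=5, n_samples=6)
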