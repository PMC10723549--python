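import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hybridsc import syndata
from hybridsc.io import CountMatrix
from hybridsc.pipeline import analyze_sample
from hybridsc.preprocess import normalize, qc_filter


def make_adata(X: np.ndarray, genes=None, barcodes=None) -> ad.AnnData:
    """Small dense cells x genes AnnData for unit tests."""
    n_cells, n_genes = X.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"c{i}" for i in range(n_cells)]
    return ad.AnnData(
        X=np.asarray(X, dtype=float),
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=genes),
    )


def make_counts(values, genes=None, barcodes=None, sample_id="T") -> CountMatrix:
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(values.shape[1])]
    return CountMatrix(sp.csc_matrix(values), genes, barcodes, sample_id)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic sample (singlets + hybrids + spiked doublets)."""
    counts, truth = syndata.simulate_dataset(syndata.SimConfig(seed=1))
    return counts, truth


@pytest.fixture(scope="session")
def default_normalized(default_dataset):
    counts, truth = default_dataset
    return normalize(qc_filter(counts)), truth


@pytest.fixture(scope="session")
def default_result(default_dataset):
    """Full pipeline run on the default synthetic sample."""
    counts, truth = default_dataset
    annotations = syndata.truth_to_annotation(truth).to_numpy()
    result = analyze_sample(counts, annotations, seed=1)
    return result, truth
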