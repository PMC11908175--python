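"""Shared fixtures: one fully generated synthetic atlas per session.

The default dataset is small (12 clusters x 100 cells) but structurally
complete: glial clusters, lineage transgenes, planted markers, TF codes,
NT/NP programmes, sex-specific genes and one planted female-biased
cluster. Expensive stages (normalisation, the marker table) are computed
once and shared.
"""

import numpy as np
import pandas as pd
import pytest

from t2atlas import io_qc, markers, synthetic


@pytest.fixture(scope="session")
def base_spec() -> synthetic.SyntheticSpec:
    return synthetic.SyntheticSpec(seed=1, sex_bias_design={"c05": 0.9})


@pytest.fixture(scope="session")
def dataset(base_spec):
    adata, truth = synthetic.generate(base_spec)
    return adata, truth


@pytest.fixture(scope="session")
def normalized(dataset):
    adata, truth = dataset
    return io_qc.normalize(adata), truth


@pytest.fixture(scope="session")
def marker_table(normalized):
    adata, _ = normalized
    return markers.find_all_markers(adata)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_tiny_anndata(counts, clusters=None, gene_ids=None, **obs_cols):
    """Small AnnData with minimal metadata for focused unit tests."""
    import anndata as ad
    import scipy.sparse as sp

    counts = np.asarray(counts, dtype=np.int64)
    n, g = counts.shape
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    obs = pd.DataFrame(index=pd.Index([f"cell{i}" for i in range(n)], name="cell_id"))
    obs["cluster"] = clusters if clusters is not None else ["c0"] * n
    obs["sample"] = obs_cols.get("sample", ["s0"] * n)
    obs["sex"] = obs_cols.get("sex", ["female"] * n)
    obs["lineage"] = "unassigned"
    var = pd.DataFrame(
        {
            "gene_class": obs_cols.get("gene_class", ["other"] * g),
            "tf_class": obs_cols.get("tf_class", ["none"] * g),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
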