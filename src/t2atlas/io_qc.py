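"""Dataset I/O, QC filtering, normalisation, lineage assignment and
cluster-level subsetting.

All operations accept and return :class:`anndata.AnnData` objects whose ``X``
holds raw counts (sparse, non-negative integers). :func:`normalize` adds the
``lognorm`` and ``scaled`` layers that every downstream stage consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._constants import TRANSGENES

CELL_COLUMNS = ("cell_id", "sample", "sex", "cluster")
GENE_COLUMNS = ("gene_id", "gene_class", "tf_class")


class FormatError(ValueError):
    """Raised when on-disk dataset files are inconsistent."""


@dataclass
class QCReport:
    """Tally of a QC filtering pass.

    Cells may fail several criteria; each is counted once under the first
    failing criterion, in the order low-genes, high-genes, mito-fraction,
    so that ``n_pass`` plus the three failure counts equals ``n_input_cells``.
    """

    n_input_cells: int
    n_pass: int
    n_fail_low_genes: int
    n_fail_high_genes: int
    n_fail_mito: int
    thresholds: tuple = (200, 2500, 0.05)
    mito_skipped: bool = False

    def __post_init__(self) -> None:
        total = (
            self.n_pass
            + self.n_fail_low_genes
            + self.n_fail_high_genes
            + self.n_fail_mito
        )
        if total != self.n_input_cells:
            raise ValueError("QCReport tallies do not sum to n_input_cells")


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    return X.tocsr()


def read_dataset(directory: str | Path) -> ad.AnnData:
    """Read a dataset written by :func:`t2atlas.synthetic.write_dataset`.

    Expects ``matrix.mtx`` (cells x genes, integer counts), ``genes.tsv`` and
    ``cells.tsv``. No normalisation is applied.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    genes_path = directory / "genes.tsv"
    cells_path = directory / "cells.tsv"
    for p in (mtx_path, genes_path, cells_path):
        if not p.exists():
            raise FormatError(f"missing dataset file: {p}")

    X = scipy.io.mmread(mtx_path).tocsr().astype(np.int64)
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)

    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"duplicated gene_id entries in genes.tsv: {dups}")
    if len(cells) and cells["cell_id"].duplicated().any():
        raise FormatError("duplicated cell_id entries in cells.tsv")
    if X.shape[0] != len(cells) or X.shape[1] != len(genes):
        raise FormatError(
            f"matrix.mtx is {X.shape[0]} x {X.shape[1]} but cells.tsv has "
            f"{len(cells)} rows and genes.tsv has {len(genes)} rows"
        )

    obs = cells.set_index("cell_id")
    obs.index = obs.index.astype(str)
    if "lineage" not in obs.columns:
        obs["lineage"] = "unassigned"
    var = genes.set_index("gene_id")
    var.index = var.index.astype(str)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    return adata


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_genes: int = 2500,
    max_mito: float = 0.05,
) -> tuple[ad.AnnData, QCReport]:
    """Remove low-quality cells.

    Retains cells with ``min_genes <= genes detected <= max_genes`` and a
    mitochondrial-read fraction ``<= max_mito``. Mitochondrial genes are the
    rows of ``var`` with ``gene_class == "mito"``; when none are annotated the
    mito criterion is skipped with a warning and recorded in the report.
    """
    X = _counts(adata)
    genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    depth = np.asarray(X.sum(axis=1)).ravel()

    mito_mask = (adata.var["gene_class"] == "mito").to_numpy()
    mito_skipped = not mito_mask.any()
    if mito_skipped:
        warnings.warn(
            "no mitochondrial genes annotated; mito criterion skipped",
            stacklevel=2,
        )
        mito_frac = np.zeros(adata.n_obs)
    else:
        mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(depth > 0, mito_counts / np.maximum(depth, 1), 0.0)

    fail_low = genes_detected < min_genes
    fail_high = ~fail_low & (genes_detected > max_genes)
    fail_mito = ~fail_low & ~fail_high & (mito_frac > max_mito)
    keep = ~(fail_low | fail_high | fail_mito)

    report = QCReport(
        n_input_cells=adata.n_obs,
        n_pass=int(keep.sum()),
        n_fail_low_genes=int(fail_low.sum()),
        n_fail_high_genes=int(fail_high.sum()),
        n_fail_mito=int(fail_mito.sum()),
        thresholds=(min_genes, max_genes, max_mito),
        mito_skipped=mito_skipped,
    )
    return adata[keep].copy(), report


def normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Add ``lognorm`` and ``scaled`` layers.

    ``lognorm[i, j] = log(1 + scale_factor * counts[i, j] / depth_i)``;
    ``scaled`` is the per-gene z-score of ``lognorm`` across cells
    (population SD), with zero-variance genes mapped to 0. Cells with zero
    depth get an all-zero ``lognorm`` row and trigger a warning.
    """
    X = _counts(adata)
    depth = np.asarray(X.sum(axis=1)).ravel().astype(float)
    zero_depth = depth == 0
    if zero_depth.any():
        warnings.warn(
            f"{int(zero_depth.sum())} cell(s) with zero depth; "
            "lognorm rows set to zero",
            stacklevel=2,
        )
    safe_depth = np.where(zero_depth, 1.0, depth)

    lognorm = X.astype(float).multiply(scale_factor / safe_depth[:, None]).tocsr()
    lognorm.data = np.log1p(lognorm.data)

    dense = lognorm.toarray()
    mean = dense.mean(axis=0)
    sd = dense.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, (dense - mean) / np.where(sd > 0, sd, 1.0), 0.0)

    out = adata.copy()
    out.layers["lognorm"] = lognorm
    out.layers["scaled"] = scaled
    return out


def assign_lineage(
    adata: ad.AnnData,
    transgenes: Sequence[str] = TRANSGENES,
    min_counts: int = 1,
) -> ad.AnnData:
    """Assign each cell a neuroblast lineage from transgene counts.

    A cell is T2 iff any lineage-tracing transgene (FLP, GFP or RFP by
    default) has raw counts ``>= min_counts``; all remaining
    (triple-negative) cells are T1, so the partition is exhaustive.
    """
    missing = [g for g in transgenes if g not in adata.var_names]
    if missing:
        raise KeyError(f"transgene gene(s) absent from dataset: {missing}")
    X = _counts(adata)
    idx = [adata.var_names.get_loc(g) for g in transgenes]
    tg = X[:, idx].toarray()
    is_t2 = (tg >= min_counts).any(axis=1)
    out = adata.copy()
    out.obs["lineage"] = np.where(is_t2, "T2", "T1")
    return out


def subset_by_cluster_gene(
    adata: ad.AnnData,
    gene: str,
    min_frac_pos: float = 0.5,
    complement: bool = False,
) -> ad.AnnData:
    """Subset to clusters "expressing" a gene (e.g. the pan-glial marker repo).

    A cluster qualifies when the fraction of its cells with raw counts >= 1
    for ``gene`` is at least ``min_frac_pos``. With ``complement=True`` the
    non-qualifying clusters are returned instead (e.g. filtering glia out to
    keep the neuronal atlas).
    """
    if gene not in adata.var_names:
        raise KeyError(f"gene not in dataset: {gene}")
    X = _counts(adata)
    pos = np.asarray((X[:, [adata.var_names.get_loc(gene)]] >= 1).todense()).ravel()
    clusters = adata.obs["cluster"]
    frac = pd.Series(pos, index=adata.obs_names).groupby(clusters, observed=True).mean()
    qualifying = set(frac.index[frac >= min_frac_pos])
    if not qualifying and not complement:
        warnings.warn(f"no cluster qualifies for {gene}+", stacklevel=2)
    keep = clusters.isin(qualifying)
    if complement:
        keep = ~keep
    return adata[keep.to_numpy()].copy()


def tally_nuclei(
    table: pd.DataFrame,
    count_col: str = "n_nuclei",
    by: str | None = None,
) -> int | pd.Series:
    """Bookkeeping sum of nuclei counts from a composition table.

    ``table`` holds one row per sample/source with a nuclei count column;
    with ``by`` the counts are summed per group, otherwise the grand total
    is returned. Used to audit atlas composition arithmetic (integration
    inputs, per-sample neuronal and glial totals).
    """
    if count_col not in table.columns:
        raise KeyError(f"missing count column: {count_col}")
    if by is None:
        return int(table[count_col].sum())
    return table.groupby(by, observed=True)[count_col].sum()


@dataclass
class LineageSummary:
    """Counts of the T1/T2 lineage partition."""

    n_total: int
    n_t1: int
    n_t2: int

    @classmethod
    def from_anndata(cls, adata: ad.AnnData) -> "LineageSummary":
        lineage = adata.obs["lineage"]
        return cls(
            n_total=int(len(lineage)),
            n_t1=int((lineage == "T1").sum()),
            n_t2=int((lineage == "T2").sum()),
        )
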