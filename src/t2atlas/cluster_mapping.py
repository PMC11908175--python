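"""Cluster-to-neuron-type mapping by three complementary routes.

1. Correlation of each cluster's mean log-normalised profile against bulk
   RNA-seq profiles of known neuron types; each cluster is assigned the
   cell type with the highest coefficient.
2. Enhancer-gene scoring for split-driver lines: a cluster qualifies for a
   driver's cell type when every enhancer-associated gene has positive
   scaled average expression in that cluster.
3. Boolean marker logic (e.g. Toy+ Runt-) over per-cluster detection
   fractions.

Routes 2 and 3 are deliberately many-to-many: several clusters may
qualify for one cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .markers import ClusterProfile

MAPPING_COLUMNS = ("cluster", "cell_type", "method", "score", "assigned")


@dataclass
class MarkerPredicate:
    """Boolean marker requirements over a cluster.

    ``conditions`` lists (gene, state) pairs with state "positive" or
    "negative". A cluster satisfies a positive gene when at least
    ``min_frac_pos`` of its cells detect it (counts >= 1), and a negative
    gene when at most ``max_frac_neg`` do.
    """

    conditions: list[tuple[str, str]]
    min_frac_pos: float = 0.5
    max_frac_neg: float = 0.1

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("predicate has no conditions")
        genes = [g for g, _ in self.conditions]
        if len(set(genes)) != len(genes):
            raise ValueError("a gene appears twice in the predicate")
        for g, state in self.conditions:
            if state not in ("positive", "negative"):
                raise ValueError(f"unknown required state for {g}: {state}")

    @classmethod
    def parse(cls, text: str, **kw) -> "MarkerPredicate":
        """Parse ``"toy:+,runt:-"`` syntax."""
        conditions = []
        for item in text.split(","):
            gene, _, sign = item.strip().rpartition(":")
            state = {"+": "positive", "-": "negative"}.get(sign)
            if not gene or state is None:
                raise ValueError(f"cannot parse predicate item: {item!r}")
            conditions.append((gene, state))
        return cls(conditions=conditions, **kw)


def read_bulk_profiles(path: str | Path) -> pd.DataFrame:
    """Read a genes x cell-type TSV of non-negative bulk expression."""
    bulk = pd.read_csv(path, sep="\t", index_col=0)
    validate_bulk_profiles(bulk)
    return bulk


def validate_bulk_profiles(bulk: pd.DataFrame) -> None:
    if (bulk.to_numpy() < 0).any():
        raise ValueError("bulk profiles contain negative entries")
    if bulk.index.duplicated().any():
        raise ValueError("duplicate gene ids in bulk profiles")


def _corr_columns(A: np.ndarray, B: np.ndarray, method: str) -> np.ndarray:
    """Column-wise correlation between columns of A and columns of B;
    zero-variance columns yield 0."""
    if method == "spearman":
        A = rankdata(A, axis=0)
        B = rankdata(B, axis=0)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    sa = np.sqrt((A**2).sum(axis=0))
    sb = np.sqrt((B**2).sum(axis=0))
    denom = np.outer(sa, sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (A.T @ B) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def bulk_correlation_map(
    profile: ClusterProfile,
    bulk: pd.DataFrame,
    method: str = "pearson",
    gene_set: str = "intersection",
    n_hvg: int = 500,
    log_bulk: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate cluster mean profiles with bulk cell-type profiles.

    Coefficients are computed over the shared gene set (at least 10 genes,
    else an error reporting the overlap); ``gene_set="hvg"`` restricts to
    the ``n_hvg`` genes most variable across clusters. Bulk values are
    log1p-transformed by default. Per cluster, the arg-max cell type is
    flagged assigned; ties break lexicographically and are flagged in the
    record table's ``tie`` column.

    Returns (records, coefficient matrix clusters x cell types).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method}")
    validate_bulk_profiles(bulk)
    shared = profile.mean_lognorm.columns.intersection(bulk.index)
    if gene_set == "hvg":
        var = profile.mean_lognorm[shared].var(axis=0, ddof=0)
        shared = var.sort_values(ascending=False).index[:n_hvg]
    elif gene_set != "intersection":
        raise ValueError(f"unknown gene_set: {gene_set}")
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} genes shared between atlas and bulk profiles "
            "(need >= 10)"
        )

    A = profile.mean_lognorm[shared].to_numpy(dtype=float).T  # genes x clusters
    B = bulk.loc[shared].to_numpy(dtype=float)  # genes x cell types
    if log_bulk:
        B = np.log1p(B)
    r = _corr_columns(A, B, method)
    coeff = pd.DataFrame(
        r, index=profile.mean_lognorm.index, columns=bulk.columns
    )

    records = []
    for c in coeff.index:
        row = coeff.loc[c]
        best = row.max()
        winners = sorted(row.index[row == best])
        for ct in coeff.columns:
            records.append(
                {
                    "cluster": str(c),
                    "cell_type": str(ct),
                    "method": "bulk_correlation",
                    "score": float(row[ct]),
                    "assigned": ct == winners[0],
                    "tie": ct == winners[0] and len(winners) > 1,
                }
            )
    return pd.DataFrame(records), coeff


def enhancer_gene_assignment(
    profile: ClusterProfile,
    driver_table: dict[str, tuple[str, list[str]]],
) -> pd.DataFrame:
    """Score clusters for split-driver enhancer genes.

    ``driver_table`` maps driver name -> (cell type, enhancer gene list).
    A cluster qualifies for a driver iff the scaled average expression of
    every enhancer gene is positive; all qualifying clusters are reported
    (``assigned=True``), with ``score`` the number of positive genes.
    """
    records = []
    for driver, (cell_type, genes) in driver_table.items():
        if not genes:
            raise ValueError(f"driver {driver} has an empty enhancer gene list")
        missing = [g for g in genes if g not in profile.scaled_avg.columns]
        if missing:
            raise KeyError(f"enhancer gene(s) absent for {driver}: {missing}")
        sub = profile.scaled_avg[list(genes)]
        n_pos = (sub > 0).sum(axis=1)
        for c in profile.scaled_avg.index:
            qualifies = bool(n_pos[c] == len(genes))
            records.append(
                {
                    "cluster": str(c),
                    "cell_type": str(cell_type),
                    "driver": str(driver),
                    "method": "enhancer_genes",
                    "score": int(n_pos[c]),
                    "assigned": qualifies,
                }
            )
    return pd.DataFrame(records)


def marker_logic_assignment(
    adata: ad.AnnData,
    predicate: MarkerPredicate,
    cluster_key: str = "cluster",
) -> set[str]:
    """Clusters satisfying every condition of a boolean marker predicate."""
    genes = [g for g, _ in predicate.conditions]
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"predicate gene(s) absent: {missing}")
    X = adata.X
    X = X.tocsr() if sp.issparse(X) else sp.csr_matrix(X)
    clusters = adata.obs[cluster_key].astype(str)
    result: set[str] | None = None
    for gene, state in predicate.conditions:
        pos = np.asarray(
            (X[:, [adata.var_names.get_loc(gene)]] >= 1).todense()
        ).ravel()
        frac = (
            pd.Series(pos, index=adata.obs_names)
            .groupby(clusters, observed=True)
            .mean()
        )
        if state == "positive":
            ok = set(frac.index[frac >= predicate.min_frac_pos].astype(str))
        else:
            ok = set(frac.index[frac <= predicate.max_frac_neg].astype(str))
        result = ok if result is None else (result & ok)
    return result or set()
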