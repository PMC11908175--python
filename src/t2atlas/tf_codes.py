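"""Transcription-factor combinatorial codes.

For one DNA-binding-domain class, each cluster's code is the binary vector
over the class's TFs with a 1 wherever the TF is a significant positive
marker of the cluster. A cluster's code is *unique* when no other cluster
carries an identical row (two all-zero clusters are mutual duplicates).
Cluster similarity is the Jaccard index of the marker sets, with J = 0 by
convention when both sets are empty so markerless clusters never drive the
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform


@dataclass
class BinaryCodeMatrix:
    """Clusters x TFs 0/1 marker-code matrix for one TF class."""

    tf_class: str
    matrix: pd.DataFrame  # int 0/1, index = cluster labels, columns = TF ids
    source_alpha: float = 0.05

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("code matrix entries must be 0/1")
        if self.matrix.index.duplicated().any():
            raise ValueError("duplicate cluster labels")
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicate TF labels")


@dataclass
class CodeStats:
    n_clusters: int
    n_unique: int
    pct_unique: float  # one decimal, half-up
    duplicate_groups: list[set[str]]


@dataclass
class JaccardOrdering:
    similarity: pd.DataFrame  # symmetric clusters x clusters
    order: list[str]


def binarize_tf_markers(
    table: pd.DataFrame,
    gene_meta: pd.DataFrame,
    tf_class: str,
    alpha: float = 0.05,
    clusters: list[str] | None = None,
) -> BinaryCodeMatrix:
    """Build the binary code matrix for one TF class from a marker table.

    Entry (c, t) is 1 iff TF t of the class is an up-regulated marker of
    cluster c with adjusted p < ``alpha``. TFs that are a marker in no
    cluster are dropped (all-zero columns removed); clusters with no class
    markers keep an all-zero row.
    """
    class_genes = gene_meta.index[gene_meta["tf_class"] == tf_class].tolist()
    if not class_genes:
        raise ValueError(f"no genes annotated with tf_class {tf_class!r}")
    if clusters is None:
        clusters = list(table.attrs.get("clusters", []))
        if not clusters:
            clusters = sorted(table["cluster"].astype(str).unique())
    clusters = [str(c) for c in clusters]

    sig = table[
        (table["direction"] == "up")
        & (table["p_adj"] < alpha)
        & (table["gene"].isin(class_genes))
    ]
    matrix = pd.DataFrame(0, index=clusters, columns=class_genes, dtype=int)
    for _, rec in sig.iterrows():
        matrix.loc[str(rec["cluster"]), rec["gene"]] = 1
    matrix = matrix.loc[:, matrix.sum(axis=0) > 0]
    return BinaryCodeMatrix(tf_class=tf_class, matrix=matrix, source_alpha=alpha)


def unique_code_stats(codes: BinaryCodeMatrix) -> CodeStats:
    """Count clusters whose code row occurs exactly once.

    The percentage is rounded half-up to one decimal. Duplicate clusters
    are grouped by shared code; every member of a group is non-unique."""
    matrix = codes.matrix
    if len(matrix) == 0:
        raise ValueError("empty code matrix")
    keys = [tuple(row) for row in matrix.to_numpy()]
    counts = pd.Series(keys).value_counts()
    key_of = dict(zip(matrix.index, keys))
    n_unique = sum(1 for c in matrix.index if counts[key_of[c]] == 1)
    groups: dict[tuple, set[str]] = {}
    for c in matrix.index:
        if counts[key_of[c]] > 1:
            groups.setdefault(key_of[c], set()).add(str(c))
    pct = float(
        (Decimal(100) * Decimal(n_unique) / Decimal(len(matrix))).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
    return CodeStats(
        n_clusters=len(matrix),
        n_unique=n_unique,
        pct_unique=pct,
        duplicate_groups=sorted(groups.values(), key=lambda s: sorted(s)),
    )


def jaccard_matrix(codes: BinaryCodeMatrix) -> pd.DataFrame:
    """Pairwise Jaccard similarity of cluster marker sets; both-empty pairs
    (including the diagonal of an all-zero row) score 0 by convention."""
    M = codes.matrix.to_numpy(dtype=float)
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return pd.DataFrame(J, index=codes.matrix.index, columns=codes.matrix.index)


def jaccard_ordering(
    codes: BinaryCodeMatrix, method: str = "average"
) -> JaccardOrdering:
    """Jaccard similarity matrix plus a most-to-least-similar cluster order.

    The order is the leaf order of hierarchical clustering (``method``
    linkage, default average) on distance 1 - J; cluster labels are sorted
    lexicographically beforehand so ties resolve deterministically."""
    labels = sorted(codes.matrix.index.astype(str))
    sorted_codes = BinaryCodeMatrix(
        tf_class=codes.tf_class,
        matrix=codes.matrix.loc[labels],
        source_alpha=codes.source_alpha,
    )
    J = jaccard_matrix(sorted_codes)
    if len(labels) == 1:
        return JaccardOrdering(similarity=J, order=labels)
    D = 1.0 - J.to_numpy()
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    order = [labels[i] for i in leaves_list(Z)]
    return JaccardOrdering(similarity=J, order=order)
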