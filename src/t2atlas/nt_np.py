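"""Neurotransmitter classification, neuropeptide restriction analysis, and
TF-neuropeptide correlation ranking.

Fast-acting transmitter identity is called per cell by thresholding one of
the derived expression layers for the seven pathway genes (VGlut, VAChT,
Gad1, Tdc2, ple, SerT, Tbh). The default is the z-scaled layer at
threshold 2; the log-normalised layer is an explicit alternative because
published descriptions of this style of analysis use both conventions.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._constants import NT_CLASS_OF_GENE, NT_GENES
from .markers import find_all_markers


@dataclass
class NTSummary:
    """Partition of cells into single-transmitter classes, multi-transmitter
    (>= 2 pathway genes above threshold) and transmitter-negative."""

    n_cells: int
    combination_counts: dict[tuple[str, ...], int]
    per_class_pct: dict[str, float]  # single-positive cells, % of all cells
    pct_multi: float
    pct_negative: float
    threshold: float = 2.0
    layer: str = "scaled"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cls, round(pct, 1)) for cls, pct in sorted(self.per_class_pct.items())
        ]
        rows.append(("multi (>=2 classes)", round(self.pct_multi, 1)))
        rows.append(("negative", round(self.pct_negative, 1)))
        return pd.DataFrame(rows, columns=["class", "pct_of_cells"])


@dataclass
class NPCorrelation:
    """TFs x neuropeptides correlation matrix with per-NP top-k TF lists."""

    matrix: pd.DataFrame  # TFs x NPs
    top: dict[str, list[tuple[str, float]]]
    method: str = "pearson"


def _layer_dense(adata: ad.AnnData, layer: str) -> np.ndarray:
    if layer not in adata.layers:
        raise ValueError(f"layer {layer!r} missing; run io_qc.normalize first")
    L = adata.layers[layer]
    return L.toarray() if hasattr(L, "toarray") else np.asarray(L)


def classify_neurotransmitters(
    adata: ad.AnnData,
    nt_genes: tuple[str, ...] = NT_GENES,
    threshold: float = 2.0,
    layer: str = "scaled",
) -> tuple[pd.DataFrame, NTSummary]:
    """Call per-cell transmitter positivity: bit j is set iff the chosen
    layer's value for pathway gene j exceeds ``threshold``.

    Returns the cells x genes boolean profile table and a summary
    partitioning cells into exactly-one-class (reported per class),
    multi-class and negative; the three blocks sum to 100% before
    rounding."""
    missing = [g for g in nt_genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"neurotransmitter gene(s) absent: {missing}")
    L = _layer_dense(adata, layer)
    cols = [adata.var_names.get_loc(g) for g in nt_genes]
    bits = L[:, cols] > threshold
    profiles = pd.DataFrame(bits, index=adata.obs_names, columns=list(nt_genes))
    summary = summarize_nt(profiles, threshold=threshold, layer=layer)
    return profiles, summary


def summarize_nt(
    profiles: pd.DataFrame, threshold: float = 2.0, layer: str = "scaled"
) -> NTSummary:
    n = len(profiles)
    combos = upset_counts(profiles)
    n_classes = profiles.sum(axis=1).to_numpy()
    per_class: dict[str, float] = {}
    for g in profiles.columns:
        single = (profiles[g].to_numpy()) & (n_classes == 1)
        per_class[NT_CLASS_OF_GENE.get(g, g)] = 100.0 * single.sum() / n if n else 0.0
    multi = 100.0 * (n_classes >= 2).sum() / n if n else 0.0
    negative = 100.0 * (n_classes == 0).sum() / n if n else 0.0
    return NTSummary(
        n_cells=n,
        combination_counts=combos,
        per_class_pct=per_class,
        pct_multi=float(multi),
        pct_negative=float(negative),
        threshold=threshold,
        layer=layer,
    )


def upset_counts(profiles: pd.DataFrame) -> dict[tuple[str, ...], int]:
    """Exact cell count for every observed positivity combination, keyed by
    the tuple of positive gene names in column order (empty tuple for
    negative cells); counts sum to the number of cells."""
    if len(profiles) == 0:
        raise ValueError("no profiles provided")
    genes = list(profiles.columns)
    counter: Counter[tuple[str, ...]] = Counter()
    for row in profiles.to_numpy():
        counter[tuple(g for g, b in zip(genes, row) if b)] += 1
    return dict(counter)


def cluster_defining_neuropeptides(
    adata: ad.AnnData,
    np_genes: list[str] | None = None,
    max_clusters: int = 4,
    alpha: float = 0.05,
    marker_table: pd.DataFrame | None = None,
) -> dict[str, set[str]]:
    """Neuropeptides whose expression defines a small set of clusters.

    A neuropeptide qualifies iff it is a significant positive marker
    (one-vs-rest test, adjusted p < ``alpha``) in at least one and at most
    ``max_clusters`` clusters; the map may be many-to-many (two NPs can
    share the same cluster pair, one NP can mark several clusters)."""
    if np_genes is None:
        np_genes = adata.var_names[
            adata.var["gene_class"] == "neuropeptide"
        ].tolist()
    present = []
    for g in np_genes:
        if g in adata.var_names:
            present.append(g)
        else:
            warnings.warn(f"neuropeptide gene absent, skipped: {g}", stacklevel=2)
    if marker_table is None:
        marker_table = find_all_markers(adata, only_pos=True, alpha=alpha)
    sig = marker_table[
        (marker_table["direction"] == "up")
        & (marker_table["p_adj"] < alpha)
        & (marker_table["gene"].isin(present))
    ]
    out: dict[str, set[str]] = {}
    for g, grp in sig.groupby("gene", observed=True):
        cs = set(grp["cluster"].astype(str))
        if 1 <= len(cs) <= max_clusters:
            out[str(g)] = cs
    return out


def tf_np_correlation(
    adata: ad.AnnData,
    tf_genes: list[str] | None = None,
    np_genes: list[str] | None = None,
    method: str = "pearson",
    top_k: int = 5,
) -> NPCorrelation:
    """Correlate TF and neuropeptide log-normalised expression across all
    cells; zero-variance genes yield coefficient 0 by convention. Top-k TF
    lists per neuropeptide are sorted descending with lexicographic
    tie-break."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method}")
    if adata.n_obs < 3:
        raise ValueError("need >= 3 cells for correlation analysis")
    if tf_genes is None:
        tf_genes = adata.var_names[adata.var["gene_class"] == "tf"].tolist()
    if np_genes is None:
        np_genes = adata.var_names[
            adata.var["gene_class"] == "neuropeptide"
        ].tolist()
    L = _layer_dense(adata, "lognorm")
    tf_idx = [adata.var_names.get_loc(g) for g in tf_genes]
    np_idx = [adata.var_names.get_loc(g) for g in np_genes]
    A = L[:, tf_idx].astype(float)
    B = L[:, np_idx].astype(float)
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
    r = np.clip(r, -1.0, 1.0)
    matrix = pd.DataFrame(r, index=tf_genes, columns=np_genes)
    top: dict[str, list[tuple[str, float]]] = {}
    for npg in np_genes:
        col = matrix[npg]
        ordered = sorted(zip(col.index, col.to_numpy()), key=lambda t: (-t[1], t[0]))
        top[npg] = [(g, float(v)) for g, v in ordered[:top_k]]
    return NPCorrelation(matrix=matrix, top=top, method=method)
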