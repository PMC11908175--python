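"""One-vs-rest marker detection and cluster expression profiles.

The test is the two-sided Wilcoxon rank-sum on log-normalised expression
(tie-corrected normal approximation with continuity correction), the same
statistic Seurat's FindAllMarkers applies by default, computed here
vectorised from per-gene ranks. Benjamini-Hochberg adjustment is applied
per cluster over the genes actually tested. Fold-changes follow the
``log2((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1))`` convention so
results can be cross-checked against Seurat output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

MARKER_COLUMNS = (
    "cluster",
    "gene",
    "log2fc",
    "pct_in",
    "pct_out",
    "p_value",
    "p_adj",
    "direction",
)


@dataclass
class ClusterProfile:
    """Cluster-level expression summaries.

    ``mean_lognorm``: clusters x genes mean of the lognorm layer.
    ``scaled_avg``: per-gene z-score of ``mean_lognorm`` across clusters
    (population SD; zero-variance genes map to 0) — the "scaled average
    expression" used for marker heatmaps and enhancer-gene scoring.
    """

    mean_lognorm: pd.DataFrame
    scaled_avg: pd.DataFrame


def _lognorm_dense(adata: ad.AnnData) -> np.ndarray:
    if "lognorm" not in adata.layers:
        raise ValueError("lognorm layer missing; run io_qc.normalize first")
    L = adata.layers["lognorm"]
    return L.toarray() if hasattr(L, "toarray") else np.asarray(L)


def _tie_term(L: np.ndarray) -> np.ndarray:
    """Per-gene sum of t^3 - t over tied groups, for the rank-sum variance."""
    n, g = L.shape
    out = np.zeros(g)
    for j in range(g):
        _, counts = np.unique(L[:, j], return_counts=True)
        t = counts[counts > 1].astype(float)
        out[j] = (t**3 - t).sum()
    return out


def find_all_markers(
    adata: ad.AnnData,
    only_pos: bool = True,
    min_pct: float = 0.1,
    min_log2fc: float = 0.25,
    alpha: float = 0.05,
    cluster_key: str = "cluster",
) -> pd.DataFrame:
    """Detect differentially expressed genes for every cluster vs the rest.

    Genes detected in fewer than ``min_pct`` of cells in both groups, or
    with |log2 fold-change| below ``min_log2fc`` (log2fc below it, when
    ``only_pos``), are excluded before testing; BH adjustment runs per
    cluster over the tested set. Clusters with fewer than 3 cells are
    skipped with a warning.

    Returns a table with columns cluster, gene, log2fc, pct_in, pct_out,
    p_value, p_adj, direction; the full cluster list and parameters are
    stored in ``.attrs``.
    """
    L = _lognorm_dense(adata)
    n_cells, n_genes = L.shape
    clusters = pd.Series(adata.obs[cluster_key].astype(str).to_numpy())
    cluster_ids = sorted(clusters.unique())
    if len(cluster_ids) < 2:
        out = pd.DataFrame(columns=MARKER_COLUMNS)
        out.attrs.update(
            clusters=cluster_ids, only_pos=only_pos, min_pct=min_pct,
            min_log2fc=min_log2fc, alpha=alpha,
        )
        return out

    detected = L > 0
    expm1 = np.expm1(L)
    ranks = np.apply_along_axis(rankdata, 0, L) if n_genes == 1 else rankdata(L, axis=0)
    tie = _tie_term(L)

    records: list[pd.DataFrame] = []
    for c in cluster_ids:
        in_mask = (clusters == c).to_numpy()
        n1 = int(in_mask.sum())
        n2 = n_cells - n1
        if n1 < 3:
            warnings.warn(f"cluster {c} has {n1} cells (<3); skipped", stacklevel=2)
            continue
        if n2 < 1:
            continue

        pct_in = detected[in_mask].mean(axis=0)
        pct_out = detected[~in_mask].mean(axis=0)
        mean_in = expm1[in_mask].mean(axis=0)
        mean_out = expm1[~in_mask].mean(axis=0)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))

        keep = np.maximum(pct_in, pct_out) >= min_pct
        keep &= log2fc >= min_log2fc if only_pos else np.abs(log2fc) >= min_log2fc
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue

        # tie-corrected normal approximation of the two-sided rank-sum test
        rank_sum_in = ranks[in_mask][:, idx].sum(axis=0)
        u = rank_sum_in - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        var = (
            n1 * n2 / 12.0
            * ((n_cells + 1) - tie[idx] / (n_cells * (n_cells - 1.0)))
        )
        sd = np.sqrt(var)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (u - mu - np.sign(u - mu) * 0.5) / np.where(sd > 0, sd, 1.0), 0.0)
        p = 2.0 * norm.sf(np.abs(z))
        p = np.clip(p, 0.0, 1.0)
        p_adj = multipletests(p, method="fdr_bh")[1]

        frame = pd.DataFrame(
            {
                "cluster": c,
                "gene": adata.var_names.to_numpy()[idx],
                "log2fc": log2fc[idx],
                "pct_in": pct_in[idx],
                "pct_out": pct_out[idx],
                "p_value": p,
                "p_adj": p_adj,
                "direction": np.where(log2fc[idx] > 0, "up", "down"),
            }
        )
        if only_pos:
            frame = frame[frame["direction"] == "up"]
        records.append(frame)

    out = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=MARKER_COLUMNS)
    )
    out.attrs.update(
        clusters=cluster_ids, only_pos=only_pos, min_pct=min_pct,
        min_log2fc=min_log2fc, alpha=alpha,
    )
    return out


def cluster_profile(adata: ad.AnnData, cluster_key: str = "cluster") -> ClusterProfile:
    """Per-cluster mean log-normalised expression and its per-gene z-score
    across clusters (zero-variance genes map to 0)."""
    L = _lognorm_dense(adata)
    clusters = adata.obs[cluster_key].astype(str).to_numpy()
    frame = pd.DataFrame(L, index=adata.obs_names, columns=adata.var_names)
    mean = frame.groupby(pd.Series(clusters, index=frame.index), observed=True).mean()
    mean = mean.sort_index()
    mu = mean.mean(axis=0)
    sd = mean.std(axis=0, ddof=0)
    scaled = (mean - mu).div(sd.where(sd > 0, 1.0), axis=1)
    scaled.loc[:, sd == 0] = 0.0
    return ClusterProfile(mean_lognorm=mean, scaled_avg=scaled)


def top_markers(
    table: pd.DataFrame, n: int = 10, alpha: float = 0.05
) -> dict[str, list[str]]:
    """Per cluster, the ``n`` up-regulated markers with largest log2
    fold-change among records with ``p_adj < alpha``. Ties break by smaller
    adjusted p-value, then lexicographic gene ID; clusters with fewer than
    ``n`` qualifying genes return all of them."""
    if table.empty:
        return {}
    qual = table[(table["direction"] == "up") & (table["p_adj"] < alpha)]
    out: dict[str, list[str]] = {}
    for c, grp in qual.groupby("cluster", observed=True):
        ordered = grp.sort_values(
            ["log2fc", "p_adj", "gene"], ascending=[False, True, True]
        )
        out[str(c)] = ordered["gene"].head(n).tolist()
    return out
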