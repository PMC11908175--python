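"""Sex-composition bias across clusters and sex differential expression.

Cells from mixed-sex samples carry no per-cell sex information and are
excluded throughout. Sample input sizes are equalised by weighting: each
sexed sample contributes the same total weight, rescaled to the mean
sexed-sample size so weighted counts stay on the scale of cell numbers.
The expected female fraction and the per-cluster observed fractions are
both computed on these weights, which makes the fractions (and the
log2 odds ratios built from them) exactly invariant to replicating all
cells of one sex's samples.

Differential expression between sexes aggregates raw counts into
pseudobulk units (one per sample, or per sample x cluster) before testing,
falling back to a per-cell test with a recorded warning when a side has
fewer than two replicate units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import binomtest, mannwhitneyu
from statsmodels.stats.multitest import multipletests

REPORT_COLUMNS = (
    "cluster",
    "n_female",
    "n_male",
    "expected_female_frac",
    "observed_female_frac",
    "log2_ratio",
    "p_value",
    "p_adj",
    "biased",
)


@dataclass
class SexBiasReport:
    table: pd.DataFrame  # one row per cluster, REPORT_COLUMNS
    excluded_samples: list[str]
    alpha: float = 0.05
    min_log2_ratio: float = 1.0

    @property
    def biased_clusters(self) -> dict[str, str]:
        sub = self.table[self.table["biased"] != "none"]
        return dict(zip(sub["cluster"], sub["biased"]))


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    X = adata.X
    return X.tocsr() if sp.issparse(X) else sp.csr_matrix(X)


def detect_sex_biased_clusters(
    adata: ad.AnnData,
    alpha: float = 0.05,
    min_log2_ratio: float = 1.0,
    cluster_key: str = "cluster",
) -> SexBiasReport:
    """Flag clusters whose sex composition departs from the input-normalised
    expectation.

    Per cluster, a two-sided binomial test compares the (weighted) female
    count against the expected female fraction; BH adjustment runs over
    clusters. A cluster is called biased when adjusted p < ``alpha`` and
    |log2(observed odds / expected odds)| >= ``min_log2_ratio``, with the
    direction given by the sign.
    """
    sex = adata.obs["sex"].astype(str)
    sample = adata.obs["sample"].astype(str)
    sexed = sex.isin(["female", "male"])
    excluded = sorted(sample[~sexed].unique())
    if not sexed.any():
        raise ValueError("no cells with per-cell sex information")

    obs = adata.obs.loc[sexed.to_numpy(), [cluster_key]].copy()
    obs["sex"] = sex[sexed].to_numpy()
    obs["sample"] = sample[sexed].to_numpy()
    sample_sizes = obs["sample"].value_counts()
    mean_size = sample_sizes.mean()
    weight = obs["sample"].map(mean_size / sample_sizes).to_numpy()
    obs["w"] = weight

    total_w = obs["w"].sum()
    female_w = obs.loc[obs["sex"] == "female", "w"].sum()
    expected = female_w / total_w
    if expected in (0.0, 1.0):
        raise ValueError("need cells of both sexes after excluding mixed samples")

    rows = []
    for c, grp in obs.groupby(cluster_key, observed=True):
        n_f = int((grp["sex"] == "female").sum())
        n_m = int((grp["sex"] == "male").sum())
        if n_f + n_m == 0:
            continue
        wf = grp.loc[grp["sex"] == "female", "w"].sum()
        wm = grp.loc[grp["sex"] == "male", "w"].sum()
        obs_frac = wf / (wf + wm)
        k = int(round(wf))
        n = max(int(round(wf + wm)), 1)
        k = min(k, n)
        p = binomtest(k, n, expected, alternative="two-sided").pvalue
        # epsilon on the fraction scale keeps the ratio invariant to
        # replicating a whole sex's samples
        eps = 1e-6
        f_clip = min(max(obs_frac, eps), 1.0 - eps)
        odds_obs = f_clip / (1.0 - f_clip)
        odds_exp = expected / (1.0 - expected)
        log2_ratio = float(np.log2(odds_obs / odds_exp))
        rows.append((str(c), n_f, n_m, expected, obs_frac, log2_ratio, p))

    table = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "n_female",
            "n_male",
            "expected_female_frac",
            "observed_female_frac",
            "log2_ratio",
            "p_value",
        ],
    )
    if table.empty:
        table["p_adj"] = []
        table["biased"] = []
        return SexBiasReport(
            table=table, excluded_samples=excluded,
            alpha=alpha, min_log2_ratio=min_log2_ratio,
        )
    table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
    biased = np.where(
        (table["p_adj"] < alpha) & (table["log2_ratio"] >= min_log2_ratio),
        "female",
        np.where(
            (table["p_adj"] < alpha) & (table["log2_ratio"] <= -min_log2_ratio),
            "male",
            "none",
        ),
    )
    table["biased"] = biased
    return SexBiasReport(
        table=table,
        excluded_samples=excluded,
        alpha=alpha,
        min_log2_ratio=min_log2_ratio,
    )


def pseudobulk_de(
    adata: ad.AnnData,
    scope: str = "global",
    alpha: float = 0.05,
    cluster_key: str = "cluster",
) -> pd.DataFrame:
    """Male-vs-female differential expression on pseudobulk log2 CPM.

    Counts are summed per (sample) unit — per (sample, cluster) with
    ``scope="per_cluster"`` — depth-normalised to log2(CPM + 1), and tested
    per gene with a two-sided rank-sum across units; BH adjustment per
    scope. With fewer than two units on either side the test falls back to
    per-cell rank-sum; the fallback is recorded in ``.attrs`` and warned.
    Positive ``log2fc_male_vs_female`` means higher in males.
    """
    if scope not in ("global", "per_cluster"):
        raise ValueError(f"unknown scope: {scope}")
    sex = adata.obs["sex"].astype(str)
    sexed = sex.isin(["female", "male"]).to_numpy()
    sub = adata[sexed]
    X = _counts(sub)

    frames = []
    fallbacks: list[str] = []
    if scope == "global":
        scopes = [("global", np.ones(sub.n_obs, dtype=bool))]
    else:
        scopes = [
            (f"cluster:{c}", (sub.obs[cluster_key].astype(str) == str(c)).to_numpy())
            for c in sorted(sub.obs[cluster_key].astype(str).unique())
        ]

    for scope_name, mask in scopes:
        s = sub[mask]
        if s.n_obs == 0:
            continue
        Xs = _counts(s)
        units = s.obs["sample"].astype(str).to_numpy()
        unit_sex = (
            pd.DataFrame({"unit": units, "sex": s.obs["sex"].astype(str).to_numpy()})
            .drop_duplicates()
            .set_index("unit")["sex"]
        )
        f_units = unit_sex.index[unit_sex == "female"].tolist()
        m_units = unit_sex.index[unit_sex == "male"].tolist()

        if len(f_units) >= 2 and len(m_units) >= 2:
            agg = np.vstack(
                [
                    np.asarray(Xs[units == u].sum(axis=0)).ravel()
                    for u in unit_sex.index
                ]
            ).astype(float)
            depth = agg.sum(axis=1, keepdims=True)
            depth[depth == 0] = 1.0
            logcpm = np.log2(1e6 * agg / depth + 1.0)
            fmask = unit_sex.to_numpy() == "female"
        else:
            fallbacks.append(scope_name)
            warnings.warn(
                f"{scope_name}: <2 pseudobulk units per sex; "
                "falling back to per-cell test",
                stacklevel=2,
            )
            dense = Xs.toarray().astype(float)
            depth = dense.sum(axis=1, keepdims=True)
            depth[depth == 0] = 1.0
            logcpm = np.log2(1e6 * dense / depth + 1.0)
            fmask = (s.obs["sex"].astype(str) == "female").to_numpy()

        F = logcpm[fmask]
        M = logcpm[~fmask]
        cpm_f = np.expm1(F * np.log(2)).mean(axis=0)  # mean CPM per gene
        cpm_m = np.expm1(M * np.log(2)).mean(axis=0)
        log2fc = np.log2((cpm_m + 1.0) / (cpm_f + 1.0))
        pvals = np.ones(logcpm.shape[1])
        varying = (logcpm.std(axis=0) > 0) & (len(F) > 0) & (len(M) > 0)
        if varying.any():
            # exact null for small replicate designs; asymptotic otherwise
            how = "exact" if 2 <= min(len(F), len(M)) <= 12 else "asymptotic"
            res = mannwhitneyu(
                M[:, varying], F[:, varying], alternative="two-sided",
                axis=0, method=how,
            )
            pvals[varying] = res.pvalue
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "gene": sub.var_names,
                    "log2fc_male_vs_female": log2fc,
                    "p_value": pvals,
                    "p_adj": p_adj,
                    "scope": scope_name,
                }
            )
        )

    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["gene", "log2fc_male_vs_female", "p_value", "p_adj", "scope"]
        )
    )
    out.attrs["fallback_scopes"] = fallbacks
    out.attrs["alpha"] = alpha
    return out
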