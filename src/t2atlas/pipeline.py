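"""Pipeline orchestration: config, stage sequencing, provenance.

``run_pipeline`` executes the analysis stages in order — QC, lineage
assignment, (optional clustering hook), marker detection, NT/NP
classification, TF combinatorial codes, sex bias, cluster mapping — on a
dataset directory or a freshly simulated dataset, writing one TSV/JSON
artifact per stage plus a provenance manifest (config hash, seed, package
version, file checksums). Reruns with the same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster_mapping, io_qc, markers, nt_np, sex_bias, synthetic, tf_codes
from ._constants import GLIAL_MARKER, TF_CLASSES


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults match the per-module defaults."""

    input_dir: str | None = None  # dataset directory; None -> simulate
    out_dir: str = "t2atlas_out"
    seed: int = 0

    # stage toggles
    run_qc: bool = True
    run_lineage: bool = True
    run_markers: bool = True
    run_nt: bool = True
    run_np: bool = True
    run_tfnp: bool = True
    run_tfcodes: bool = True
    run_sexbias: bool = True
    run_map: bool = False

    # QC
    min_genes: int = 200
    max_genes: int = 2500
    max_mito: float = 0.05
    scale_factor: float = 1e4

    # lineage / subsetting
    transgene_min_counts: int = 1
    glial_gene: str = GLIAL_MARKER
    glial_min_frac: float = 0.5

    # clustering hook (plumbing for inputs without cluster labels)
    cluster_method: str = "none"  # none | kmeans
    n_clusters_hint: int = 10

    # markers
    only_pos: bool = True
    min_pct: float = 0.1
    min_log2fc: float = 0.25
    alpha: float = 0.05
    top_n: int = 10

    # NT / NP
    nt_threshold: float = 2.0
    nt_layer: str = "scaled"
    np_max_clusters: int = 4
    corr_method: str = "pearson"
    top_k: int = 5

    # sex bias
    bias_alpha: float = 0.05
    bias_min_log2_ratio: float = 1.0
    de_scope: str = "global"

    # mapping inputs
    bulk_profiles: str | None = None
    drivers: str | None = None
    predicate: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.min_genes > self.max_genes:
            raise ConfigError(
                f"min_genes ({self.min_genes}) > max_genes ({self.max_genes})"
            )
        if not 0.0 <= self.max_mito <= 1.0:
            raise ConfigError("max_mito must be in [0, 1]")
        if self.nt_layer not in ("scaled", "lognorm"):
            raise ConfigError(f"nt_layer must be scaled or lognorm, got {self.nt_layer}")
        if self.corr_method not in ("pearson", "spearman"):
            raise ConfigError(f"unknown corr_method: {self.corr_method}")
        if self.cluster_method not in ("none", "kmeans"):
            raise ConfigError(f"unknown cluster_method: {self.cluster_method}")
        if self.de_scope not in ("global", "per_cluster"):
            raise ConfigError(f"unknown de_scope: {self.de_scope}")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cluster_hook(adata, n_clusters: int, seed: int = 0):
    """Library-backed fallback clustering for inputs lacking labels.

    This is plumbing, not part of the analysed method: upstream graph-based
    clustering is assumed done, and its labels consumed as input. K-means
    on the scaled layer stands in when labels are absent entirely.
    """
    from sklearn.cluster import KMeans

    layer = adata.layers.get("scaled")
    if layer is None:
        raise ValueError("run io_qc.normalize before the clustering hook")
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(np.asarray(layer))
    out = adata.copy()
    out.obs["cluster"] = [f"k{int(x):02d}" for x in labels]
    return out


def _write_tsv(frame: pd.DataFrame, path: Path, **kw) -> None:
    frame.to_csv(path, sep="\t", float_format="%.6g", **kw)


def run_pipeline(config: PipelineConfig):
    """Execute configured stages in order; returns the run manifest dict."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    stage = "load"

    try:
        if config.input_dir is None:
            spec = synthetic.SyntheticSpec(seed=config.seed)
            adata, _truth = synthetic.generate(spec)
        else:
            adata = io_qc.read_dataset(config.input_dir)

        if config.run_qc:
            stage = "qc"
            adata, report = io_qc.qc_filter(
                adata, config.min_genes, config.max_genes, config.max_mito
            )
            with open(out_dir / "qc_report.json", "w") as fh:
                json.dump(dataclasses.asdict(report), fh, indent=2, sort_keys=True)
            outputs.append("qc_report.json")

        stage = "normalize"
        adata = io_qc.normalize(adata, scale_factor=config.scale_factor)

        if config.run_lineage:
            stage = "lineage"
            adata = io_qc.assign_lineage(adata, min_counts=config.transgene_min_counts)
            summary = io_qc.LineageSummary.from_anndata(adata)
            with open(out_dir / "lineage_summary.json", "w") as fh:
                json.dump(dataclasses.asdict(summary), fh, indent=2, sort_keys=True)
            outputs.append("lineage_summary.json")

        if "cluster" not in adata.obs or adata.obs["cluster"].isna().all():
            if config.cluster_method == "kmeans":
                stage = "cluster_hook"
                adata = cluster_hook(adata, config.n_clusters_hint, config.seed)
            else:
                raise ConfigError(
                    "input has no cluster labels; set cluster_method: kmeans "
                    "or provide labels"
                )

        marker_table = None
        if config.run_markers or config.run_np or config.run_tfcodes:
            stage = "markers"
            marker_table = markers.find_all_markers(
                adata,
                only_pos=config.only_pos,
                min_pct=config.min_pct,
                min_log2fc=config.min_log2fc,
                alpha=config.alpha,
            )
            if config.run_markers:
                _write_tsv(marker_table, out_dir / "markers.tsv", index=False)
                outputs.append("markers.tsv")
                tops = markers.top_markers(marker_table, n=config.top_n, alpha=config.alpha)
                top_frame = pd.DataFrame(
                    [(c, i + 1, g) for c, gs in sorted(tops.items())
                     for i, g in enumerate(gs)],
                    columns=["cluster", "rank", "gene"],
                )
                _write_tsv(top_frame, out_dir / "top_markers.tsv", index=False)
                outputs.append("top_markers.tsv")

        profile = markers.cluster_profile(adata)

        if config.run_nt:
            stage = "nt"
            profiles, summary = nt_np.classify_neurotransmitters(
                adata, threshold=config.nt_threshold, layer=config.nt_layer
            )
            _write_tsv(summary.to_frame(), out_dir / "nt_summary.tsv", index=False)
            upset = pd.DataFrame(
                sorted(
                    (("&".join(k) or "none", v)
                     for k, v in summary.combination_counts.items()),
                ),
                columns=["combination", "n_cells"],
            )
            _write_tsv(upset, out_dir / "nt_upset.tsv", index=False)
            outputs += ["nt_summary.tsv", "nt_upset.tsv"]

        if config.run_np:
            stage = "np"
            np_map = nt_np.cluster_defining_neuropeptides(
                adata,
                max_clusters=config.np_max_clusters,
                alpha=config.alpha,
                marker_table=marker_table,
            )
            np_frame = pd.DataFrame(
                [(g, c) for g, cs in sorted(np_map.items()) for c in sorted(cs)],
                columns=["neuropeptide", "cluster"],
            )
            _write_tsv(np_frame, out_dir / "np_report.tsv", index=False)
            outputs.append("np_report.tsv")

        if config.run_tfnp:
            stage = "tfnp"
            corr = nt_np.tf_np_correlation(
                adata, method=config.corr_method, top_k=config.top_k
            )
            _write_tsv(corr.matrix, out_dir / "tfnp_correlation.tsv",
                       index_label="tf")
            outputs.append("tfnp_correlation.tsv")

        if config.run_tfcodes:
            stage = "tfcodes"
            stats_all = {}
            for cls in TF_CLASSES:
                if (adata.var["tf_class"] == cls).sum() == 0:
                    continue
                code = tf_codes.binarize_tf_markers(
                    marker_table, adata.var, cls, alpha=config.alpha
                )
                _write_tsv(code.matrix, out_dir / f"tf_code_{cls}.tsv",
                           index_label="cluster")
                outputs.append(f"tf_code_{cls}.tsv")
                stats = tf_codes.unique_code_stats(code)
                stats_all[cls] = {
                    "n_clusters": stats.n_clusters,
                    "n_unique": stats.n_unique,
                    "pct_unique": stats.pct_unique,
                    "duplicate_groups": [sorted(g) for g in stats.duplicate_groups],
                }
                ordering = tf_codes.jaccard_ordering(code)
                _write_tsv(
                    ordering.similarity.loc[ordering.order, ordering.order],
                    out_dir / f"tf_jaccard_{cls}.tsv",
                    index_label="cluster",
                )
                outputs.append(f"tf_jaccard_{cls}.tsv")
            with open(out_dir / "tf_code_stats.json", "w") as fh:
                json.dump(stats_all, fh, indent=2, sort_keys=True)
            outputs.append("tf_code_stats.json")

        if config.run_sexbias:
            stage = "sexbias"
            report = sex_bias.detect_sex_biased_clusters(
                adata, alpha=config.bias_alpha,
                min_log2_ratio=config.bias_min_log2_ratio,
            )
            _write_tsv(report.table, out_dir / "sex_bias.tsv", index=False)
            de = sex_bias.pseudobulk_de(adata, scope=config.de_scope)
            _write_tsv(de, out_dir / "pseudobulk_de.tsv", index=False)
            outputs += ["sex_bias.tsv", "pseudobulk_de.tsv"]

        if config.run_map:
            stage = "map"
            if config.bulk_profiles:
                bulk = cluster_mapping.read_bulk_profiles(config.bulk_profiles)
                records, coeff = cluster_mapping.bulk_correlation_map(
                    profile, bulk, method=config.corr_method
                )
                _write_tsv(records, out_dir / "bulk_mapping.tsv", index=False)
                _write_tsv(coeff, out_dir / "bulk_coefficients.tsv",
                           index_label="cluster")
                outputs += ["bulk_mapping.tsv", "bulk_coefficients.tsv"]
            if config.drivers:
                with open(config.drivers) as fh:
                    raw = yaml.safe_load(fh)
                driver_table = {
                    d: (v["cell_type"], list(v["enhancer_genes"]))
                    for d, v in raw.items()
                }
                rec = cluster_mapping.enhancer_gene_assignment(profile, driver_table)
                _write_tsv(rec, out_dir / "enhancer_mapping.tsv", index=False)
                outputs.append("enhancer_mapping.tsv")
            if config.predicate:
                pred = cluster_mapping.MarkerPredicate.parse(config.predicate)
                hits = cluster_mapping.marker_logic_assignment(adata, pred)
                frame = pd.DataFrame(sorted(hits), columns=["cluster"])
                _write_tsv(frame, out_dir / "marker_logic.tsv", index=False)
                outputs.append("marker_logic.tsv")
    except Exception as exc:
        record = {"stage": stage, "error": type(exc).__name__, "message": str(exc)}
        with open(out_dir / "error.json", "w") as fh:
            json.dump(record, fh, indent=2)
        raise

    from . import __version__ as pkg_version

    manifest = {
        "version": pkg_version,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "outputs": {
            f: hashlib.sha256((out_dir / f).read_bytes()).hexdigest()
            for f in outputs
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
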