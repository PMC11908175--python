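"""Synthetic snRNA-seq data with full ground truth.

Emulates the structure of a T1+T2 adult central-brain single-nucleus
experiment: negative-binomial UMI counts with log-normal library-size
variation, planted per-cluster marker genes, lineage-tracing transgenes
(FLP/GFP/RFP) expressed only in T2-derived cells subject to per-cell
detection dropout, a pan-glial marker (repo) in glial clusters, the seven
fast-acting neurotransmitter pathway genes, 49 neuropeptide genes of which
a planted subset is cluster-restricted, transcription-factor genes in six
DNA-binding-domain classes expressing planted per-cluster binary codes,
sex-specific genes (yolk proteins in females, roX lncRNAs in males), and
mitochondrial genes with controllable per-cell fractions.

Every planted signal is recorded in :class:`GroundTruth` so downstream
stages can be scored against construction rather than convention.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._constants import (
    GLIAL_MARKER,
    MITO_GENES,
    NT_CLASS_OF_GENE,
    NT_GENES,
    TF_CLASSES,
    TRANSGENES,
)

N_NEUROPEPTIDES = 49


class SpecValidationError(ValueError):
    """A SyntheticSpec field is inconsistent; the message names the field."""


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults describe a small but structurally complete experiment: twelve
    clusters (two glial) of 100 cells, one female, one male and one
    mixed-sex sample, planted markers at log2 fold-change 3, and distinct
    planted TF codes per DNA-binding-domain class.
    """

    n_cells_per_cluster: int = 100
    n_clusters: int = 12
    n_glial_clusters: int = 2
    n_genes_background: int = 200
    markers_per_cluster: int = 5
    marker_log2fc: float = 3.0
    nb_dispersion: float = 2.0
    base_mean: float = 0.5
    t2_fraction: float = 0.5
    transgene_detection_rate: float = 0.9
    sex_design: Mapping[str, str] = field(
        default_factory=lambda: {"F1": "female", "M1": "male", "X1": "mixed"}
    )
    tf_class_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "zinc_finger": 10,
            "helix_turn_helix": 8,
            "homeodomain": 8,
            "basic_domain": 6,
            "unspecified_dbd": 6,
            "hmg": 4,
        }
    )
    # per TF class: clusters x TFs 0/1 array; None -> random distinct codes
    planted_codes: Mapping[str, np.ndarray] | None = None
    # cluster id -> subset of the 7 NT genes; None -> sparse default rotation
    nt_assignment: Mapping[str, Sequence[str]] | None = None
    # neuropeptide gene -> clusters expressing it; None -> 13 restricted NPs
    np_assignment: Mapping[str, Sequence[str]] | None = None
    sex_genes: Mapping[str, Sequence[tuple[str, float]]] = field(
        default_factory=lambda: {
            "female": [("yp1", 3.0), ("yp2", 3.0), ("yp3", 3.0)],
            "male": [("roX1", 3.0), ("roX2", 3.0)],
        }
    )
    # cluster id -> target female fraction among single-sex-sample cells
    sex_bias_design: Mapping[str, float] = field(default_factory=dict)
    mito_fraction_range: tuple[float, float] = (0.0, 0.04)
    seed: int = 0

    # emission levels (mean counts) for planted on/off programmes
    tf_on_mean: float = 4.0
    tf_off_mean: float = 0.02
    nt_on_mean: float = 8.0
    nt_off_mean: float = 0.01
    np_on_mean: float = 6.0
    np_off_mean: float = 0.02
    glial_marker_mean: float = 6.0
    transgene_mean: float = 3.0
    libsize_sigma: float = 0.3

    def cluster_ids(self) -> list[str]:
        return [f"c{i:02d}" for i in range(self.n_clusters)]

    def glial_cluster_ids(self) -> list[str]:
        return self.cluster_ids()[: self.n_glial_clusters]

    def validate(self) -> None:
        clusters = set(self.cluster_ids())
        if self.n_cells_per_cluster <= 0:
            raise SpecValidationError("n_cells_per_cluster must be positive")
        if self.n_clusters <= 0:
            raise SpecValidationError("n_clusters must be positive")
        if not 0 <= self.n_glial_clusters < self.n_clusters:
            raise SpecValidationError(
                "n_glial_clusters must be in [0, n_clusters)"
            )
        if not 0.0 <= self.t2_fraction <= 1.0:
            raise SpecValidationError("t2_fraction must be in [0, 1]")
        if not 0.0 <= self.transgene_detection_rate <= 1.0:
            raise SpecValidationError(
                "transgene_detection_rate must be in [0, 1]"
            )
        lo, hi = self.mito_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise SpecValidationError(
                "mito_fraction_range must be an interval within [0, 1]"
            )
        for name in self.tf_class_sizes:
            if name not in TF_CLASSES:
                raise SpecValidationError(f"tf_class_sizes: unknown class {name}")
        if self.planted_codes is not None:
            for cls, mat in self.planted_codes.items():
                mat = np.asarray(mat)
                want = (self.n_clusters, self.tf_class_sizes.get(cls, -1))
                if mat.shape != want:
                    raise SpecValidationError(
                        f"planted_codes[{cls}] has shape {mat.shape}, "
                        f"expected {want}"
                    )
                if not np.isin(mat, (0, 1)).all():
                    raise SpecValidationError(
                        f"planted_codes[{cls}] must be binary"
                    )
        if self.nt_assignment is not None:
            for c, genes in self.nt_assignment.items():
                if c not in clusters:
                    raise SpecValidationError(
                        f"nt_assignment: unknown cluster {c}"
                    )
                bad = set(genes) - set(NT_GENES)
                if bad:
                    raise SpecValidationError(
                        f"nt_assignment[{c}]: unknown NT gene(s) {sorted(bad)}"
                    )
        if self.np_assignment is not None:
            for gene, cs in self.np_assignment.items():
                bad = set(cs) - clusters
                if bad:
                    raise SpecValidationError(
                        f"np_assignment[{gene}]: unknown cluster(s) {sorted(bad)}"
                    )
        for c in self.sex_bias_design:
            if c not in clusters:
                raise SpecValidationError(f"sex_bias_design: unknown cluster {c}")
        if not any(v == "female" for v in self.sex_design.values()) or not any(
            v == "male" for v in self.sex_design.values()
        ):
            raise SpecValidationError(
                "sex_design must include at least one female and one male sample"
            )


@dataclass
class GroundTruth:
    """Planted truth for one generated dataset."""

    cell_lineage: pd.Series  # T1 / T2 per cell (pre-dropout truth)
    cluster_of_cell: pd.Series
    marker_genes: dict[str, list[str]]  # cluster -> planted markers
    tf_code: dict[str, pd.DataFrame]  # class -> clusters x TFs 0/1
    nt_labels: dict[str, frozenset[str]]  # cell -> true NT classes
    np_clusters: dict[str, set[str]]  # restricted NP -> clusters
    sex_of_cell: pd.Series  # true sex incl. inside mixed samples
    sex_biased_clusters: set[str]
    glial_clusters: set[str]


def _default_codes(spec: SyntheticSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Random per-class codes, distinct across clusters whenever 2**n_tfs
    allows. Codes are sparse (density ~0.35): a TF expressed in nearly every
    cluster is not a positive one-vs-rest marker of any of them, so only
    cluster-restricted TFs can carry a recoverable code."""
    codes: dict[str, np.ndarray] = {}
    for cls, n_tf in spec.tf_class_sizes.items():
        seen: set[tuple] = set()
        rows = []
        for _ in range(spec.n_clusters):
            for _attempt in range(200):
                row = (rng.random(n_tf) < 0.35).astype(np.int8)
                key = tuple(row.tolist())
                if key not in seen or len(seen) >= 2**n_tf:
                    seen.add(key)
                    rows.append(row)
                    break
        codes[cls] = np.vstack(rows)
    return codes


def _default_nt_assignment(spec: SyntheticSpec) -> dict[str, list[str]]:
    """Sparse rotation over neuronal clusters: each NT gene on in about one
    cluster so single-gene positive fractions stay low, plus one
    co-expressing cluster when room allows (mirrors multi-transmitter
    cells)."""
    neuronal = spec.cluster_ids()[spec.n_glial_clusters :]
    assignment: dict[str, list[str]] = {}
    for i, c in enumerate(neuronal):
        if i < len(NT_GENES):
            assignment[c] = [NT_GENES[i]]
    if len(neuronal) > len(NT_GENES):
        assignment[neuronal[len(NT_GENES)]] = list(NT_GENES[:2])
    return assignment


def _default_np_assignment(spec: SyntheticSpec, rng: np.random.Generator) -> dict[str, list[str]]:
    """Thirteen cluster-restricted neuropeptides planted in 1-3 neuronal
    clusters each, including the many-to-many motif of two neuropeptides
    sharing the same two clusters."""
    neuronal = spec.cluster_ids()[spec.n_glial_clusters :]
    if not neuronal:
        return {}
    names = [f"np{i:02d}" for i in range(N_NEUROPEPTIDES)]
    assignment: dict[str, list[str]] = {}
    n_restricted = min(13, N_NEUROPEPTIDES)
    shared = neuronal[: min(2, len(neuronal))]
    # two NPs sharing the same cluster pair
    assignment[names[0]] = list(shared)
    assignment[names[1]] = list(shared)
    for k in range(2, n_restricted):
        width = 1 + (k % 3)
        start = rng.integers(0, len(neuronal))
        assignment[names[k]] = [
            neuronal[(start + j) % len(neuronal)] for j in range(min(width, len(neuronal)))
        ]
    return assignment


def _gene_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Assemble the gene universe with class annotations."""
    rows: list[tuple[str, str, str]] = []
    for i in range(spec.n_genes_background):
        rows.append((f"bg{i:04d}", "other", "none"))
    for c in spec.cluster_ids():
        for j in range(spec.markers_per_cluster):
            rows.append((f"mk_{c}_{j}", "other", "none"))
    for cls in TF_CLASSES:
        for j in range(spec.tf_class_sizes.get(cls, 0)):
            rows.append((f"tf_{cls}_{j:02d}", "tf", cls))
    for g in NT_GENES:
        rows.append((g, "nt_pathway", "none"))
    for i in range(N_NEUROPEPTIDES):
        rows.append((f"np{i:02d}", "neuropeptide", "none"))
    for g in TRANSGENES:
        rows.append((g, "transgene", "none"))
    rows.append((GLIAL_MARKER, "glial_marker", "none"))
    for sex in ("female", "male"):
        for g, _fc in spec.sex_genes.get(sex, []):
            rows.append((g, "sex_marker", "none"))
    for g in MITO_GENES:
        rows.append((g, "mito", "none"))
    table = pd.DataFrame(rows, columns=["gene_id", "gene_class", "tf_class"])
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise SpecValidationError(f"gene universe has duplicate ids: {dup}")
    return table.set_index("gene_id")


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with size (dispersion) r and mean mu:
    p = r / (r + mu). mu = 0 yields exact zeros."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def generate(spec: SyntheticSpec) -> tuple[ad.AnnData, GroundTruth]:
    """Generate a dataset and its ground truth. Deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    clusters = spec.cluster_ids()
    glial = set(spec.glial_cluster_ids())
    n_cells = spec.n_cells_per_cluster * spec.n_clusters
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    cluster_of_cell = np.repeat(clusters, spec.n_cells_per_cluster)

    genes = _gene_table(spec)
    gene_index = {g: i for i, g in enumerate(genes.index)}
    n_genes = len(genes)

    planted_codes = (
        {k: np.asarray(v, dtype=np.int8) for k, v in spec.planted_codes.items()}
        if spec.planted_codes is not None
        else _default_codes(spec, rng)
    )
    nt_assignment = (
        {k: list(v) for k, v in spec.nt_assignment.items()}
        if spec.nt_assignment is not None
        else _default_nt_assignment(spec)
    )
    np_assignment = (
        {k: list(v) for k, v in spec.np_assignment.items()}
        if spec.np_assignment is not None
        else _default_np_assignment(spec, rng)
    )

    # ---- sample / sex structure -------------------------------------------
    samples = list(spec.sex_design)
    female_samples = [s for s in samples if spec.sex_design[s] == "female"]
    male_samples = [s for s in samples if spec.sex_design[s] == "male"]
    mixed_samples = [s for s in samples if spec.sex_design[s] == "mixed"]

    sample_of_cell = np.empty(n_cells, dtype=object)
    for ci, c in enumerate(clusters):
        sl = slice(ci * spec.n_cells_per_cluster, (ci + 1) * spec.n_cells_per_cluster)
        if c in spec.sex_bias_design:
            f = spec.sex_bias_design[c]
            pick_female = rng.random(spec.n_cells_per_cluster) < f
            fs = rng.choice(female_samples, size=spec.n_cells_per_cluster)
            ms = rng.choice(male_samples, size=spec.n_cells_per_cluster)
            sample_of_cell[sl] = np.where(pick_female, fs, ms)
        else:
            sample_of_cell[sl] = rng.choice(samples, size=spec.n_cells_per_cluster)

    sex_label = np.array([spec.sex_design[s] for s in sample_of_cell], dtype=object)
    true_sex = sex_label.copy()
    mixed_mask = sex_label == "mixed"
    true_sex[mixed_mask] = np.where(
        rng.random(int(mixed_mask.sum())) < 0.5, "female", "male"
    )

    # ---- mean matrix -------------------------------------------------------
    mean = np.zeros((n_cells, n_genes), dtype=np.float32)
    fold = 2.0**spec.marker_log2fc

    bg_cols = [gene_index[f"bg{i:04d}"] for i in range(spec.n_genes_background)]
    mean[:, bg_cols] = spec.base_mean

    marker_genes: dict[str, list[str]] = {}
    for c in clusters:
        names = [f"mk_{c}_{j}" for j in range(spec.markers_per_cluster)]
        marker_genes[c] = names
        cols = [gene_index[g] for g in names]
        mean[:, cols] = spec.base_mean
        in_c = cluster_of_cell == c
        mean[np.ix_(in_c, cols)] = spec.base_mean * fold

    tf_code_frames: dict[str, pd.DataFrame] = {}
    for cls, code in planted_codes.items():
        tf_names = [f"tf_{cls}_{j:02d}" for j in range(spec.tf_class_sizes[cls])]
        tf_code_frames[cls] = pd.DataFrame(code, index=clusters, columns=tf_names)
        cols = [gene_index[g] for g in tf_names]
        mean[:, cols] = spec.tf_off_mean
        for ci, c in enumerate(clusters):
            on = code[ci].astype(bool)
            if on.any():
                on_cols = [cols[j] for j in np.flatnonzero(on)]
                mean[np.ix_(cluster_of_cell == c, on_cols)] = spec.tf_on_mean

    for g in NT_GENES:
        mean[:, gene_index[g]] = spec.nt_off_mean
    for c, gs in nt_assignment.items():
        in_c = cluster_of_cell == c
        for g in gs:
            mean[in_c, gene_index[g]] = spec.nt_on_mean

    for i in range(N_NEUROPEPTIDES):
        mean[:, gene_index[f"np{i:02d}"]] = spec.np_off_mean
    for g, cs in np_assignment.items():
        for c in cs:
            mean[cluster_of_cell == c, gene_index[g]] = spec.np_on_mean

    mean[:, gene_index[GLIAL_MARKER]] = 0.0
    for c in glial:
        mean[cluster_of_cell == c, gene_index[GLIAL_MARKER]] = spec.glial_marker_mean

    for sex in ("female", "male"):
        for g, log2fc in spec.sex_genes.get(sex, []):
            col = gene_index[g]
            mean[:, col] = spec.base_mean
            mean[true_sex == sex, col] = spec.base_mean * 2.0**log2fc

    # log-normal library-size variation
    libsize = np.exp(rng.normal(0.0, spec.libsize_sigma, size=n_cells)).astype(
        np.float32
    )
    mean *= libsize[:, None]

    counts = _nb_draw(rng, mean, spec.nb_dispersion).astype(np.int64)

    # ---- transgenes: expressed in T2 cells only, with detection dropout ----
    is_t2 = rng.random(n_cells) < spec.t2_fraction
    tg_cols = [gene_index[g] for g in TRANSGENES]
    tg_pre = _nb_draw(
        rng,
        np.full((n_cells, len(TRANSGENES)), spec.transgene_mean) * libsize[:, None],
        spec.nb_dispersion,
    )
    tg_pre[~is_t2] = 0
    # every true T2 cell expresses >= 1 transgene before dropout
    silent = is_t2 & (tg_pre.sum(axis=1) == 0)
    tg_pre[silent, 1] = 1
    # dropout uniforms drawn for every (cell, transgene) so that datasets
    # generated at different detection rates from one seed are coupled
    # monotonically
    u = rng.random((n_cells, len(TRANSGENES)))
    detected = u < spec.transgene_detection_rate
    counts[:, tg_cols] = np.where(detected, tg_pre, 0)

    # ---- mitochondrial reads ----------------------------------------------
    # binomial so the realised per-cell fraction tracks the drawn target
    lo, hi = spec.mito_fraction_range
    target_frac = rng.uniform(lo, hi, size=n_cells)
    non_mito_total = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(target_frac < 1.0, target_frac / (1.0 - target_frac), 1.0)
    mito_total = rng.binomial(non_mito_total, np.clip(odds, 0.0, 1.0))
    mito_cols = [gene_index[g] for g in MITO_GENES]
    counts[:, mito_cols] = rng.multinomial(
        mito_total, np.full(len(MITO_GENES), 1.0 / len(MITO_GENES))
    )

    # ---- assemble ----------------------------------------------------------
    obs = pd.DataFrame(
        {
            "sample": sample_of_cell,
            "sex": sex_label,
            "cluster": cluster_of_cell,
            "lineage": "unassigned",
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=genes.copy())

    nt_labels = {}
    for cid, c in zip(cell_ids, cluster_of_cell):
        gs = nt_assignment.get(c, [])
        nt_labels[cid] = frozenset(NT_CLASS_OF_GENE[g] for g in gs)

    truth = GroundTruth(
        cell_lineage=pd.Series(
            np.where(is_t2, "T2", "T1"), index=cell_ids, name="lineage"
        ),
        cluster_of_cell=pd.Series(cluster_of_cell, index=cell_ids, name="cluster"),
        marker_genes=marker_genes,
        tf_code=tf_code_frames,
        nt_labels=nt_labels,
        np_clusters={g: set(cs) for g, cs in np_assignment.items()},
        sex_of_cell=pd.Series(true_sex, index=cell_ids, name="sex"),
        sex_biased_clusters=set(spec.sex_bias_design),
        glial_clusters=set(glial),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# on-disk round trip


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_dataset(
    adata: ad.AnnData,
    truth: GroundTruth | None,
    directory: str | Path,
    overwrite: bool = False,
) -> dict:
    """Write matrix.mtx + genes.tsv + cells.tsv (+ truth tables) and a
    manifest with SHA-256 checksums. Refuses a non-empty directory unless
    ``overwrite`` is set."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{directory} is not empty; pass overwrite=True to replace it"
            )
        shutil.rmtree(directory)
    directory.mkdir(parents=True, exist_ok=True)

    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(directory / "matrix.mtx", X.tocoo(), field="integer")

    genes = adata.var.reset_index()
    genes.columns = ["gene_id"] + list(adata.var.columns)
    genes.to_csv(directory / "genes.tsv", sep="\t", index=False)

    cells = adata.obs.reset_index()
    cells = cells.rename(columns={cells.columns[0]: "cell_id"})
    cells.to_csv(directory / "cells.tsv", sep="\t", index=False)

    files = ["matrix.mtx", "genes.tsv", "cells.tsv"]

    if truth is not None:
        tdir = directory / "truth"
        tdir.mkdir()
        per_cell = pd.DataFrame(
            {
                "cell_id": truth.cluster_of_cell.index,
                "lineage": truth.cell_lineage.values,
                "cluster": truth.cluster_of_cell.values,
                "sex": truth.sex_of_cell.values,
            }
        )
        per_cell.to_csv(tdir / "cells.tsv", sep="\t", index=False)
        files.append("truth/cells.tsv")

        mk = pd.DataFrame(
            [(c, g) for c, gs in sorted(truth.marker_genes.items()) for g in gs],
            columns=["cluster", "gene"],
        )
        mk.to_csv(tdir / "marker_genes.tsv", sep="\t", index=False)
        files.append("truth/marker_genes.tsv")

        for cls, frame in sorted(truth.tf_code.items()):
            name = f"tf_code_{cls}.tsv"
            frame.to_csv(tdir / name, sep="\t", index_label="cluster")
            files.append(f"truth/{name}")

        npc = pd.DataFrame(
            [(g, c) for g, cs in sorted(truth.np_clusters.items()) for c in sorted(cs)],
            columns=["neuropeptide", "cluster"],
        )
        npc.to_csv(tdir / "np_clusters.tsv", sep="\t", index=False)
        files.append("truth/np_clusters.tsv")

        extra = pd.DataFrame(
            {
                "kind": ["sex_biased"] * len(truth.sex_biased_clusters)
                + ["glial"] * len(truth.glial_clusters),
                "cluster": sorted(truth.sex_biased_clusters)
                + sorted(truth.glial_clusters),
            }
        )
        extra.to_csv(tdir / "cluster_flags.tsv", sep="\t", index=False)
        files.append("truth/cluster_flags.tsv")

    manifest = {
        "n_cells": int(adata.n_obs),
        "n_genes": int(adata.n_vars),
        "files": {f: _sha256(directory / f) for f in files},
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
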