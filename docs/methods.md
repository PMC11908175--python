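# Methods

This note records the statistical conventions, the synthetic-data model,
and the design choices made where the underlying procedures are commonly
described only loosely.

## Container and normalisation

Data live in an `AnnData`: raw counts in `X` (sparse integers), cell
metadata in `obs` (`sample`, `sex` ∈ {female, male, mixed}, `cluster`,
`lineage`), gene annotations in `var` (`gene_class`, `tf_class`).
`io_qc.normalize` adds `lognorm[i,j] = log(1 + s·c[i,j]/depth_i)` with
scale `s = 10⁴`, and `scaled`, the per-gene z-score of `lognorm` across
cells using the population SD; zero-variance genes map to 0 rather than
NaN, and zero-depth cells get all-zero rows with a warning. "Scaled
average expression" used by profiles and enhancer scoring is the z-score
*across clusters* of the per-cluster mean of `lognorm` — a different
standardisation from the per-cell `scaled` layer, kept distinct on
purpose.

## QC

Cells are retained when 200 ≤ genes detected ≤ 2500 and the mitochondrial
read fraction is ≤ 0.05 (all bounds configurable). The phrases "fewer
than 200", "more than 2500" and "more than 5%" are read literally, so the
bounds themselves are kept. A cell failing several criteria is tallied
once under the first failing criterion (low genes, high genes, mito) so
the report partitions the input exactly. Filtering is idempotent.

## Lineage assignment

A cell is T2-derived iff any lineage-tracing transgene (FLP, GFP, RFP)
has ≥ 1 raw count (threshold configurable); everything else is T1, making
the partition exhaustive by construction. No expression-level evidence
beyond transgene detection is used, so detection dropout biases counts
toward T1 — the same direction the experimental design implies.

## Marker detection

One-vs-rest two-sided Wilcoxon rank-sum on `lognorm`, computed from
per-gene ranks with the tie-corrected normal approximation and a 0.5
continuity correction (verified against `scipy.stats.mannwhitneyu
(method="asymptotic")` on small instances, and against scanpy's Wilcoxon
ranking as an independent route). Genes are prefiltered before testing:
detection fraction ≥ `min_pct` (0.1) in at least one group, and Seurat-
convention fold-change `log2((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1))`
at least `min_log2fc` (0.25, absolute when negative markers are
requested). BH adjustment runs per cluster over the genes actually
tested, matching common FindAllMarkers-style reporting. Clusters with
fewer than 3 cells are skipped with a warning. Top-marker extraction
sorts by fold-change, then adjusted p, then gene ID, so ties are
deterministic.

## Neurotransmitter and neuropeptide analysis

Per-cell transmitter positivity thresholds one expression layer for the
seven pathway genes. The default is the z-scaled layer at threshold 2;
the log-normalised layer is an explicit alternative because both
conventions circulate for this analysis, and the choice is surfaced in
the summary rather than silently resolved. The summary partitions cells
into exactly-one-class (reported per class), multi-class (≥ 2) and
negative; percentages are exact before any display rounding, and UpSet
counts are exact per combination. On near-binary on/off expression the
z-score of positive cells is roughly √((1−p)/p) for positive fraction p,
so a threshold of 2 implies a gene must be expressed in ≲ 20% of cells to
be callable — a real constraint of this classification style, reproduced
faithfully here.

A neuropeptide is "cluster-defining" when it is a significant positive
marker in at least 1 and at most `max_clusters` (default 4) clusters; the
underlying criterion is not standardised anywhere, so the bound is
configurable and recorded. TF–neuropeptide association is plain Pearson
(or Spearman) correlation across all cells on `lognorm`, zero-variance
genes scoring 0; single-cell correlations on sparse data are descriptive,
not inferential.

## TF combinatorial codes

Entry (c, t) of a class's binary matrix is 1 iff TF t is an up-regulated
marker of cluster c at adjusted p < α; TFs that are markers nowhere are
dropped. A cluster is *unique* iff its row occurs exactly once — two
all-zero clusters are mutual duplicates, and in a duplicate group every
member counts as non-unique (the only reading consistent with reporting
"N unique clusters"). Percentages are rounded half-up to one decimal.
Jaccard similarity uses the marker sets, with J ≡ 0 when both sets are
empty so markerless clusters never anchor the ordering; the display order
is the average-linkage leaf order on distance 1 − J with labels
pre-sorted lexicographically for deterministic ties.

## Sex bias

Mixed-sex samples carry no per-cell sex, so their cells are excluded
(listed in the report). Sample inputs are equalised by weights: each
sexed sample contributes equal total weight, rescaled to the mean sample
size. Both the expected female fraction and the per-cluster observed
fractions are weighted, which makes the fractions and log2 odds ratios
exactly invariant to replicating all cells of one sex's samples; the
per-cluster two-sided binomial test uses the rounded weighted counts. A
cluster is called biased when BH-adjusted p < α *and* the |log2 odds
ratio| is at least 1 (both configurable) — the effect-size floor keeps
trivially significant but tiny imbalances out.

Pseudobulk DE sums raw counts per sample (per sample × cluster in
per-cluster scope), converts to log2(CPM+1), and applies a two-sided
rank-sum across units, with the exact null when a side has ≤ 12 units.
Rank tests on few replicates have a hard p-value floor of 2/C(n_f+n_m,
n_f); with fewer than ~7 units per sex no gene can clear a 5% FDR over
hundreds of genes, so with fewer than two units on a side the
implementation falls back to a per-cell rank-sum and records the
fallback in the output provenance.

## Cluster mapping

Bulk-profile mapping correlates each cluster's mean `lognorm` vector with
each cell type's log1p bulk vector over the shared gene set (error below
10 shared genes; an HVG-restricted option exists because the appropriate
gene set is an open choice) and assigns the arg-max cell type per
cluster, ties broken lexicographically and flagged. Enhancer-gene scoring
declares a cluster a candidate for a split-driver's cell type when every
enhancer-associated gene has scaled average expression > 0 — deliberately
permissive and many-to-many, like the visual criterion it formalises.
Marker logic evaluates per-cluster detection fractions: positive genes
need ≥ 50% of cells detecting, negative genes ≤ 10% (both configurable);
note that a gene expressed at ordinary background levels will not pass as
"negative" — negativity is meaningful only for genes that are truly off
outside their clusters.

## Synthetic data model

Counts are negative binomial with gene-and-cluster-specific means and
shared size (dispersion) 2, multiplied by per-cell log-normal library
factors (σ = 0.3) — the standard overdispersed model for UMI counts.
Defaults describe a small but structurally complete experiment: 12
clusters (2 glial) × 100 cells, 200 background genes at mean 0.5, five
markers per cluster planted at log2FC 3, 42 TFs across the six
DNA-binding-domain classes with distinct random codes at density 0.35
(sparse on purpose: a TF expressed in nearly every cluster is not a
positive one-vs-rest marker of any of them, so only cluster-restricted
TFs can carry a recoverable code), the seven NT genes planted roughly one
per cluster plus one co-expressing cluster, 49 neuropeptides of which 13
are restricted to 1–3 clusters (including two NPs sharing one cluster
pair, the many-to-many motif), yolk-protein/roX sex genes at 8-fold in
the corresponding sex, and a 50%-T2 population whose transgene reads
survive an independent per-cell-per-transgene Bernoulli detection of 0.9.
Mitochondrial totals are drawn binomially against a per-cell target
fraction from `mito_fraction_range` so the realised fraction tracks the
draw. All randomness flows from one `numpy` Generator seeded by `seed`;
the dropout uniforms are drawn for every cell regardless of the detection
rate, so datasets generated at different rates from one seed are coupled
monotonically.

What the generator does *not* emulate: ambient RNA, doublets, batch
effects beyond sample labels, gene–gene correlation beyond the planted
programmes, and realistic transcriptome-scale gene counts. Passing
recovery tests therefore demonstrate the correctness and calibration of
the analysis logic under the stated model, not performance on real
tissue.

## Problem sizes and determinism

Tests and the acceptance script run on the default 1,200-cell generator
outputs (a few seconds per stage on one CPU), with the bookkeeping and
worked-example checks on constructed tables at their published sizes
(30,699 nuclei; 161 clusters). Property tests are seeded/derandomised.
Known limitations: the binomial sex-composition test treats cells as
independent within clusters (no overdispersion across animals); marker
p-values are asymptotic and anti-conservative for very small clusters;
and enhancer/marker-logic thresholds formalise visual criteria whose
original operating points are unknown.
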