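"""Neurotransmitter classification, UpSet counting, neuropeptide restriction
and TF-NP correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from t2atlas import io_qc, nt_np
from t2atlas._constants import NT_CLASS_OF_GENE, NT_GENES
from tests.conftest import make_tiny_anndata


class TestClassifyNeurotransmitters:
    def test_all_zero_expression_is_all_negative(self):
        counts = np.zeros((5, len(NT_GENES)), dtype=int)
        counts[:, 0] = 0
        adata = make_tiny_anndata(counts, gene_ids=list(NT_GENES))
        with pytest.warns(UserWarning):
            adata = io_qc.normalize(adata)
        _, summary = nt_np.classify_neurotransmitters(adata)
        assert summary.pct_negative == 100.0
        assert summary.pct_multi == 0.0

    def test_recovers_planted_programmes(self, normalized):
        """Per-cell calls match the planted single- and multi-NT programmes."""
        adata, truth = normalized
        profiles, _ = nt_np.classify_neurotransmitters(adata)
        called = {
            cell: frozenset(
                NT_CLASS_OF_GENE[g] for g in profiles.columns[row]
            )
            for cell, row in zip(profiles.index, profiles.to_numpy())
        }
        agree = np.mean([
            called[c] == truth.nt_labels[c] for c in profiles.index
        ])
        assert agree >= 0.8

    def test_partition_sums_to_100_before_rounding(self, normalized):
        adata, _ = normalized
        _, summary = nt_np.classify_neurotransmitters(adata)
        total = (
            sum(summary.per_class_pct.values())
            + summary.pct_multi
            + summary.pct_negative
        )
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_monotone_in_threshold(self, normalized):
        adata, _ = normalized
        prev = None
        for thr in (0.5, 1.0, 2.0, 3.0):
            profiles, _ = nt_np.classify_neurotransmitters(adata, threshold=thr)
            counts = profiles.sum(axis=0)
            if prev is not None:
                assert (counts <= prev).all()
            prev = counts

    def test_missing_gene_is_an_error(self, normalized):
        adata, _ = normalized
        with pytest.raises(KeyError, match="NOPE"):
            nt_np.classify_neurotransmitters(adata, nt_genes=("NOPE",))

    def test_lognorm_layer_switch(self, normalized):
        adata, _ = normalized
        _, s = nt_np.classify_neurotransmitters(adata, layer="lognorm",
                                                threshold=2.0)
        assert s.layer == "lognorm"


class TestUpsetCounts:
    def test_single_cell_single_class(self):
        profiles = pd.DataFrame([[False, True]], columns=["VGlut", "VAChT"])
        assert nt_np.upset_counts(profiles) == {("VAChT",): 1}

    def test_counts_conserve_cells(self, rng):
        profiles = pd.DataFrame(
            rng.random((500, 7)) < 0.3, columns=list(NT_GENES)
        )
        counts = nt_np.upset_counts(profiles)
        assert sum(counts.values()) == 500

    def test_planted_combinations_exact(self):
        rows = [
            *([{"VGlut"}] * 3),
            *([{"VGlut", "Gad1"}] * 2),
            *([set()] * 4),
        ]
        profiles = pd.DataFrame(
            [[g in r for g in NT_GENES] for r in rows], columns=list(NT_GENES)
        )
        counts = nt_np.upset_counts(profiles)
        assert counts[("VGlut",)] == 3
        assert counts[("VGlut", "Gad1")] == 2
        assert counts[()] == 4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            nt_np.upset_counts(pd.DataFrame(columns=list(NT_GENES)))


class TestClusterDefiningNeuropeptides:
    def test_planted_restriction_recovered(self, normalized, marker_table):
        adata, truth = normalized
        result = nt_np.cluster_defining_neuropeptides(
            adata, marker_table=marker_table
        )
        for gene, clusters in truth.np_clusters.items():
            if len(clusters) <= 4:
                assert result.get(gene) == clusters

    def test_uniform_neuropeptide_not_defining(self, normalized, marker_table):
        """NPs planted everywhere (constant background) never qualify."""
        adata, truth = normalized
        result = nt_np.cluster_defining_neuropeptides(
            adata, marker_table=marker_table
        )
        unrestricted = (
            set(adata.var_names[adata.var["gene_class"] == "neuropeptide"])
            - set(truth.np_clusters)
        )
        assert not (set(result) & unrestricted)

    def test_many_to_many_structure_representable(self, normalized,
                                                  marker_table):
        """Two NPs may share one cluster pair (NPF/AstA-style motif)."""
        adata, truth = normalized
        result = nt_np.cluster_defining_neuropeptides(
            adata, marker_table=marker_table
        )
        assert result["np00"] == result["np01"]
        assert len(result["np00"]) == 2

    def test_absent_gene_warns_and_skips(self, normalized, marker_table):
        adata, _ = normalized
        with pytest.warns(UserWarning, match="ghostNP"):
            nt_np.cluster_defining_neuropeptides(
                adata, np_genes=["ghostNP", "np00"], marker_table=marker_table
            )


class TestTfNpCorrelation:
    def _adata(self, rng, n=50):
        counts = rng.integers(0, 15, (n, 6))
        counts[:, 5] = counts[:, 0]  # np copy of a tf column
        counts[:, 4] = 0  # constant after depth normalisation
        gene_ids = ["tfA", "tfB", "tfC", "npX", "tfD", "npY"]
        adata = make_tiny_anndata(
            counts,
            gene_ids=gene_ids,
            gene_class=["tf", "tf", "tf", "neuropeptide", "tf", "neuropeptide"],
        )
        return io_qc.normalize(adata)

    def test_identical_columns_correlate_perfectly(self, rng):
        adata = self._adata(rng)
        corr = nt_np.tf_np_correlation(adata)
        assert corr.matrix.loc["tfA", "npY"] == pytest.approx(1.0)

    def test_constant_gene_yields_zero(self, rng):
        adata = self._adata(rng)
        corr = nt_np.tf_np_correlation(adata)
        assert corr.matrix.loc["tfD", "npX"] == 0.0
        assert corr.matrix.loc["tfD", "npY"] == 0.0

    @pytest.mark.parametrize("method,oracle", [
        ("pearson", pearsonr), ("spearman", spearmanr),
    ])
    def test_matches_scipy_oracle(self, rng, method, oracle):
        adata = self._adata(rng)
        corr = nt_np.tf_np_correlation(adata, method=method)
        L = adata.layers["lognorm"].toarray()
        names = list(adata.var_names)
        for tf in ("tfA", "tfB", "tfC"):
            for npg in ("npX", "npY"):
                expected = oracle(L[:, names.index(tf)],
                                  L[:, names.index(npg)])[0]
                assert corr.matrix.loc[tf, npg] == pytest.approx(
                    expected, abs=1e-12
                )

    def test_invariant_to_cell_order(self, rng):
        adata = self._adata(rng)
        perm = rng.permutation(adata.n_obs)
        corr1 = nt_np.tf_np_correlation(adata)
        corr2 = nt_np.tf_np_correlation(adata[perm].copy())
        np.testing.assert_allclose(
            corr1.matrix.to_numpy(), corr2.matrix.to_numpy(), atol=1e-12
        )

    def test_top_k_sorted_descending(self, normalized):
        adata, _ = normalized
        corr = nt_np.tf_np_correlation(adata, top_k=5)
        for npg, tfs in corr.top.items():
            values = [v for _, v in tfs]
            assert values == sorted(values, reverse=True)
            assert len(tfs) == 5
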