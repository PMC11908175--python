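"""Cluster-to-cell-type mapping: bulk correlation, enhancer genes, marker
logic."""

import numpy as np
import pandas as pd
import pytest

from t2atlas import cluster_mapping, markers, synthetic
from tests.conftest import make_tiny_anndata


@pytest.fixture(scope="module")
def profile(normalized):
    adata, _ = normalized
    return markers.cluster_profile(adata)


class TestBulkCorrelationMap:
    def test_exact_copy_attains_r_one_and_is_assigned(self, profile):
        target = "c03"
        bulk = pd.DataFrame(
            {"typeA": np.expm1(profile.mean_lognorm.loc[target])},
            index=profile.mean_lognorm.columns,
        )
        bulk["typeB"] = bulk["typeA"].iloc[::-1].to_numpy()
        records, coeff = cluster_mapping.bulk_correlation_map(profile, bulk)
        assert coeff.loc[target, "typeA"] == pytest.approx(1.0, abs=1e-9)
        assigned = records[(records["cluster"] == target) & records["assigned"]]
        assert assigned["cell_type"].tolist() == ["typeA"]

    def test_constant_bulk_profile_scores_zero(self, profile):
        bulk = pd.DataFrame(
            {
                "flat": np.ones(profile.mean_lognorm.shape[1]),
                "informative": np.expm1(profile.mean_lognorm.iloc[0]),
            },
            index=profile.mean_lognorm.columns,
        )
        _, coeff = cluster_mapping.bulk_correlation_map(profile, bulk)
        assert (coeff["flat"] == 0.0).all()

    def test_noisy_bulk_recovers_most_clusters(self, normalized):
        """Bulk profiles built as noisy cluster means map back >= 90%."""
        adata, _ = normalized
        prof = markers.cluster_profile(adata)
        rng = np.random.default_rng(7)
        means = np.expm1(prof.mean_lognorm)
        noisy = means * rng.lognormal(0.0, 0.3, size=means.shape)
        bulk = pd.DataFrame(
            noisy.to_numpy().T,
            index=prof.mean_lognorm.columns,
            columns=[f"type_{c}" for c in prof.mean_lognorm.index],
        )
        records, _ = cluster_mapping.bulk_correlation_map(prof, bulk)
        assigned = records[records["assigned"]]
        hits = (assigned["cell_type"] == "type_" + assigned["cluster"]).mean()
        assert hits >= 0.9

    def test_one_assignment_per_cluster(self, profile, rng):
        bulk = pd.DataFrame(
            rng.random((profile.mean_lognorm.shape[1], 4)),
            index=profile.mean_lognorm.columns,
            columns=list("wxyz"),
        )
        records, _ = cluster_mapping.bulk_correlation_map(profile, bulk)
        per_cluster = records[records["assigned"]].groupby("cluster").size()
        assert (per_cluster == 1).all()
        assert set(per_cluster.index) == set(profile.mean_lognorm.index.astype(str))

    def test_spearman_invariant_to_monotone_bulk_rescaling(self, profile, rng):
        genes = profile.mean_lognorm.columns
        bulk = pd.DataFrame(rng.random((len(genes), 3)) * 50,
                            index=genes, columns=list("abc"))
        _, c1 = cluster_mapping.bulk_correlation_map(
            profile, bulk, method="spearman", log_bulk=False
        )
        _, c2 = cluster_mapping.bulk_correlation_map(
            profile, bulk**3, method="spearman", log_bulk=False
        )
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-12)

    def test_pearson_invariant_to_affine_bulk_rescaling(self, profile, rng):
        genes = profile.mean_lognorm.columns
        bulk = pd.DataFrame(rng.random((len(genes), 3)) * 50,
                            index=genes, columns=list("abc"))
        _, c1 = cluster_mapping.bulk_correlation_map(
            profile, bulk, method="pearson", log_bulk=False
        )
        _, c2 = cluster_mapping.bulk_correlation_map(
            profile, 2.5 * bulk + 7.0, method="pearson", log_bulk=False
        )
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-10)

    def test_too_few_shared_genes_is_an_error(self, profile):
        bulk = pd.DataFrame({"a": [1.0, 2.0]},
                            index=["bg0000", "bg0001"])
        with pytest.raises(ValueError, match="2 genes shared"):
            cluster_mapping.bulk_correlation_map(profile, bulk)


class TestEnhancerGeneAssignment:
    def _drivers(self, genes):
        return {"SSx": ("FB2A", list(genes))}

    def test_all_positive_genes_qualify(self, profile):
        # pick a cluster's own planted markers: positive scaled average
        sub = profile.scaled_avg.loc["c04", ["mk_c04_0", "mk_c04_1"]]
        assert (sub > 0).all()
        rec = cluster_mapping.enhancer_gene_assignment(
            profile, self._drivers(["mk_c04_0", "mk_c04_1"])
        )
        hits = rec[rec["assigned"]]
        assert hits["cluster"].tolist() == ["c04"]
        assert (hits["cell_type"] == "FB2A").all()

    def test_one_negative_gene_disqualifies(self, profile):
        rec = cluster_mapping.enhancer_gene_assignment(
            profile, self._drivers(["mk_c04_0", "mk_c05_0"])
        )
        hits = rec[rec["assigned"]]
        assert "c04" not in set(hits["cluster"])
        scores = rec.set_index("cluster")["score"]
        assert scores["c04"] == 1  # one of two conditions met

    def test_empty_gene_list_is_an_error(self, profile):
        with pytest.raises(ValueError, match="empty"):
            cluster_mapping.enhancer_gene_assignment(
                profile, {"SSx": ("FB2A", [])}
            )

    def test_missing_gene_is_an_error(self, profile):
        with pytest.raises(KeyError, match="ghost"):
            cluster_mapping.enhancer_gene_assignment(
                profile, self._drivers(["ghost"])
            )


class TestMarkerLogicAssignment:
    def test_exclusive_marker_recovers_its_cluster(self, normalized):
        adata, _ = normalized
        # VGlut is planted on in other clusters and off (near-zero) in c06,
        # so it works as a negative condition; mk_c06_0 is elevated only
        # in c06 (baseline elsewhere stays under the 50% positive rule)
        pred = cluster_mapping.MarkerPredicate(
            conditions=[("mk_c06_0", "positive"), ("VGlut", "negative")]
        )
        assert cluster_mapping.marker_logic_assignment(adata, pred) == {"c06"}

    def test_contradictory_predicate_is_unsatisfiable(self, normalized):
        adata, _ = normalized
        with pytest.raises(ValueError, match="twice"):
            cluster_mapping.MarkerPredicate(
                conditions=[("mk_c06_0", "positive"), ("mk_c06_0", "negative")]
            )
        # distinct genes with impossible joint requirement -> empty set
        pred = cluster_mapping.MarkerPredicate(
            conditions=[("mk_c06_0", "positive"), ("mk_c06_1", "negative")]
        )
        assert cluster_mapping.marker_logic_assignment(adata, pred) == set()

    def test_dropping_a_condition_relaxes_to_a_superset(self, normalized):
        adata, _ = normalized
        full = cluster_mapping.MarkerPredicate(
            conditions=[("mk_c06_0", "positive"), ("VGlut", "negative")]
        )
        relaxed = cluster_mapping.MarkerPredicate(
            conditions=[("mk_c06_0", "positive")]
        )
        a = cluster_mapping.marker_logic_assignment(adata, full)
        b = cluster_mapping.marker_logic_assignment(adata, relaxed)
        assert a <= b

    def test_parse_syntax(self):
        pred = cluster_mapping.MarkerPredicate.parse("toy:+,runt:-")
        assert pred.conditions == [("toy", "positive"), ("runt", "negative")]
        with pytest.raises(ValueError):
            cluster_mapping.MarkerPredicate.parse("toy")
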