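import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from perduraflow.core import AnalysisConfig, CountMatrix, ValidationError
from perduraflow.markers import (
    cluster_summary,
    module_score,
    overlap_fraction,
    refine_marker_cluster,
    stage_contrast,
    upregulated_genes,
)


def _cm(counts, ids=None, cells=None):
    counts = np.asarray(counts)
    ids = ids or [f"g{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{i}" for i in range(counts.shape[1])]
    return CountMatrix(sp.csr_matrix(counts), ids, cells, "nuclear")


def _cell_table(cm, clusters):
    return pd.DataFrame({"cell_id": cm.cell_ids, "cluster_label": clusters})


class TestClusterSummary:
    def test_fraction_detected_zero_for_silent_cluster(self):
        cm = _cm([[0, 0, 3, 1], [1, 2, 0, 0]])
        table = _cell_table(cm, ["a", "a", "b", "b"])
        gene_stats, cluster_stats = cluster_summary(cm, table)
        assert gene_stats[("fraction_detected", "a")].loc["g0"] == 0.0
        assert gene_stats[("fraction_detected", "b")].loc["g0"] == 1.0

    def test_scaled_means_centered_across_two_clusters(self):
        # equal column totals keep depth normalization neutral
        cm = _cm([[1, 1, 3, 3], [3, 3, 1, 1]])
        table = _cell_table(cm, ["a", "a", "b", "b"])
        gene_stats, _ = cluster_summary(cm, table)
        scaled = gene_stats["scaled_mean"].loc["g0"]
        np.testing.assert_allclose(sorted(scaled), [-1.0, 1.0])

    def test_per_cluster_umi_and_gene_counts(self):
        cm = _cm([[4, 0], [4, 8]])
        table = _cell_table(cm, ["a", "b"])
        _, cluster_stats = cluster_summary(cm, table)
        row = cluster_stats.set_index("cluster_label")
        assert row.loc["a", "mean_total_umi"] == 8
        assert row.loc["a", "mean_n_genes_detected"] == 2
        assert row.loc["b", "mean_n_genes_detected"] == 1

    def test_invariant_to_cell_permutation(self, rng):
        counts = rng.poisson(2.0, size=(15, 40))
        clusters = rng.choice(["a", "b", "c"], size=40)
        cm = _cm(counts)
        g1, _ = cluster_summary(cm, _cell_table(cm, clusters))
        perm = rng.permutation(40)
        cm2 = _cm(counts[:, perm], cells=[f"c{i}" for i in perm])
        g2, _ = cluster_summary(cm2, _cell_table(cm2, clusters[perm]))
        np.testing.assert_allclose(
            g1["mean"].to_numpy(), g2["mean"][g1["mean"].columns].to_numpy()
        )


class TestModuleScore:
    @pytest.fixture(scope="class")
    def background(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(np.exp(rng.normal(1.0, 1.0, size=(400, 1))), size=(400, 1000))
        return _cm(counts)

    def test_null_target_set_scores_near_zero(self, background):
        rng = np.random.default_rng(5)
        targets = [f"g{i}" for i in rng.choice(400, size=30, replace=False)]
        result = module_score(background, targets, seed=3)
        assert abs(result.scores.mean()) < 0.05

    def test_deterministic_under_seed(self, background):
        targets = [f"g{i}" for i in range(0, 60, 2)]
        a = module_score(background, targets, seed=9)
        b = module_score(background, targets, seed=9)
        c = module_score(background, targets, seed=10)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert a.control_genes == b.control_genes
        assert not np.array_equal(a.scores, c.scores)

    def test_upshifted_subpopulation_detected(self, rng):
        counts = rng.poisson(3.0, size=(300, 1000)).astype(float)
        targets = [f"g{i}" for i in range(20)]
        counts[:20, 500:] *= 4  # targets doubled-plus in second half
        cm = _cm(counts.astype(int))
        result = module_score(cm, targets, seed=1)
        p = mannwhitneyu(result.scores[500:], result.scores[:500],
                         alternative="greater").pvalue
        assert p < 1e-6

    def test_controls_drawn_from_matching_bins_exclude_targets(self, background):
        targets = [f"g{i}" for i in range(25)]
        result = module_score(background, targets, n_ctrl=50, seed=2)
        assert set(result.control_genes).isdisjoint(targets)
        assert len(result.control_genes) == 25 * 50

    def test_empty_target_set_rejected(self, background):
        with pytest.raises(ValidationError):
            module_score(background, ["absent_gene"])

    def test_x_module_declines_after_silencing_on_simulation(self, small_sim):
        _, datasets, truth = small_sim
        cm = datasets["nuclear"][0]
        genes = truth.genes.set_index("gene_id")
        x_set = genes.index[genes["chromosome"] == "X"].tolist()
        result = module_score(cm, x_set, n_bins=20, seed=1)
        lat = truth.cells["nuclear"]["latent_time"].to_numpy()
        off = genes.loc[x_set, "transcription_off_time"].max()
        during = result.scores[(lat > 0.25) & (lat < off)].mean()
        after = result.scores[lat > off + 0.2].mean()
        assert after < during


class TestUpregulatedGenes:
    def test_flat_gene_excluded_and_enriched_gene_included(self):
        # equal column totals; background is the FULL dataset (cluster included)
        counts = np.array(
            [[2, 2, 2, 2, 2, 2],
             [1, 1, 1, 1, 20, 20],
             [22, 22, 22, 22, 3, 3]]
        )
        cm = _cm(counts)
        table = _cell_table(cm, ["bg"] * 4 + ["hub"] * 2)
        out = upregulated_genes(cm, table, "hub", log2fc_min=1.0)
        assert out["gene_id"].tolist() == ["g1"]

    def test_log2fc_matches_hand_arithmetic(self):
        counts = np.array([[1, 1, 4, 4], [4, 4, 1, 1]])
        cm = _cm(counts)
        table = _cell_table(cm, ["bg", "bg", "cl", "cl"])
        out = upregulated_genes(cm, table, "cl", log2fc_min=0.1)
        lo, hi = np.log1p(1.0), np.log1p(4.0)
        full_mean = (2 * lo + 2 * hi) / 4
        eps = 1e-9 * hi
        expected = np.log2((hi + eps) / (full_mean + eps))
        assert out["log2fc"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_small_cluster_flagged_low_confidence(self):
        counts = np.array([[1, 1, 9]])
        cm = _cm(counts)
        table = _cell_table(cm, ["bg", "bg", "solo"])
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = upregulated_genes(cm, table, "solo", log2fc_min=0.1)
        assert out["low_confidence"].all()


class TestOverlap:
    def test_identity_disjoint_and_bound(self):
        a = {"x", "y", "z"}
        same = overlap_fraction(a, a)
        assert same["jaccard"] == 1.0 and same["fraction_of_a"] == 1.0
        disjoint = overlap_fraction(a, {"q"})
        assert disjoint["n_intersection"] == 0 and disjoint["jaccard"] == 0.0
        partial = overlap_fraction(a, {"x", "q"})
        assert partial["n_intersection"] <= min(partial["n_a"], partial["n_b"])
        assert partial["fraction_of_b"] == 0.5


class TestRefineMarkerCluster:
    def test_rules_and_reasons(self):
        counts = np.array(
            # sig1 sig2 vas
            [[3, 2, 0, 5],   # sig1
             [1, 4, 0, 2],   # sig2
             [0, 0, 3, 0]],  # vas (germline contaminant marker)
        )
        cm = _cm(counts, ids=["sig1", "sig2", "vas"], cells=["a", "b", "c", "d"])
        kept, excluded = refine_marker_cluster(
            cm, ["a", "b", "c", "d"], ["sig1", "sig2"], ["vas"], min_pos=2
        )
        assert kept == ["a", "b", "d"]
        assert excluded["c"] == "negative marker vas"

    def test_insufficient_signature_reason(self):
        counts = np.array([[0, 3], [0, 3], [0, 0]])
        cm = _cm(counts, ids=["s1", "s2", "neg"], cells=["poor", "good"])
        kept, excluded = refine_marker_cluster(
            cm, ["poor", "good"], ["s1", "s2"], ["neg"], min_pos=2
        )
        assert kept == ["good"]
        assert excluded["poor"] == "insufficient positive signature"


class TestStageContrast:
    def test_identical_stages_give_zero_delta(self):
        counts = np.array([[3, 3, 3, 3], [1, 1, 1, 1]])
        cm = _cm(counts)
        table = _cell_table(cm, ["s2", "s2", "s3", "s3"])
        out = stage_contrast(cm, table, "s2", "s3")
        np.testing.assert_allclose(out["delta_log2"], 0.0, atol=1e-12)
        assert not out["upregulated"].any()

    def test_delta_matches_hand_arithmetic(self):
        counts = np.array([[0, 2, 7, 3]])
        cm = _cm(counts)
        table = _cell_table(cm, ["a", "a", "b", "b"])
        out = stage_contrast(cm, table, "a", "b", threshold=0.25)
        expected = np.mean([np.log2(8), np.log2(4)]) - np.mean([0, np.log2(3)])
        assert out["delta_log2"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert bool(out["upregulated"].iloc[0]) == (expected > 0.25)

    def test_missing_stage_rejected(self):
        cm = _cm([[1, 2]])
        table = _cell_table(cm, ["a", "a"])
        with pytest.raises(ValidationError):
            stage_contrast(cm, table, "a", "missing")
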