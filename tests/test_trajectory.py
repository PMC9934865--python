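import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

from perduraflow.core import AnalysisConfig, CountMatrix
from perduraflow.trajectory import (
    DegenerateStatisticError,
    bh_adjust,
    binary_weights,
    compute_pseudotime,
    morans_i,
    morans_i_analytic,
    morans_i_permutation,
    preprocess_embed,
    resolve_root,
    score_genes_moran,
)


def _random_graph(rng, n=12, p=0.4):
    A = (rng.uniform(size=(n, n)) < p).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    if A.sum() == 0:
        A[0, 1] = A[1, 0] = 1.0
    return sp.csr_matrix(A)


def _morans_i_double_loop(x, W):
    """Independent O(n^2) evaluation of the defining formula."""
    W = W.toarray()
    n = len(x)
    xb = x.mean()
    num = sum(
        W[i, j] * (x[i] - xb) * (x[j] - xb) for i in range(n) for j in range(n)
    )
    return (n / W.sum()) * num / sum((xi - xb) ** 2 for xi in x)


class TestMoransI:
    def test_two_node_antithetic_pair(self):
        W = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert morans_i(np.array([-1.0, 1.0]), W) == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        W = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(DegenerateStatisticError):
            morans_i(np.array([2.0, 2.0]), W)

    def test_matches_double_loop_formula(self, rng):
        for _ in range(20):
            W = _random_graph(rng)
            x = rng.normal(size=12)
            assert morans_i(x, W) == pytest.approx(
                _morans_i_double_loop(x, W), abs=1e-12
            )

    def test_permutation_null_mean_is_minus_one_over_n_minus_one(self, rng):
        W = _random_graph(rng, n=30)
        x = rng.normal(size=30)
        _, null, _ = morans_i_permutation(x, W, 1000, rng)
        se = null.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.mean() - (-1.0 / 29)) < 3 * se

    def test_analytic_z_detects_smooth_signal(self, rng):
        # chain graph with x increasing along the chain: strong autocorrelation
        n = 50
        A = sp.diags([np.ones(n - 1), np.ones(n - 1)], [1, -1], format="csr")
        I, z, p = morans_i_analytic(np.arange(n, dtype=float) + rng.normal(0, 0.1, n), A)
        assert I > 0.8 and p < 1e-10


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.5, 1.0])
        np.testing.assert_allclose(bh_adjust(p), [0.05, 0.05, 0.05, 0.625, 1.0])

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(200):
            p = rng.uniform(size=rng.integers(2, 40))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(p), q_ref, atol=1e-12)

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestPseudotime:
    def test_collinear_points_ordered_from_root(self):
        emb = np.array([[0.0, 0.0], [1.0, 0.0], [2.5, 0.0]])
        graph = compute_pseudotime(emb, k=2, root=0)
        pt = graph.pseudotime
        assert pt[0] == 0.0 and 0 < pt[1] < pt[2]

    def test_disconnected_blob_gets_undefined_pseudotime(self, rng):
        blob1 = rng.normal(0, 0.1, size=(20, 3))
        blob2 = rng.normal(100, 0.1, size=(10, 3))
        emb = np.vstack([blob1, blob2])
        graph = compute_pseudotime(emb, k=3, root=0)
        assert np.isfinite(graph.pseudotime[:20]).all()
        assert np.isnan(graph.pseudotime[20:]).all()
        assert graph.connected_fraction == pytest.approx(20 / 30)

    def test_invariant_to_cell_order_shuffle(self, rng):
        emb = rng.normal(size=(60, 4))
        perm = rng.permutation(60)
        g1 = compute_pseudotime(emb, k=5, root=7)
        g2 = compute_pseudotime(emb[perm], k=5, root=int(np.flatnonzero(perm == 7)[0]))
        np.testing.assert_allclose(g1.pseudotime[perm], g2.pseudotime, atol=1e-9)

    def test_root_resolution(self):
        emb = np.array([[0.0, 0], [1, 0], [5, 0], [6, 0]])
        clusters = np.array(["a", "a", "b", "b"])
        assert resolve_root("c2", ["c1", "c2", "c3", "c4"], clusters, emb) == 1
        assert resolve_root("b", ["c1", "c2", "c3", "c4"], clusters, emb) in (2, 3)
        with pytest.raises(Exception):
            resolve_root("missing", ["c1"], None, emb[:1])


class TestPreprocessEmbed:
    def test_proportional_cells_coincide_in_embedding(self, rng):
        base = rng.poisson(5.0, size=(40, 30)).astype(float)
        base[:, 1] = base[:, 0] * 3  # cell 1 is a scaled copy of cell 0
        cm = CountMatrix(
            sp.csr_matrix(base),
            [f"g{i}" for i in range(40)],
            [f"c{i}" for i in range(30)],
            "nuclear",
        )
        config = AnalysisConfig(n_dims=5, seed=0)
        emb = preprocess_embed(cm, config)
        assert np.linalg.norm(emb[0] - emb[1]) < 1e-8

    def test_constant_gene_excluded_from_variable_set(self, rng):
        counts = rng.poisson(3.0, size=(10, 50))
        counts[4, :] = 0  # constant zero gene
        cm = CountMatrix(
            sp.csr_matrix(counts),
            [f"g{i}" for i in range(10)],
            [f"c{i}" for i in range(50)],
            "nuclear",
        )
        _, info = preprocess_embed(cm, AnalysisConfig(n_dims=3), return_info=True)
        assert 4 not in info["hvg_indices"]

    def test_dims_reduced_with_warning_for_tiny_inputs(self, rng):
        counts = rng.poisson(5.0, size=(30, 8))
        cm = CountMatrix(
            sp.csr_matrix(counts),
            [f"g{i}" for i in range(30)],
            [f"c{i}" for i in range(8)],
            "nuclear",
        )
        with pytest.warns(UserWarning, match="reducing embedding dimensions"):
            emb = preprocess_embed(cm, AnalysisConfig(n_dims=50))
        assert emb.shape[1] < 50


class TestSelectionOnSimulation:
    def test_leading_pc_tracks_latent_time(self, small_sim):
        """A leading PC orders cells by latent time.

        For a one-dimensional trajectory PCA produces the classic arch: one
        leading component is symmetric about the trajectory midpoint and the
        other is monotone, so the monotone axis is among the first two.
        """
        _, datasets, truth = small_sim
        cm = datasets["nuclear"][0]
        emb = preprocess_embed(cm, AnalysisConfig(n_dims=10, seed=1))
        lat = truth.cells["nuclear"]["latent_time"].to_numpy()
        rho = max(
            abs(stats.spearmanr(emb[:, i], lat).statistic) for i in range(2)
        )
        assert rho >= 0.8

    def test_constant_gene_never_selected(self, rng):
        n = 80
        emb = np.linspace(0, 1, n)[:, None] + rng.normal(0, 0.01, size=(n, 1))
        graph = compute_pseudotime(np.hstack([emb, emb]), k=5, root=0)
        counts = rng.poisson(4.0, size=(3, n))
        counts[1] = 0  # undetected gene: constant after normalization
        cm = CountMatrix(
            sp.csr_matrix(counts), ["a", "b", "c"], [f"c{i}" for i in range(n)],
            "nuclear",
        )
        res = score_genes_moran(cm, graph, AnalysisConfig(seed=0))
        assert not res.table.loc[1, "selected"]
        assert np.isnan(res.table.loc[1, "moran_i"])
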