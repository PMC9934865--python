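"""Embedding, graph-based pseudotime, and Moran's I trajectory-gene selection.

Pseudotime here is the geodesic distance from a chosen root cell along the
minimum spanning tree of a symmetrized k-nearest-neighbor graph built in PCA
space — a deliberately simple stand-in for principal-graph methods that
preserves the statistic that matters downstream (a smooth ordering of cells).
Cells outside the root's connected component have undefined (NaN) pseudotime.

Trajectory-variable genes are flagged by Moran's I autocorrelation on the
cell neighbor graph with binary symmetric weights, with one-sided p-values
from the analytic randomization z-score (or label permutation) and
Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core import AnalysisConfig, CountMatrix, ValidationError, normalize_log1p


class DegenerateStatisticError(ValueError):
    """Raised when a statistic is undefined (e.g. constant input)."""


def preprocess_embed(
    counts: CountMatrix, config: AnalysisConfig, return_info: bool = False
):
    """Normalize, select variable genes, standardize and project to PCA space.

    Steps: per-cell depth normalization to the median total, ``log1p``,
    selection of the top ``n_hvg`` most variable genes, per-gene
    standardization (clipped at |z|=10), and PCA to ``n_dims`` components.
    If there are fewer cells than requested dimensions the dimensionality is
    reduced with a warning.
    """
    X = normalize_log1p(counts)  # genes x cells
    var = X.var(axis=1)
    order = np.argsort(-var, kind="stable")
    keep = order[: min(config.n_hvg, (var > 0).sum())]
    keep = keep[var[keep] > 0]
    if keep.size == 0:
        raise ValidationError("no variable genes after normalization")
    Xv = X[keep, :]
    mu = Xv.mean(axis=1, keepdims=True)
    sd = Xv.std(axis=1, keepdims=True)
    Z = np.clip((Xv - mu) / sd, -10, 10)
    n_dims = min(config.n_dims, counts.n_cells - 1, Z.shape[0])
    if n_dims < config.n_dims:
        warnings.warn(
            f"reducing embedding dimensions from {config.n_dims} to {n_dims} "
            f"(limited by input size)"
        )
    pca = PCA(n_components=n_dims, svd_solver="full" if min(Z.shape) < 500 else "randomized",
              random_state=config.seed)
    emb = pca.fit_transform(Z.T)  # cells x dims
    if return_info:
        return emb, {"hvg_indices": keep, "explained_variance_ratio": pca.explained_variance_ratio_}
    return emb


@dataclass
class TrajectoryGraph:
    """kNN graph + spanning forest with root-anchored pseudotime."""

    knn: sp.csr_matrix          # symmetric weighted adjacency (distances)
    mst: sp.csr_matrix          # symmetric spanning forest
    root: int
    pseudotime: np.ndarray      # NaN outside the root's component
    connected_fraction: float
    cell_ids: list[str] = field(default_factory=list)

    def scaled_pseudotime(self) -> np.ndarray:
        """Pseudotime divided by the component maximum, on [0, 1]."""
        pt = self.pseudotime
        finite = np.isfinite(pt)
        top = pt[finite].max() if finite.any() else 1.0
        return pt / top if top > 0 else pt


def _symmetric_knn(embedding: np.ndarray, k: int) -> sp.csr_matrix:
    nn = NearestNeighbors(n_neighbors=min(k, len(embedding) - 1)).fit(embedding)
    graph = nn.kneighbors_graph(mode="distance")
    graph = graph.maximum(graph.T)  # union of directed kNN, symmetric weights
    return sp.csr_matrix(graph)


def resolve_root(
    root, cell_ids: list[str], clusters: np.ndarray | None, embedding: np.ndarray
) -> int:
    """Resolve a root spec (cell id, index, or cluster label) to a cell index.

    A cluster label resolves to the cluster's medoid in embedding space.
    """
    if isinstance(root, (int, np.integer)):
        if not 0 <= root < len(cell_ids):
            raise ValidationError(f"root index {root} out of range")
        return int(root)
    root = str(root)
    if root in cell_ids:
        return cell_ids.index(root)
    if clusters is not None:
        members = np.flatnonzero(np.asarray(clusters).astype(str) == root)
        if members.size:
            sub = embedding[members]
            d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
            return int(members[np.argmin(d2.sum(axis=1))])
    raise ValidationError(f"root {root!r} is neither a cell id nor a cluster label")


def compute_pseudotime(
    embedding: np.ndarray, k: int, root: int, cell_ids: list[str] | None = None
) -> TrajectoryGraph:
    """Root-anchored pseudotime along the MST of the symmetric kNN graph."""
    if k < 2:
        raise ValidationError("knn_k must be >= 2")
    n = len(embedding)
    knn = _symmetric_knn(embedding, k)
    mst = csgraph.minimum_spanning_tree(knn)
    mst = mst.maximum(mst.T)
    dist = csgraph.dijkstra(mst, directed=False, indices=root)
    pseudotime = np.where(np.isfinite(dist), dist, np.nan)
    connected = np.isfinite(dist).sum() / n
    return TrajectoryGraph(
        knn=knn,
        mst=sp.csr_matrix(mst),
        root=int(root),
        pseudotime=pseudotime,
        connected_fraction=float(connected),
        cell_ids=list(cell_ids) if cell_ids is not None else [str(i) for i in range(n)],
    )


def binary_weights(graph: sp.csr_matrix) -> sp.csr_matrix:
    """Binary symmetric weights from a (distance-)weighted adjacency."""
    W = graph.copy()
    W.data = np.ones_like(W.data)
    return sp.csr_matrix(W.maximum(W.T))


def morans_i(x: np.ndarray, W: sp.csr_matrix) -> float:
    """Moran's I autocorrelation of ``x`` on the weighted graph ``W``.

    I = (N / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise DegenerateStatisticError("Moran's I undefined for constant input")
    s0 = W.sum()
    if s0 == 0:
        raise DegenerateStatisticError("graph has no edges")
    num = float(xc @ (W @ xc))
    return (n / s0) * num / denom


def morans_i_analytic(x: np.ndarray, W: sp.csr_matrix):
    """Moran's I with the randomization-assumption z-score and one-sided p.

    Expectation is E[I] = -1/(N-1); the variance uses the standard
    randomization (permutation-moment) formula involving S0, S1, S2 and the
    sample kurtosis.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    I = morans_i(x, W)
    s0 = float(W.sum())
    Wd = W + W.T
    s1 = 0.5 * float((Wd.multiply(Wd)).sum())
    row = np.asarray(W.sum(axis=1)).ravel() + np.asarray(W.sum(axis=0)).ravel()
    s2 = float((row**2).sum())
    xc = x - x.mean()
    m2 = (xc**2).mean()
    b2 = (xc**4).mean() / m2**2
    e_i = -1.0 / (n - 1)
    num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
        (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0 * s0
    var = num / den - e_i**2
    z = (I - e_i) / np.sqrt(var) if var > 0 else np.inf * np.sign(I - e_i)
    p = float(stats.norm.sf(z))
    return I, float(z), p


def morans_i_permutation(
    x: np.ndarray, W: sp.csr_matrix, n_permutations: int, rng: np.random.Generator
):
    """Moran's I with a one-sided permutation p-value (label shuffles)."""
    I = morans_i(x, W)
    x = np.asarray(x, dtype=float)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = morans_i(rng.permutation(x), W)
    p = (1 + (null >= I).sum()) / (n_permutations + 1)
    return I, null, float(p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class GeneSelectionResult:
    """Per-gene Moran's I statistics with BH control and a selection flag."""

    table: pd.DataFrame  # gene_id, moran_i, z, p_value, q_value, selected

    @property
    def selected_genes(self) -> list[str]:
        return self.table.loc[self.table["selected"], "gene_id"].tolist()


def score_genes_moran(
    counts: CountMatrix,
    graph: TrajectoryGraph,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
) -> GeneSelectionResult:
    """Moran's I selection of trajectory-variable genes for one modality.

    Only cells with defined pseudotime participate.  ``q_max = 0`` (strict
    mode) is interpreted as "q below float-representable minimum p", i.e.
    q-values that underflow to exactly 0; the relaxed default uses
    ``config.q_max``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    in_comp = np.isfinite(graph.pseudotime)
    W = binary_weights(graph.knn)[np.ix_(in_comp, in_comp)]
    X = normalize_log1p(counts)[:, in_comp]
    n_genes = counts.n_genes
    I_vals = np.full(n_genes, np.nan)
    z_vals = np.full(n_genes, np.nan)
    p_vals = np.ones(n_genes)
    for g in range(n_genes):
        x = X[g]
        if np.ptp(x) == 0:
            continue  # constant gene: undefined I, never selected
        if config.selection_method == "permutation":
            I, _, p = morans_i_permutation(x, W, config.n_permutations, rng)
            z = np.nan
        else:
            I, z, p = morans_i_analytic(x, W)
        I_vals[g], z_vals[g], p_vals[g] = I, z, p
    q_vals = bh_adjust(p_vals)
    q_cut = 0.0 if config.strict_q_zero else config.q_max
    selected = (q_vals <= q_cut) & (np.nan_to_num(I_vals, nan=-np.inf) >= config.moran_min)
    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "moran_i": I_vals,
            "z": z_vals,
            "p_value": p_vals,
            "q_value": q_vals,
            "selected": selected,
        }
    )
    return GeneSelectionResult(table=table)


def select_trajectory_genes(
    counts_by_modality: dict[str, CountMatrix],
    graphs: dict[str, TrajectoryGraph],
    config: AnalysisConfig,
) -> tuple[dict[str, GeneSelectionResult], list[str]]:
    """Per-modality Moran's I selection plus the full-join (union) gene list."""
    results = {}
    union: list[str] = []
    seen = set()
    for modality, counts in counts_by_modality.items():
        res = score_genes_moran(counts, graphs[modality], config)
        results[modality] = res
        for g in res.selected_genes:
            if g not in seen:
                seen.add(g)
                union.append(g)
    if not union:
        warnings.warn("no gene passed trajectory-variable selection")
    return results, union
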