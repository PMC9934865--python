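"""Cluster-level analytics: dot-plot statistics, expression-matched module
scores, upregulated-gene sets and overlaps, marker-based cluster refinement,
and raw-count stage contrasts.

Two expression conventions coexist deliberately: most statistics use
depth-normalized ``log1p`` expression (the same convention as trajectory
preprocessing), while :func:`stage_contrast` works on ``log2(count + 1)`` of
raw counts — the convention used when contrasting per-cluster averages of
curated gene lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix, ValidationError, normalize_log1p

LOG2FC_EPS_SCALE = 1e-9  # pseudocount as a fraction of the normalization scale


def cluster_summary(counts: CountMatrix, cell_table: pd.DataFrame):
    """Per-(cluster, gene) dot-plot statistics and per-cluster QC summaries.

    Returns ``(gene_stats, cluster_stats)``: gene_stats has mean normalized
    expression, the across-cluster scaled mean (z per gene), and the
    fraction of cluster cells detecting the gene; cluster_stats has mean
    total UMI, mean genes detected and cell counts.  Empty clusters are
    excluded with a warning.
    """
    clusters = cell_table.set_index("cell_id").reindex(counts.cell_ids)["cluster_label"]
    if clusters.isna().any():
        raise ValidationError("every cell needs a cluster label")
    X = normalize_log1p(counts)
    detected = counts.values.toarray() > 0
    labels = pd.unique(clusters)
    labels = [l for l in labels if (clusters == l).sum() > 0]
    if len(labels) < len(pd.unique(clusters)):
        warnings.warn("empty clusters excluded from summary")
    mean_rows, frac_rows, cl_rows = [], [], []
    total = counts.total_umi()
    ngenes = counts.n_genes_detected()
    for label in labels:
        mask = (clusters == label).to_numpy()
        mean_rows.append(X[:, mask].mean(axis=1))
        frac_rows.append(detected[:, mask].mean(axis=1))
        cl_rows.append(
            {
                "cluster_label": label,
                "n_cells": int(mask.sum()),
                "mean_total_umi": float(total[mask].mean()),
                "mean_n_genes_detected": float(ngenes[mask].mean()),
            }
        )
    means = np.column_stack(mean_rows)  # genes x clusters
    fracs = np.column_stack(frac_rows)
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, keepdims=True)
    scaled = np.where(sd > 0, (means - mu) / np.where(sd == 0, 1, sd), 0.0)
    gene_stats = pd.concat(
        {
            "mean": pd.DataFrame(means, index=counts.gene_ids, columns=labels),
            "scaled_mean": pd.DataFrame(scaled, index=counts.gene_ids, columns=labels),
            "fraction_detected": pd.DataFrame(fracs, index=counts.gene_ids, columns=labels),
        },
        axis=1,
    ).rename_axis("gene_id")
    return gene_stats, pd.DataFrame(cl_rows)


@dataclass
class ModuleScoreResult:
    """Per-cell module scores relative to an expression-matched control set."""

    scores: np.ndarray
    target_genes: list[str]
    control_genes: list[str]
    n_bins: int
    n_ctrl: int
    seed: int


def module_score(
    counts: CountMatrix,
    target_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Score a gene module against bin-matched random control genes.

    Genes are binned into ``n_bins`` quantile bins of dataset-average
    normalized expression; each target gene contributes ``n_ctrl`` control
    draws (with replacement) from its own bin, excluding target genes.  The
    per-cell score is mean target expression minus mean control expression
    (controls counted with multiplicity).
    """
    targets = [g for g in target_set if g in counts.gene_ids]
    if not targets:
        raise ValidationError("target set empty after filtering to present genes")
    X = normalize_log1p(counts)
    avg = X.mean(axis=1)
    if len(np.unique(avg)) < n_bins:
        raise ValidationError(
            f"need >= {n_bins} distinct average-expression values for binning"
        )
    bins = pd.qcut(pd.Series(avg, index=counts.gene_ids), q=n_bins,
                   labels=False, duplicates="drop")
    target_idx = [counts.gene_ids.index(g) for g in targets]
    target_set_lookup = set(targets)
    rng = np.random.default_rng(seed)
    gene_index = pd.Index(counts.gene_ids)
    control_rows: list[int] = []
    for g in targets:
        bin_id = bins[g]
        pool = bins.index[(bins == bin_id) & ~bins.index.isin(target_set_lookup)]
        if pool.empty:
            pool = bins.index[~bins.index.isin(target_set_lookup)]
        chosen = rng.choice(pool.to_numpy(), size=n_ctrl, replace=True)
        control_rows.extend(gene_index.get_indexer(chosen))
    scores = X[target_idx].mean(axis=0) - X[control_rows].mean(axis=0)
    return ModuleScoreResult(
        scores=scores,
        target_genes=targets,
        control_genes=[counts.gene_ids[i] for i in control_rows],
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def upregulated_genes(
    counts: CountMatrix,
    cell_table: pd.DataFrame,
    cluster: str,
    log2fc_min: float = 1.0,
    min_fraction_detected: float = 0.1,
) -> pd.DataFrame:
    """Genes upregulated in a cluster vs the full dataset background.

    log2FC = log2((cluster mean + eps) / (background mean + eps)) on
    normalized expression, with a minimum cluster detection-fraction filter.
    Clusters of fewer than 3 cells yield a low-confidence warning flag.
    """
    clusters = cell_table.set_index("cell_id").reindex(counts.cell_ids)["cluster_label"]
    mask = (clusters.astype(str) == str(cluster)).to_numpy()
    if mask.sum() == 0:
        raise ValidationError(f"cluster {cluster!r} has no cells")
    low_confidence = mask.sum() < 3
    if low_confidence:
        warnings.warn(f"cluster {cluster!r} has fewer than 3 cells; low confidence")
    X = normalize_log1p(counts)
    eps = LOG2FC_EPS_SCALE * max(X.max(), 1.0)
    mean_cluster = X[:, mask].mean(axis=1)
    mean_background = X.mean(axis=1)
    log2fc = np.log2((mean_cluster + eps) / (mean_background + eps))
    frac = (counts.values[:, mask].toarray() > 0).mean(axis=1)
    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "log2fc": log2fc,
            "mean_cluster": mean_cluster,
            "mean_background": mean_background,
            "fraction_detected": frac,
            "low_confidence": low_confidence,
        }
    )
    return table[(table["log2fc"] >= log2fc_min) &
                 (table["fraction_detected"] >= min_fraction_detected)].reset_index(drop=True)


def overlap_fraction(set_a, set_b) -> dict:
    """Set overlap sizes, directional fractions and Jaccard index."""
    A, B = set(set_a), set(set_b)
    inter = A & B
    return {
        "n_a": len(A),
        "n_b": len(B),
        "n_intersection": len(inter),
        "fraction_of_a": len(inter) / len(A) if A else 0.0,
        "fraction_of_b": len(inter) / len(B) if B else 0.0,
        "jaccard": len(inter) / len(A | B) if A | B else 0.0,
    }


def refine_marker_cluster(
    counts: CountMatrix,
    cluster_cells: list[str],
    positive_signature: list[str],
    negative_markers: list[str],
    min_pos: int = 2,
    neg_threshold: int = 1,
):
    """Rule-based refinement of a marker-defined cluster on raw counts.

    A cell is excluded when any negative marker reaches ``neg_threshold``
    counts, or when it detects fewer than ``min_pos`` positive-signature
    genes.  Returns ``(kept, excluded)`` where ``excluded`` maps cell id to
    the recorded reason.
    """
    if not positive_signature or not negative_markers:
        raise ValidationError("signatures must be nonempty")
    cell_idx = {c: i for i, c in enumerate(counts.cell_ids)}
    pos_rows = [counts.gene_ids.index(g) for g in positive_signature if g in counts.gene_ids]
    neg_rows = [(g, counts.gene_ids.index(g)) for g in negative_markers if g in counts.gene_ids]
    dense = counts.values.toarray()
    kept, excluded = [], {}
    for cell in cluster_cells:
        col = cell_idx[cell]
        reason = None
        for g, r in neg_rows:
            if dense[r, col] >= neg_threshold:
                reason = f"negative marker {g}"
                break
        if reason is None and (dense[pos_rows, col] > 0).sum() < min_pos:
            reason = "insufficient positive signature"
        if reason is None:
            kept.append(cell)
        else:
            excluded[cell] = reason
    return kept, excluded


def stage_contrast(
    counts: CountMatrix,
    cell_table: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    gene_list: list[str] | None = None,
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Per-gene difference of mean log2(count+1) between two stages/clusters.

    Delta = mean(stage_b) - mean(stage_a); genes with Delta > ``threshold``
    are flagged upregulated.  Works on raw counts by design.
    """
    clusters = cell_table.set_index("cell_id").reindex(counts.cell_ids)["cluster_label"].astype(str)
    masks = {}
    for stage in (stage_a, stage_b):
        m = (clusters == str(stage)).to_numpy()
        if m.sum() == 0:
            raise ValidationError(f"stage {stage!r} has no cells")
        masks[stage] = m
    genes = gene_list if gene_list is not None else counts.gene_ids
    rows = [counts.gene_ids.index(g) for g in genes if g in counts.gene_ids]
    L = np.log2(counts.values.toarray()[rows, :] + 1.0)
    delta = L[:, masks[stage_b]].mean(axis=1) - L[:, masks[stage_a]].mean(axis=1)
    return pd.DataFrame(
        {
            "gene_id": [counts.gene_ids[r] for r in rows],
            "delta_log2": delta,
            "upregulated": delta > threshold,
        }
    )
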