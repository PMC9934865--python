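"""End-to-end orchestration: QC -> embed -> pseudotime -> gene selection ->
smoothing -> DTW warping -> transcript classification -> marker analytics.

Each stage is a thin call into the corresponding module; this file owns the
ordering, the run manifest (config snapshot, seed fan-out, per-stage wall
time, output hashes, warnings) and the result directory layout.  One global
seed fans out to stage-specific seeds by fixed offsets so any stage can be
re-run in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse.csgraph as csgraph
from scipy import stats

from . import __version__
from .core import (
    AnalysisConfig,
    filter_low_expression_genes,
    normalize_log1p,
    qc_filter,
    write_results,
)
from .dynamics import classify_transcript_dynamics
from .markers import cluster_summary, module_score
from .profiles import heatmap_table, order_by_peak, smooth_profiles
from .synthetic import (
    TRUE_TO_INFERRED,
    SimTruth,
    default_gene_params,
    simulate_paired_datasets,
)
from .trajectory import (
    compute_pseudotime,
    preprocess_embed,
    resolve_root,
    select_trajectory_genes,
)
from .warp import assign_warped_time, dtw_align

SEED_OFFSETS = {"simulate": 0, "embed": 101, "selection": 202, "modules": 303}
STAGES = ("qc", "pseudotime", "select_genes", "smooth", "align", "classify", "markers")


def _tip_root(embedding, graph, cluster_labels, root_cluster: str) -> int:
    """Refine a cluster-level root to the trajectory tip inside that cluster.

    Double sweep on the spanning forest: from the cluster medoid find the
    farthest cell overall (the opposite end of the lineage), then root at
    the cluster cell farthest from it.  Keeps the root at the extreme end
    of the starting population rather than at its middle.
    """
    medoid = resolve_root(root_cluster, [], cluster_labels, embedding)
    d0 = csgraph.dijkstra(graph.mst, directed=False, indices=medoid)
    far = int(np.nanargmax(np.where(np.isfinite(d0), d0, -np.inf)))
    d1 = csgraph.dijkstra(graph.mst, directed=False, indices=far)
    members = np.flatnonzero(np.asarray(cluster_labels).astype(str) == str(root_cluster))
    reachable = members[np.isfinite(d1[members])]
    if reachable.size == 0:
        return medoid
    return int(reachable[np.argmax(d1[reachable])])


def run_pipeline(
    config: AnalysisConfig,
    datasets: dict | None = None,
    truth: SimTruth | None = None,
    simulate: bool = False,
    n_genes: int = 300,
    n_cells_per_modality: int = 3000,
    root: dict[str, object] | str | None = None,
    out_dir: str | Path | None = None,
    until: str = "markers",
) -> dict:
    """Run the pipeline (optionally only up to stage ``until``).

    Parameters
    ----------
    datasets
        Mapping modality -> (CountMatrix, cell_table, gene_table); required
        unless ``simulate`` is set.
    truth
        Optional :class:`SimTruth`; enables recovery metrics in the summary.
    root
        Root spec per modality (cell id or cluster label), one spec for
        both, or None (defaults to the simulator's first stage label).
    """
    if until not in STAGES:
        raise ValueError(f"until must be one of {STAGES}")
    stop_at = STAGES.index(until)
    t_start = time.perf_counter()
    manifest: dict = {
        "software_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }

    def _timed(name, fn):
        t0 = time.perf_counter()
        out = fn()
        manifest["stages"][name] = {"wall_time_s": round(time.perf_counter() - t0, 3)}
        return out

    selection = union_genes = profiles = warp = warped = calls = None
    gene_stats = cluster_stats = module_scores = gene_order = None

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        if simulate:
            def _sim():
                params = default_gene_params(
                    n_genes=n_genes, seed=config.seed + SEED_OFFSETS["simulate"]
                )
                return simulate_paired_datasets(
                    params,
                    n_cells_per_modality=n_cells_per_modality,
                    seed=config.seed + SEED_OFFSETS["simulate"],
                )
            datasets, truth = _timed("simulate", _sim)
        if datasets is None:
            raise ValueError("provide datasets or set simulate=True")
        if root is None:
            root = "spermatogonia"
        if not isinstance(root, dict):
            root = {m: root for m in datasets}

        def _qc():
            out = {}
            for modality, (counts, cell_table, gene_table) in datasets.items():
                counts_qc, keep = qc_filter(counts, config)
                counts_qc = filter_low_expression_genes(
                    counts_qc, config.min_cells_per_gene
                )
                out[modality] = (
                    counts_qc,
                    cell_table.loc[keep].reset_index(drop=True),
                    gene_table,
                )
            return out

        filtered = _timed("qc", _qc)

        graphs, embeddings = {}, {}
        if stop_at >= 1:
            def _pt():
                for modality, (counts, cell_table, _) in filtered.items():
                    emb = preprocess_embed(counts, config)
                    clusters = cell_table["cluster_label"].to_numpy()
                    root_idx = resolve_root(root[modality], counts.cell_ids, clusters, emb)
                    graph = compute_pseudotime(emb, config.knn_k, root_idx, counts.cell_ids)
                    if str(root[modality]) in set(map(str, clusters)):
                        tip = _tip_root(emb, graph, clusters, str(root[modality]))
                        if tip != root_idx:
                            graph = compute_pseudotime(
                                emb, config.knn_k, tip, counts.cell_ids
                            )
                    cell_table["pseudotime"] = graph.pseudotime
                    graphs[modality] = graph
                    embeddings[modality] = emb
            _timed("pseudotime", _pt)

        if stop_at >= 2:
            selection, union_genes = _timed(
                "select_genes",
                lambda: select_trajectory_genes(
                    {m: filtered[m][0] for m in filtered}, graphs, config
                ),
            )

        shared = sorted(
            set(filtered["nuclear"][0].gene_ids)
            & set(filtered["whole_cell"][0].gene_ids)
        ) if len(filtered) == 2 else None
        if stop_at >= 3:
            def _smooth():
                out = {}
                for modality, (counts, cell_table, _) in filtered.items():
                    sub = counts.subset_genes(shared)
                    out[modality] = smooth_profiles(
                        normalize_log1p(sub),
                        graphs[modality].scaled_pseudotime(),
                        shared,
                        config,
                        modality=modality,
                    )
                return out
            profiles = _timed("smooth", _smooth)
            gene_order = order_by_peak(profiles["nuclear"], profiles["whole_cell"])

        align_genes = None
        if stop_at >= 4:
            def _align():
                genes = [g for g in union_genes if g in shared]
                w = dtw_align(profiles["nuclear"], profiles["whole_cell"], genes)
                wt = assign_warped_time(
                    w,
                    {m: graphs[m].scaled_pseudotime() for m in graphs},
                    config.grid_size,
                    query_modality="nuclear",
                )
                for modality in filtered:
                    filtered[modality][1]["warped_time"] = wt[modality]
                return genes, w, wt
            align_genes, warp, warped = _timed("align", _align)

        if stop_at >= 5:
            calls = _timed(
                "classify",
                lambda: classify_transcript_dynamics(
                    profiles["nuclear"], profiles["whole_cell"], warp, align_genes, config
                ),
            )

        if stop_at >= 6:
            def _markers():
                sn_counts, sn_cells, sn_genes = filtered["nuclear"]
                gstats, cstats = cluster_summary(sn_counts, sn_cells)
                scores = {}
                if "chromosome" in sn_genes.columns:
                    chrom = sn_genes.set_index("gene_id")["chromosome"]
                    for tag in ("X", "Y"):
                        members = [
                            g for g in sn_counts.gene_ids if chrom.get(g) == tag
                        ]
                        if len(members) >= 3:
                            scores[tag] = module_score(
                                sn_counts,
                                members,
                                n_bins=config.module_n_bins,
                                n_ctrl=config.module_n_ctrl,
                                seed=config.seed + SEED_OFFSETS["modules"],
                            )
                return gstats, cstats, scores
            gene_stats, cluster_stats, module_scores = _timed("markers", _markers)

        manifest["warnings"] = [str(w.message) for w in wrec]

    summary: dict = {
        "connected_fraction": {m: graphs[m].connected_fraction for m in graphs},
    }
    if union_genes is not None:
        summary["n_union_genes"] = len(union_genes)
    if warp is not None:
        summary["dtw_normalized_distance"] = warp.normalized_distance
    if calls is not None:
        summary["class_counts"] = calls["inferred_class"].value_counts().to_dict()
    if truth is not None and graphs:
        pt_spearman = {}
        for modality in filtered:
            ct = filtered[modality][1]
            lat = (
                truth.cells[modality]
                .set_index("cell_id")
                .reindex(ct["cell_id"])["latent_time"]
                .to_numpy()
            )
            ok = np.isfinite(ct["pseudotime"].to_numpy())
            pt_spearman[modality] = float(
                stats.spearmanr(ct["pseudotime"][ok], lat[ok]).statistic
            )
        summary["pseudotime_spearman"] = pt_spearman
        if calls is not None:
            merged = calls.merge(truth.genes, on="gene_id")
            expected = merged["true_class"].map(TRUE_TO_INFERRED)
            summary["class_recovery_accuracy"] = float(
                (merged["inferred_class"] == expected).mean()
            )
    manifest["summary"] = summary
    manifest["total_wall_time_s"] = round(time.perf_counter() - t_start, 3)

    results = {
        "datasets": filtered,
        "graphs": graphs,
        "embeddings": embeddings,
        "selection": selection,
        "union_genes": union_genes,
        "profiles": profiles,
        "warp": warp,
        "warped_time": warped,
        "calls": calls,
        "gene_order": gene_order,
        "gene_stats": gene_stats,
        "cluster_stats": cluster_stats,
        "module_scores": module_scores,
        "truth": truth,
        "manifest": manifest,
    }

    if out_dir is not None:
        tables = {}
        for modality in filtered:
            tables[f"cells_{modality}"] = filtered[modality][1]
            if selection is not None:
                tables[f"selection_{modality}"] = selection[modality].table
            if profiles is not None and gene_order is not None:
                keep = gene_order if align_genes is None else [
                    g for g in gene_order if g in align_genes
                ]
                tables[f"heatmap_{modality}"] = heatmap_table(
                    profiles[modality], keep
                ).reset_index()
        if calls is not None:
            tables["dynamics_calls"] = calls
        if cluster_stats is not None:
            tables["cluster_stats"] = cluster_stats
        if gene_order is not None:
            tables["gene_order"] = pd.DataFrame({"gene_id": gene_order})
        if warp is not None:
            warp_tab = pd.DataFrame(
                warp.path, columns=["grid_nuclear", "grid_whole_cell"]
            )
            warp_tab["warped_coordinate"] = warp.step_coordinates
            tables["warp_path"] = warp_tab
        file_manifest = write_results(tables, out_dir)
        manifest["files"] = file_manifest["files"]
        (Path(out_dir) / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
    return results
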