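"""Classification of nuclear vs whole-cell transcript behavior.

After the two modality grids share a warped-time axis, each
trajectory-variable gene is assigned exactly one behavior class:

* ``early_program`` — peaks in the first quarter of the axis;
* ``coordinate_decay`` — nuclear and whole-cell signal drop together
  (cytoplasmic decay keeps pace with transcription shutdown);
* ``perdurant_degraded_late`` — transcription stops but the mRNA persists in
  the cytoplasm, dropping only much later;
* ``perdurant_stable`` — the mRNA never falls halfway to its nadir by the end
  of the axis;
* ``spermatid_transcribed`` — (re)activated transcription late on the axis,
  detected as late nuclear enrichment over earlier maxima;
* ``flat`` — not trajectory-variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisConfig, CountMatrix, ValidationError, normalize_log1p
from .profiles import SmoothedProfiles, find_drop_landmark
from .warp import WarpPath

CLASSES = (
    "early_program",
    "coordinate_decay",
    "perdurant_degraded_late",
    "perdurant_stable",
    "spermatid_transcribed",
    "flat",
)


def call_spermatid_transcribed(
    profiles_sn: SmoothedProfiles,
    late_window_fraction: float = 0.25,
    fold_min: float = 2.0,
    floor: float | None = None,
    axis: np.ndarray | None = None,
) -> pd.DataFrame:
    """Call genes transcriptionally (re)activated late on the axis.

    A gene is called when its late-window maximum of smoothed (non-z)
    nuclear expression is at least ``fold_min`` times its earlier maximum
    (floored at ``floor``) and itself exceeds ``floor``.  ``axis`` defaults
    to the profile grid; pass per-grid warped coordinates to call on warped
    time.  ``floor`` defaults to the 5th percentile of positive smoothed
    values.
    """
    grid_axis = profiles_sn.grid if axis is None else np.asarray(axis, float)
    late = grid_axis >= grid_axis.max() - late_window_fraction * (
        grid_axis.max() - grid_axis.min()
    )
    if not late.any() or late.all():
        raise ValidationError("late window is empty or covers the whole axis")
    S = profiles_sn.smooth
    if floor is None:
        positive = S[S > 0]
        floor = float(np.percentile(positive, 5)) if positive.size else 1e-6
    late_max = S[:, late].max(axis=1)
    early_max = S[:, ~late].max(axis=1)
    fold = late_max / np.maximum(early_max, floor)
    called = (fold >= fold_min) & (late_max >= floor)
    return pd.DataFrame(
        {
            "gene_id": profiles_sn.gene_ids,
            "late_fold_change": fold,
            "late_max": late_max,
            "early_max": early_max,
            "called": called,
        }
    )


@dataclass
class DynamicsCall:
    gene_id: str
    inferred_class: str
    sn_drop: float
    sc_drop: float
    perdurance_delta: float
    late_fold_change: float


def classify_transcript_dynamics(
    profiles_sn: SmoothedProfiles,
    profiles_sc: SmoothedProfiles,
    warp: WarpPath,
    selected_genes: list[str],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """One behavior class per gene via a deterministic decision cascade.

    Cascade: not selected -> flat; late nuclear enrichment ->
    spermatid_transcribed; early peak -> early_program; otherwise compare
    nuclear and whole-cell 50%-drop landmarks on the warped axis:
    small offset -> coordinate_decay, large offset -> perdurant_degraded_late,
    no whole-cell drop -> perdurant_stable.
    """
    if profiles_sn.gene_ids != profiles_sc.gene_ids:
        raise ValidationError("profiles must be aligned on an identical gene set")
    axis_sn = warp.grid_coordinates("query")
    axis_sc = warp.grid_coordinates("reference")
    spermatid = call_spermatid_transcribed(
        profiles_sn,
        late_window_fraction=config.late_window_fraction,
        fold_min=config.reactivation_fold_min,
        axis=axis_sn,
    ).set_index("gene_id")
    selected = set(selected_genes)
    rows = []
    for i, gene in enumerate(profiles_sn.gene_ids):
        fold = float(spermatid.loc[gene, "late_fold_change"])
        sn_drop = sc_drop = delta = np.nan
        if gene not in selected:
            cls = "flat"
        elif bool(spermatid.loc[gene, "called"]):
            cls = "spermatid_transcribed"
        else:
            peak_pos = axis_sn[profiles_sn.peak_index[i]]
            sn_grid_drop = find_drop_landmark(
                profiles_sn.zscore[i], profiles_sn.grid, config.drop_fraction
            )
            sc_grid_drop = find_drop_landmark(
                profiles_sc.zscore[i], profiles_sc.grid, config.drop_fraction
            )
            # map grid-time landmarks onto the warped axis
            if np.isfinite(sn_grid_drop):
                sn_drop = float(np.interp(sn_grid_drop, profiles_sn.grid, axis_sn))
            if np.isfinite(sc_grid_drop):
                sc_drop = float(np.interp(sc_grid_drop, profiles_sc.grid, axis_sc))
            delta = sc_drop - sn_drop
            if peak_pos <= config.early_peak_fraction:
                cls = "early_program"
            elif np.isfinite(sn_drop) and np.isfinite(sc_drop) and delta <= config.delta_min:
                cls = "coordinate_decay"
            elif np.isfinite(sc_drop) and (not np.isfinite(sn_drop) or delta > config.delta_min):
                cls = "perdurant_degraded_late"
            else:
                cls = "perdurant_stable"
        rows.append(
            {
                "gene_id": gene,
                "inferred_class": cls,
                "sn_drop": sn_drop,
                "sc_drop": sc_drop,
                "perdurance_delta": delta,
                "late_fold_change": fold,
            }
        )
    return pd.DataFrame(rows)


def reactivation_concordance(
    counts_sn: CountMatrix,
    warped_time: np.ndarray,
    called_genes: list[str],
    late_window_fraction: float = 0.25,
    n_shuffles: int = 10000,
    seed: int = 0,
):
    """Pairwise detection concordance of late-transcribed genes in late cells.

    Detection is count >= 1 per cell in the late window; concordance is the
    phi coefficient per gene pair.  Genes detected in no or all late cells
    have undefined phi and are excluded (flagged).  Reports the Spearman
    correlation between per-gene mean concordance and mean late normalized
    expression, with a permutation p-value.
    """
    if len(called_genes) < 2:
        raise ValidationError("need >= 2 called genes")
    wt = np.asarray(warped_time, float)
    late = np.isfinite(wt) & (wt >= 1.0 - late_window_fraction)
    if late.sum() < 20:
        raise ValidationError("need >= 20 late-window cells")
    sub = counts_sn.subset_genes(called_genes).subset_cells(late)
    det = (sub.values.toarray() > 0).astype(float)  # genes x late cells
    rates = det.mean(axis=1)
    usable = (rates > 0) & (rates < 1)
    excluded = [g for g, u in zip(called_genes, usable) if not u]
    det_u = det[usable]
    genes_u = [g for g, u in zip(called_genes, usable) if u]
    if len(genes_u) < 2:
        raise ValidationError("fewer than 2 genes with non-degenerate detection")
    phi = np.corrcoef(det_u)  # Pearson on binaries == phi coefficient
    np.fill_diagonal(phi, np.nan)
    mean_phi = np.nanmean(phi, axis=1)
    expr = normalize_log1p(sub)[usable].mean(axis=1)
    rho = float(stats.spearmanr(mean_phi, expr).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", stats.ConstantInputWarning)
        for b in range(n_shuffles):
            null[b] = stats.spearmanr(mean_phi, rng.permutation(expr)).statistic
    p = float((1 + (np.abs(null) >= abs(rho)).sum()) / (n_shuffles + 1))
    table = pd.DataFrame(
        {"gene_id": genes_u, "mean_concordance": mean_phi, "mean_late_expression": expr}
    )
    return {
        "pairwise_phi": pd.DataFrame(phi, index=genes_u, columns=genes_u),
        "per_gene": table,
        "excluded": excluded,
        "spearman_rho": rho,
        "permutation_p": p,
        "n_late_cells": int(late.sum()),
    }
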