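# perduraflow

Comparative nuclear vs whole-cell transcriptomics of a differentiating
lineage: pseudotime inference, trajectory-variable gene selection,
spline-smoothed expression profiles, dynamic-time-warping alignment of the
two modalities onto one warped axis, and classification of transcripts into
storage / decay / late-transcription behavior classes — plus the
cluster-level marker and module-score analytics that accompany such
studies.

## The problem

Single-nucleus RNA-seq sees transcripts where they are made; single-cell
RNA-seq additionally sees the cytoplasmic pool, which can outlive
transcription by a long time.  In a differentiating germline (the
motivating system is *Drosophila* spermatogenesis), transcription largely
shuts down as spermatids form, yet many mRNAs persist — stored for later
translation — while a small set of genes is newly transcribed in otherwise
quiet spermatids.  Comparing the two modalities along a shared
differentiation axis separates these behaviors gene by gene.

For each modality, cells get a pseudotime: the geodesic distance from a
root cell along the minimum spanning tree of a kNN graph in PCA space.
Genes varying along the trajectory are flagged by Moran's I
autocorrelation on the cell graph,

    I = (N / Σw) · Σᵢⱼ wᵢⱼ (xᵢ − x̄)(xⱼ − x̄) / Σᵢ (xᵢ − x̄)²,

with analytic one-sided p-values and Benjamini–Hochberg control (selected:
q ≤ 1e-4 and I ≥ 0.25).  Expression is smoothed over pseudotime with a
3-df penalized cubic spline onto a 100-point grid and z-scored per gene.
The nuclear and whole-cell grids are aligned by dynamic time warping
(local cost 1 − Pearson correlation across the shared gene vector,
symmetric2 steps), giving every cell a warped-time coordinate.  Each gene
is then classified by a deterministic cascade into `flat`,
`early_program`, `coordinate_decay`, `perdurant_degraded_late`,
`perdurant_stable`, or `spermatid_transcribed` (late nuclear enrichment
≥ 2× earlier maxima), using 50%-drop landmarks ("dropped halfway from peak
to nadir") as evidence.

A two-compartment kinetic simulator (dn/dt = α(t) − βn,
dc/dt = βn − δ(t)c, negative-binomial sampling, stage-dependent depth)
generates paired datasets with known per-gene classes, so the whole
pipeline is testable offline.  See `docs/methods.md` for the model,
parameter meanings, and design choices.

## Worked example

```python
import json
from perduraflow import AnalysisConfig, run_pipeline

config = AnalysisConfig(seed=1, min_genes_per_cell=30)
res = run_pipeline(config, simulate=True, n_genes=300, n_cells_per_modality=3000)
print(json.dumps(res["manifest"]["summary"], indent=2, sort_keys=True))
```

prints (about five seconds on one CPU):

```json
{
  "class_counts": {
    "coordinate_decay": 141,
    "early_program": 45,
    "flat": 60,
    "perdurant_stable": 24,
    "spermatid_transcribed": 30
  },
  "class_recovery_accuracy": 0.93,
  "connected_fraction": {"nuclear": 1.0, "whole_cell": 1.0},
  "dtw_normalized_distance": 0.07119428821365466,
  "n_union_genes": 240,
  "pseudotime_spearman": {
    "nuclear": 0.9773786468198495,
    "whole_cell": 0.9736141921793546
  }
}
```

Reading this: every cell connected to the root's component in both
modalities; 240 of 300 genes called trajectory-variable (all 240 dynamic
genes, none of the 60 flat ones); pseudotime rank-agrees with the hidden
latent time at ρ ≈ 0.97 per modality; the two grids align with a small
DTW distance; and 93% of genes land in their true kinetic class — the
`perdurance_delta` column of `res["calls"]` holds the per-gene evidence
(whole-cell minus nuclear drop time on the warped axis).

The same run from a shell, with TSV/MTX artifacts written to `out/`:

```sh
perduraflow run --simulate --seed 1 --out out/
perduraflow simulate --seed 1 --out sim/        # datasets + ground truth
perduraflow pseudotime --nuclear sim/ --cells sim/ --out out/   # single stage
```

Stage subcommands (`pseudotime`, `select-genes`, `smooth`, `align`,
`classify`, `markers`) recompute deterministically from the raw inputs up
to the named stage.  Real datasets enter as Matrix Market counts plus TSV
gene/cell annotations (genes are rows; MTX is 1-based on disk, 0-based in
memory).

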