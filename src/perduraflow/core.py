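"""Shared domain types and count-matrix / annotation-table I/O.

Conventions used throughout the package:

* genes are rows, cells are columns;
* Matrix Market files are 1-based on disk (the format's own convention) and
  0-based once loaded;
* counts are raw non-negative integers; "normalized expression" always means
  per-cell depth normalization to the median total followed by ``log1p``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

MODALITIES = ("nuclear", "whole_cell")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the expected layout."""


class ValidationError(ValueError):
    """Raised when in-memory data violates a domain invariant."""


@dataclass
class CountMatrix:
    """Sparse genes x cells raw count matrix with aligned identifiers.

    Parameters
    ----------
    values
        Sparse non-negative integer matrix, genes in rows, cells in columns.
    gene_ids, cell_ids
        Ordered unique identifiers for the two axes.
    modality
        ``"nuclear"`` (snRNA-seq style, nuclear transcripts only) or
        ``"whole_cell"`` (scRNA-seq style, nuclear + cytoplasmic).
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"gene axis mismatch: matrix has {n_genes} rows but "
                f"{len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise FormatError(
                f"cell axis mismatch: matrix has {n_cells} columns but "
                f"{len(self.cell_ids)} cell ids"
            )
        for axis, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValidationError(f"duplicated {axis} ids: {dupes}")
        if self.values.nnz:
            data = self.values.data
            if data.min() < 0:
                raise ValidationError("negative count entries are not allowed")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer count entries are not allowed")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def total_umi(self) -> np.ndarray:
        """Per-cell total counts (column sums)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def n_genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with a nonzero count."""
        return np.asarray((self.values > 0).sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        keep = np.asarray(mask)
        return CountMatrix(
            self.values[:, keep],
            self.gene_ids,
            [c for c, m in zip(self.cell_ids, keep) if m]
            if keep.dtype == bool
            else [self.cell_ids[i] for i in keep],
            self.modality,
        )

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return CountMatrix(self.values[rows, :], list(gene_ids), self.cell_ids, self.modality)


def make_cell_table(counts: CountMatrix, extra: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build the per-cell annotation table, recomputing the derived columns."""
    table = pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "modality": counts.modality,
            "total_umi": counts.total_umi().astype(int),
            "n_genes_detected": counts.n_genes_detected().astype(int),
        }
    )
    for col, default in (
        ("cluster_label", ""),
        ("annotation", ""),
        ("pseudotime", np.nan),
        ("warped_time", np.nan),
    ):
        table[col] = default
    if extra is not None:
        extra = extra.set_index("cell_id") if "cell_id" in extra.columns else extra
        for col in extra.columns:
            if col in ("total_umi", "n_genes_detected", "modality"):
                continue
            table[col] = extra.reindex(counts.cell_ids)[col].to_numpy()
    return table


def make_gene_table(counts: CountMatrix, extra: pd.DataFrame | None = None) -> pd.DataFrame:
    table = pd.DataFrame({"gene_id": counts.gene_ids})
    table["symbol"] = table["gene_id"]
    table["chromosome"] = "autosome"
    if extra is not None:
        extra = extra.set_index("gene_id") if "gene_id" in extra.columns else extra
        for col in extra.columns:
            table[col] = extra.reindex(counts.gene_ids)[col].to_numpy()
    return table


@dataclass
class AnalysisConfig:
    """Thresholds and sizes for every pipeline stage.

    Defaults follow the upstream snRNA-seq workflow this pipeline mirrors:
    cells with fewer than 200 detected genes or more than 15% mitochondrial
    counts are discarded, embeddings use 50 principal components, trajectory
    genes require Moran's I >= 0.25 at a (relaxed) q <= 1e-4, expression is
    smoothed with a 3-degree-of-freedom spline, and the drop landmark is the
    point where a profile has fallen 50% from peak toward its nadir.
    """

    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.15
    mito_prefixes: tuple[str, ...] = ("mt:",)
    min_cells_per_gene: int = 3
    gene_filter_before_subset: bool = True
    n_dims: int = 50
    n_hvg: int = 2000
    knn_k: int = 30
    spline_df: float = 3.0
    spline_basis_size: int = 24
    grid_size: int = 100
    moran_min: float = 0.25
    q_max: float = 1e-4
    strict_q_zero: bool = False
    selection_method: str = "analytic"  # or "permutation"
    n_permutations: int = 1000
    drop_fraction: float = 0.5
    early_peak_fraction: float = 0.25
    delta_min: float = 0.1
    late_window_fraction: float = 0.25
    reactivation_fold_min: float = 2.0
    log2fc_min: float = 1.0
    min_fraction_detected: float = 0.1
    stage_delta_threshold: float = 0.25
    module_n_bins: int = 25
    module_n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.min_genes_per_cell >= 0, "min_genes_per_cell must be >= 0"),
            (0 <= self.max_mito_fraction <= 1, "max_mito_fraction must be in [0,1]"),
            (self.n_dims >= 1, "n_dims must be >= 1"),
            (self.knn_k >= 2, "knn_k must be >= 2"),
            (self.spline_df >= 2, "spline_df must be >= 2"),
            (self.grid_size >= 4, "grid_size must be >= 4"),
            (0 < self.drop_fraction <= 1, "drop_fraction must be in (0,1]"),
            (0 < self.late_window_fraction < 1, "late_window_fraction in (0,1)"),
            (self.q_max >= 0, "q_max must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)
        self.mito_prefixes = tuple(self.mito_prefixes)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["mito_prefixes"] = list(data["mito_prefixes"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def read_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    modality: str,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a Matrix Market counts file plus TSV gene/cell annotations.

    Returns the validated :class:`CountMatrix` together with freshly built
    cell and gene tables (derived columns such as ``total_umi`` are always
    recomputed from the matrix, never trusted from disk).
    """
    for p in (matrix_path, genes_path, cells_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"could not parse Matrix Market file {matrix_path}: {exc}")
    genes = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str})
    cells = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str})
    if "gene_id" not in genes.columns:
        raise FormatError(f"{genes_path} lacks a 'gene_id' header column")
    if "cell_id" not in cells.columns:
        raise FormatError(f"{cells_path} lacks a 'cell_id' header column")
    counts = CountMatrix(
        sp.csr_matrix(mat), genes["gene_id"].tolist(), cells["cell_id"].tolist(), modality
    )
    return counts, make_cell_table(counts, cells), make_gene_table(counts, genes)


def write_counts(counts: CountMatrix, cell_table: pd.DataFrame,
                 gene_table: pd.DataFrame, out_dir: str | Path, prefix: str = "") -> dict:
    """Write one modality's matrix + annotation triplet; returns the manifest entry."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{prefix}{counts.modality}"
    mtx = out / f"{stem}_matrix.mtx"
    scipy.io.mmwrite(str(mtx), sp.coo_matrix(counts.values), field="integer")
    genes_p = out / f"{stem}_genes.tsv"
    cells_p = out / f"{stem}_cells.tsv"
    gene_table.to_csv(genes_p, sep="\t", index=False)
    cell_table.to_csv(cells_p, sep="\t", index=False)
    return {
        "matrix": mtx.name,
        "genes": genes_p.name,
        "cells": cells_p.name,
        "n_genes": counts.n_genes,
        "n_cells": counts.n_cells,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict:
    """Write named tables as TSV with stable column order plus a JSON manifest.

    The manifest lists every file with its row count and content hash; writing
    the same inputs twice produces byte-identical output.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out} is not writable: {exc}")
    manifest: dict = {"files": []}
    for name in sorted(tables):
        table = tables[name]
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, lineterminator="\n")
        manifest["files"].append(
            {"name": path.name, "rows": int(len(table)), "sha256": _sha256(path)}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def mito_fraction(counts: CountMatrix, prefixes: tuple[str, ...] = ("mt:",)) -> np.ndarray:
    """Per-cell fraction of counts from mitochondrial genes (id-prefix match)."""
    is_mito = np.array(
        [any(g.startswith(p) for p in prefixes) for g in counts.gene_ids], dtype=bool
    )
    total = counts.total_umi().astype(float)
    if not is_mito.any():
        return np.zeros(counts.n_cells)
    mito = np.asarray(counts.values[is_mito, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / total, 0.0)
    return frac


def qc_filter(
    counts: CountMatrix, config: AnalysisConfig
) -> tuple[CountMatrix, np.ndarray]:
    """Keep cells with >= min_genes_per_cell detected genes and bounded mito content."""
    keep = (counts.n_genes_detected() >= config.min_genes_per_cell) & (
        mito_fraction(counts, config.mito_prefixes) <= config.max_mito_fraction
    )
    return counts.subset_cells(keep), keep


def filter_low_expression_genes(counts: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Drop genes detected in fewer than ``min_cells`` cells."""
    detected = np.asarray((counts.values > 0).sum(axis=1)).ravel()
    keep = [g for g, d in zip(counts.gene_ids, detected) if d >= min_cells]
    return counts.subset_genes(keep)


def normalize_log1p(counts: CountMatrix, target: float | None = None) -> np.ndarray:
    """Depth-normalize each cell to the median total (or ``target``) and log1p.

    Returns a dense genes x cells array of normalized expression.
    """
    totals = counts.total_umi().astype(float)
    if target is None:
        positive = totals[totals > 0]
        target = float(np.median(positive)) if positive.size else 1.0
    scale = np.where(totals > 0, target / np.maximum(totals, 1e-12), 0.0)
    dense = counts.values.toarray().astype(float)
    return np.log1p(dense * scale[None, :])
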