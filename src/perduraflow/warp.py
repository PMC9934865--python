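"""Dynamic time warping of two modality-specific pseudotime grids.

The local cost between grid point i of the nuclear profiles and grid point
j of the whole-cell profiles is 1 - Pearson correlation across the shared
gene vector.  Accumulation uses the symmetric2 step pattern

    D(i,j) = min( D(i-1,j)   +     d(i,j),
                  D(i-1,j-1) + 2 * d(i,j),
                  D(i,j-1)   +     d(i,j) )

with D(0,0) = d(0,0), full boundary conditions and no window constraint.
Backtracking prefers the diagonal on ties for determinism.  The aligned
path defines a common warped-time coordinate on [0, 1]: step k of an
L-step path sits at k/(L-1), and each grid index takes the mean coordinate
of the path steps that visit it.  Note DTW distance is not a metric
(no triangle inequality); only identity and symmetry are relied upon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError
from .profiles import SmoothedProfiles


@dataclass
class WarpPath:
    """A symmetric2 DTW alignment of an m-grid onto an n-grid."""

    local_cost: np.ndarray        # m x n
    accumulated_cost: np.ndarray  # m x n
    path: list[tuple[int, int]]   # (i, j) pairs from (0,0) to (m-1,n-1)
    normalized_distance: float    # D(m-1,n-1) / (m + n)

    @property
    def step_coordinates(self) -> np.ndarray:
        L = len(self.path)
        return np.arange(L) / (L - 1) if L > 1 else np.zeros(1)

    def grid_coordinates(self, side: str) -> np.ndarray:
        """Warped coordinate per grid index for 'query' (i) or 'reference' (j)."""
        axis = 0 if side == "query" else 1
        size = self.local_cost.shape[axis]
        coords = self.step_coordinates
        out = np.empty(size)
        idx = np.array([p[axis] for p in self.path])
        for g in range(size):
            out[g] = coords[idx == g].mean()
        return out


def correlation_cost_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between every column pair of A and B.

    Zero-variance columns get cost 1 (zero correlation by convention).
    """
    Ac = A - A.mean(axis=0, keepdims=True)
    Bc = B - B.mean(axis=0, keepdims=True)
    sa = np.sqrt((Ac**2).sum(axis=0))
    sb = np.sqrt((Bc**2).sum(axis=0))
    num = Ac.T @ Bc
    denom = np.outer(sa, sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / np.where(denom == 0, 1.0, denom), 0.0)
    return 1.0 - corr


def dtw_from_cost(d: np.ndarray) -> WarpPath:
    """Symmetric2 DTW over a precomputed local cost matrix."""
    m, n = d.shape
    D = np.full((m, n), np.inf)
    D[0, 0] = d[0, 0]
    for i in range(1, m):
        D[i, 0] = D[i - 1, 0] + d[i, 0]
    for j in range(1, n):
        D[0, j] = D[0, j - 1] + d[0, j]
    for i in range(1, m):
        for j in range(1, n):
            D[i, j] = min(
                D[i - 1, j - 1] + 2 * d[i, j],
                D[i - 1, j] + d[i, j],
                D[i, j - 1] + d[i, j],
            )
    # backtrack, diagonal preferred on ties, then vertical, then horizontal
    path = [(m - 1, n - 1)]
    i, j = m - 1, n - 1
    tol = 1e-12
    while (i, j) != (0, 0):
        here = D[i, j]
        if i > 0 and j > 0 and abs(D[i - 1, j - 1] + 2 * d[i, j] - here) <= tol:
            i, j = i - 1, j - 1
        elif i > 0 and abs(D[i - 1, j] + d[i, j] - here) <= tol:
            i -= 1
        elif j > 0 and abs(D[i, j - 1] + d[i, j] - here) <= tol:
            j -= 1
        else:  # numerical fallback: take the cheapest admissible predecessor
            cands = []
            if i > 0 and j > 0:
                cands.append((D[i - 1, j - 1] + 2 * d[i, j], 0, (i - 1, j - 1)))
            if i > 0:
                cands.append((D[i - 1, j] + d[i, j], 1, (i - 1, j)))
            if j > 0:
                cands.append((D[i, j - 1] + d[i, j], 2, (i, j - 1)))
            i, j = min(cands)[2]
        path.append((i, j))
    path.reverse()
    return WarpPath(
        local_cost=d,
        accumulated_cost=D,
        path=path,
        normalized_distance=float(D[m - 1, n - 1] / (m + n)),
    )


def dtw_align(
    profiles_sn: SmoothedProfiles,
    profiles_sc: SmoothedProfiles,
    shared_genes: list[str] | None = None,
) -> WarpPath:
    """Align two modality grids with correlation cost and symmetric2 steps.

    Both profile sets are restricted to ``shared_genes`` (default: the
    intersection in nuclear order) and compared via their z-scored rows.
    """
    if shared_genes is None:
        sc_set = set(profiles_sc.gene_ids)
        shared_genes = [g for g in profiles_sn.gene_ids if g in sc_set]
    if len(shared_genes) < 2:
        raise ValidationError(
            "need >= 2 shared genes for a correlation cost; run "
            "select_trajectory_genes first"
        )
    A = profiles_sn.subset(shared_genes).zscore  # genes x m
    B = profiles_sc.subset(shared_genes).zscore  # genes x n
    return dtw_from_cost(correlation_cost_matrix(A, B))


def grid_index_of(pseudotime_scaled: np.ndarray, grid_size: int) -> np.ndarray:
    """Nearest-grid-point index for scaled pseudotime, NaN-preserving."""
    pt = np.asarray(pseudotime_scaled, dtype=float)
    idx = np.full(pt.shape, -1, dtype=int)
    ok = np.isfinite(pt)
    idx[ok] = np.clip(np.round(pt[ok] * (grid_size - 1)).astype(int), 0, grid_size - 1)
    return idx


def assign_warped_time(
    warp: WarpPath,
    pseudotime_by_modality: dict[str, np.ndarray],
    grid_size: int,
    query_modality: str = "nuclear",
) -> dict[str, np.ndarray]:
    """Give every cell in both modalities a warped-time coordinate in [0, 1].

    Each cell maps to the nearest grid point of its own (scaled) pseudotime
    axis and inherits that grid point's warped coordinate.  Cells without
    pseudotime get NaN.
    """
    out = {}
    for modality, pt in pseudotime_by_modality.items():
        side = "query" if modality == query_modality else "reference"
        coords = warp.grid_coordinates(side)
        idx = grid_index_of(pt, grid_size)
        wt = np.full(len(idx), np.nan)
        ok = idx >= 0
        wt[ok] = coords[idx[ok]]
        out[modality] = wt
    return out
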