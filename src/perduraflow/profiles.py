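"""Smoothed, z-scored per-gene expression profiles on a pseudotime grid.

The smoother is a penalized cubic B-spline on uniform (unrepeated) knots
with a second-order difference penalty on the coefficients; the penalty
weight is chosen by bisection so that the trace of the smoother matrix —
the effective degrees of freedom — equals the configured ``spline_df``
(default 3, matching a 3-df smoothing spline).  Because the knots are
uniform, straight lines lie exactly in the penalty null space: linear data
are reproduced exactly and the fit is affine-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .core import AnalysisConfig, ValidationError


class DegenerateSupportError(ValueError):
    """Raised when pseudotime support cannot anchor a spline fit."""


def _uniform_basis(x: np.ndarray, n_basis: int, lo: float, hi: float):
    """Cubic B-spline design matrix on uniform knots extended past [lo, hi]."""
    n_seg = n_basis - 3
    h = (hi - lo) / n_seg
    knots = lo + h * np.arange(-3, n_seg + 4)
    B = BSpline.design_matrix(np.clip(x, lo, hi), knots, 3).toarray()
    return B, knots


def _second_difference_penalty(n_basis: int) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    return D.T @ D


def effective_df(BtB: np.ndarray, P: np.ndarray, lam: float) -> float:
    """tr(S) for the smoother S = B (B'B + lam P)^-1 B'."""
    A = np.linalg.solve(BtB + lam * P, BtB)
    return float(np.trace(A))


def _solve_lambda_for_df(BtB: np.ndarray, P: np.ndarray, df: float, tol: float = 1e-3):
    """Bisection on log-lambda so that the smoother trace equals ``df``."""
    lo, hi = 1e-10, 1e12
    if effective_df(BtB, P, lo) < df - tol:
        return lo  # cannot reach requested df; basis too small (caller warns)
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        d = effective_df(BtB, P, mid)
        if abs(d - df) <= tol:
            return mid
        if d > df:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


@dataclass
class SmoothedProfiles:
    """Per-gene smoothed expression over a shared pseudotime grid.

    ``smooth`` holds spline-fitted normalized expression (genes x grid);
    ``zscore`` is the row-standardized version, all-zero (and flagged) for
    constant rows.  ``peak_time`` is the grid argmax of the smooth row.
    """

    modality: str
    gene_ids: list[str]
    grid: np.ndarray
    smooth: np.ndarray
    zscore: np.ndarray
    constant_mask: np.ndarray

    @property
    def peak_time(self) -> np.ndarray:
        return self.grid[np.argmax(self.smooth, axis=1)]

    @property
    def peak_index(self) -> np.ndarray:
        return np.argmax(self.smooth, axis=1)

    def row(self, gene_id: str, z: bool = False) -> np.ndarray:
        i = self.gene_ids.index(gene_id)
        return self.zscore[i] if z else self.smooth[i]

    def subset(self, gene_ids: list[str]) -> "SmoothedProfiles":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return SmoothedProfiles(
            self.modality, list(gene_ids), self.grid,
            self.smooth[idx], self.zscore[idx], self.constant_mask[idx],
        )


def fit_penalized_spline(
    x: np.ndarray, Y: np.ndarray, grid: np.ndarray, df: float, n_basis: int = 24
) -> np.ndarray:
    """Fit each row of ``Y`` (observations along ``x``) at trace-df ``df``.

    Returns fitted values on ``grid`` (rows x grid).  The penalty weight is
    shared across rows: the smoother trace depends only on the design, not
    the response.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if np.ptp(x) == 0:
        raise DegenerateSupportError("all observations at a single pseudotime")
    n_basis = int(min(n_basis, max(int(df) + 2, x.size // 2, 6)))
    lo, hi = float(min(x.min(), grid.min())), float(max(x.max(), grid.max()))
    B, knots = _uniform_basis(x, n_basis, lo, hi)
    P = _second_difference_penalty(n_basis)
    BtB = B.T @ B
    lam = _solve_lambda_for_df(BtB, P, df)
    coef = np.linalg.solve(BtB + lam * P, B.T @ Y.T)  # n_basis x rows
    B_grid = BSpline.design_matrix(np.clip(grid, lo, hi), knots, 3).toarray()
    return (B_grid @ coef).T


def zscore_rows(M: np.ndarray, tol: float = 1e-12):
    """Row-standardize; constant rows become all zeros and are flagged."""
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    constant = (sd < tol).ravel()
    sd_safe = np.where(sd < tol, 1.0, sd)
    Z = (M - mu) / sd_safe
    Z[constant] = 0.0
    return Z, constant


def smooth_profiles(
    expression: np.ndarray,
    pseudotime: np.ndarray,
    gene_ids: list[str],
    config: AnalysisConfig,
    modality: str = "nuclear",
) -> SmoothedProfiles:
    """Smooth normalized log1p expression over scaled pseudotime.

    Cells with undefined pseudotime are dropped.  Profiles are evaluated on
    ``grid_size`` evenly spaced points spanning [0, 1] of scaled pseudotime.
    """
    pt = np.asarray(pseudotime, dtype=float)
    ok = np.isfinite(pt)
    if ok.sum() < 10:
        raise ValidationError("need >= 10 cells with defined pseudotime")
    pt = pt[ok]
    if np.ptp(pt) == 0:
        raise DegenerateSupportError("all cells share one pseudotime value")
    E = np.atleast_2d(expression)[:, ok]
    grid = np.linspace(0.0, 1.0, config.grid_size)
    smooth = fit_penalized_spline(
        pt, E, grid, df=config.spline_df, n_basis=config.spline_basis_size
    )
    Z, constant = zscore_rows(smooth)
    return SmoothedProfiles(
        modality=modality, gene_ids=list(gene_ids), grid=grid,
        smooth=smooth, zscore=Z, constant_mask=constant,
    )


def order_by_peak(
    profiles_sn: SmoothedProfiles, profiles_sc: SmoothedProfiles
) -> list[str]:
    """Order genes by the mean of their two modality peak times.

    Ties are broken lexicographically by gene id for determinism.
    """
    if profiles_sn.gene_ids != profiles_sc.gene_ids:
        raise ValidationError("profiles must share an identical, aligned gene set")
    mean_peak = 0.5 * (profiles_sn.peak_time + profiles_sc.peak_time)
    order = sorted(zip(mean_peak, profiles_sn.gene_ids))
    return [g for _, g in order]


def find_drop_landmark(
    profile: np.ndarray, grid: np.ndarray, drop_fraction: float = 0.5
) -> float:
    """First grid time after the peak where the profile has fallen
    ``drop_fraction`` of the way from its peak to its nadir.

    The nadir is the post-peak minimum, so for a z-scored row descending
    symmetrically and ``drop_fraction=0.5`` the threshold is the z=0
    crossing.  Returns NaN when the row is constant, when the peak sits at
    the last grid point (a profile still at maximum at the axis end — a
    stable perdurant transcript), or when no post-peak point reaches the
    threshold.
    """
    profile = np.asarray(profile, dtype=float)
    if np.ptp(profile) == 0:
        return np.nan
    k = int(np.argmax(profile))
    post = profile[k:]
    if post.size < 2:
        return np.nan
    peak = post[0]
    nadir = post.min()
    if nadir == peak:
        return np.nan
    threshold = peak - drop_fraction * (peak - nadir)
    below = np.nonzero(post[1:] <= threshold)[0]
    if below.size == 0:
        return np.nan
    return float(grid[k + 1 + below[0]])


def heatmap_table(
    profiles: SmoothedProfiles, gene_order: list[str]
) -> pd.DataFrame:
    """Z-score heatmap matrix (rows ordered by peak time) ready for export."""
    sub = profiles.subset(gene_order)
    return pd.DataFrame(sub.zscore, index=gene_order,
                        columns=[f"t{t:.4f}" for t in sub.grid]).rename_axis("gene_id")
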