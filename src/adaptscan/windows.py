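"""Spline-delimited genomic windows and the Wstat window statistic.

A cubic smoothing spline (penalty chosen by generalized cross-validation)
is fitted to the per-SNP Bayes-factor track along each chromosome and
evaluated on a fixed grid (default 10 kbp). Sign changes of the discrete
second difference of the fitted values — inflection points — become window
boundaries, so windows adapt their length to the local signal. Each window
is scored with

    Wstat = sqrt(n) * (mean(BF in window) - mu) / sigma

where mu and sigma are the genome-wide mean and standard deviation of the
statistic, and windows above the 99th percentile of Wstat (per covariate,
strict inequality, linear-interpolation quantile) are outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline


@dataclass
class SplineFit:
    chrom: str
    grid: np.ndarray       # bp positions, fixed spacing
    fitted: np.ndarray


def fit_spline(
    positions: np.ndarray,
    bf: np.ndarray,
    grid_bp: int = 10000,
    chrom: str = "",
) -> SplineFit:
    """GCV smoothing spline of the BF track, evaluated at grid_bp spacing."""
    positions = np.asarray(positions, dtype=float)
    bf = np.asarray(bf, dtype=float)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    grid = np.arange(positions[0], positions[-1] + grid_bp, grid_bp)
    grid = grid[grid <= positions[-1]]
    if grid[-1] < positions[-1]:
        grid = np.append(grid, positions[-1])
    if np.allclose(bf, bf[0]):
        # constant signal: spline is the constant itself
        return SplineFit(chrom=chrom, grid=grid, fitted=np.full_like(grid, bf[0]))
    spl = make_smoothing_spline(positions, bf)  # lam chosen by GCV
    return SplineFit(chrom=chrom, grid=grid, fitted=spl(grid))


def window_boundaries(fit: SplineFit) -> np.ndarray:
    """Window boundaries: chromosome span ends plus inflection points.

    Inflections are sign changes of the discrete second difference of the
    fitted grid values, placed at the midpoint of the flanking grid cells.
    The returned boundaries are strictly increasing; windows are half-open
    [b_i, b_{i+1}), with the final boundary one past the last grid
    position so the last SNP is covered.
    """
    g, f = fit.grid, fit.fitted
    start, end = g[0], g[-1] + 1
    if len(g) < 4:
        return np.array([start, end])
    d2 = np.diff(f, 2)                     # d2[i] curvature at g[i+1]
    sign = np.sign(d2)
    interior = []
    for i in range(len(d2) - 1):
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            interior.append(0.5 * (g[i + 1] + g[i + 2]))
    bounds = np.array([start, *interior, end])
    return np.unique(bounds)


def wstat(window_bfs: np.ndarray, mu: float, sigma: float) -> float:
    """sqrt(n) * (window mean - mu) / sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    n = len(window_bfs)
    if n == 0:
        raise ValueError("empty window has no score")
    return float(np.sqrt(n) * (np.mean(window_bfs) - mu) / sigma)


def score_windows(
    track: pd.DataFrame,
    grid_bp: int = 10000,
    min_snps_spline: int = 10,
) -> pd.DataFrame:
    """Delimit and score windows for one covariate's genome-wide BF track.

    ``track`` has columns chrom, pos, bf_db. mu/sigma are computed over the
    ENTIRE track (all chromosomes). Chromosomes with fewer than
    ``min_snps_spline`` SNPs become a single whole-chromosome window.
    Returns a window table (chrom, start, end, n_snps, mean_bf, wstat) in
    which windows tile each chromosome's span; windows with no SNPs are
    kept with n_snps = 0 and NaN scores.
    """
    mu = float(track["bf_db"].mean())
    sigma = float(track["bf_db"].std(ddof=0))
    if sigma <= 0:
        warnings.warn("constant BF track: Wstat undefined, reported as NaN")
    rows = []
    for chrom, grp in track.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        bf = grp["bf_db"].to_numpy(dtype=float)
        if len(pos) < min_snps_spline:
            bounds = np.array([pos[0], pos[-1] + 1])
        else:
            fit = fit_spline(pos, bf, grid_bp=grid_bp, chrom=str(chrom))
            bounds = window_boundaries(fit)
        which = np.searchsorted(bounds, pos, side="right") - 1
        for w in range(len(bounds) - 1):
            in_w = which == w
            n = int(in_w.sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start": float(bounds[w]),
                    "end": float(bounds[w + 1]),
                    "n_snps": n,
                    "mean_bf": float(bf[in_w].mean()) if n else np.nan,
                    "wstat": (
                        wstat(bf[in_w], mu, sigma) if n and sigma > 0 else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def outlier_windows(windows: pd.DataFrame, q: float = 0.99) -> pd.DataFrame:
    """Flag windows with Wstat strictly above the empirical q-quantile.

    The quantile is the linear-interpolation (type-7) quantile of all
    scored windows (n_snps >= 1). Returns the input with an ``outlier``
    boolean column.
    """
    scored = windows["n_snps"] >= 1
    n_scored = int(scored.sum())
    if n_scored < 100:
        warnings.warn(
            f"only {n_scored} scored windows; the {q:.0%} quantile is noisy"
        )
    out = windows.copy()
    if n_scored == 0:
        out["outlier"] = False
        return out
    thr = float(np.quantile(out.loc[scored, "wstat"], q))
    out["outlier"] = scored & (out["wstat"] > thr)
    return out
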