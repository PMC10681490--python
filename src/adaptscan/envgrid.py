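"""Environmental predictor extraction and collinearity screening.

Predictor values are read from gridded layers (ESRI ASCII grid format),
averaged over a circular buffer around each sampling location (default
radius 50 km, i.e. a 100 km diameter circle approximating a minimal lynx
home range), assembled into a samples x predictors table, and screened for
collinearity with pairwise Pearson correlation and variance inflation
factors.

Coordinates are planar (km) throughout; synthetic rasters are generated on
projected grids, so Euclidean buffer distances are exact for them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# Raster container and ESRI ASCII grid IO
# --------------------------------------------------------------------------

@dataclass
class Raster:
    """A single rectangular grid layer.

    Row 0 is the NORTHERNMOST row, following the ESRI ASCII convention.
    ``xll``/``yll`` locate the lower-left corner of the grid; cell centers
    are offset by half a cell.
    """

    values: np.ndarray          # (nrows, ncols) float, np.nan marks nodata
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate arrays, each (nrows, ncols)."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def contains(self, x: float, y: float) -> bool:
        return (
            self.xll <= x <= self.xll + self.ncols * self.cellsize
            and self.yll <= y <= self.yll + self.nrows * self.cellsize
        )


def read_asc(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", -9999.0)
    values[values == nodata] = np.nan
    return Raster(
        values=values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=nodata,
    )


def write_asc(raster: Raster, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (.asc)."""
    vals = raster.values.copy()
    vals[np.isnan(vals)] = raster.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:g}\n")
        fh.write(f"yllcorner {raster.yll:g}\n")
        fh.write(f"cellsize {raster.cellsize:g}\n")
        fh.write(f"nodata_value {raster.nodata:g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


# --------------------------------------------------------------------------
# Buffer extraction
# --------------------------------------------------------------------------

class EmptyBufferError(ValueError):
    """No raster cell contributes to a sample's buffer."""


def buffer_mean(
    raster: Raster, x: float, y: float, radius_km: float = 50.0,
    sample: str | None = None,
) -> tuple[float, int]:
    """Mean of non-nodata cells whose centers lie within ``radius_km`` of (x, y).

    Returns ``(mean, n_cells)``. Raises :class:`EmptyBufferError` when no
    cell contributes, naming the offending sample.
    """
    cx, cy = raster.cell_centers()
    inside = (cx - x) ** 2 + (cy - y) ** 2 <= radius_km**2
    vals = raster.values[inside]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        who = f" for sample {sample!r}" if sample else ""
        raise EmptyBufferError(
            f"empty buffer at ({x:g}, {y:g}) radius {radius_km:g} km{who}"
        )
    return float(vals.mean()), int(vals.size)


def extract_predictors(
    rasters: dict[str, Raster],
    meta: pd.DataFrame,
    radius_km: float = 50.0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Buffer-average every raster at every sample location.

    ``meta`` needs columns ``sample_id``, ``x_km``, ``y_km``. Returns a
    samples x predictors DataFrame indexed by sample_id; columns are
    z-scored when ``standardize`` (the default, so ordination loadings and
    spline knots are comparable across predictors).
    """
    out = {}
    for name, raster in rasters.items():
        col = []
        for _, row in meta.iterrows():
            val, _ = buffer_mean(
                raster, float(row["x_km"]), float(row["y_km"]),
                radius_km, sample=str(row["sample_id"]),
            )
            col.append(val)
        out[name] = col
    table = pd.DataFrame(out, index=pd.Index(meta["sample_id"], name="sample_id"))
    if standardize:
        table = standardize_predictors(table)
    return table


def standardize_predictors(table: pd.DataFrame) -> pd.DataFrame:
    sd = table.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance predictor(s): {bad}")
    return (table - table.mean()) / sd


# --------------------------------------------------------------------------
# Collinearity screening
# --------------------------------------------------------------------------

def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Predictor x predictor Pearson correlation matrix."""
    if len(table) < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    sd = table.std(ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance predictor(s): {bad}")
    return table.corr()


def vif(table: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each predictor regressed on all others.

    VIF_j = 1 / (1 - R^2_j); perfect collinearity yields +inf rather than
    an exception.
    """
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    if p == 1:
        return pd.Series([1.0], index=table.columns)
    if n <= p + 1:
        raise ValueError(f"need more samples ({n}) than predictors + 1 ({p + 1})")
    out = {}
    for j, name in enumerate(table.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def collinearity_prune(
    table: pd.DataFrame,
    contributions: pd.Series,
    vif_max: float = 7.0,
    r_max: float = 0.85,
) -> list[str]:
    """Iteratively drop collinear predictors, keeping high contributors.

    While any predictor has VIF > ``vif_max`` or belongs to a pair with
    |r| > ``r_max``, the violating predictor with the LOWEST model
    contribution (adjusted R^2 from forward selection) is removed and the
    diagnostics recomputed.
    """
    kept = list(table.columns)
    while len(kept) > 1:
        sub = table[kept]
        v = vif(sub)
        corr = pearson_matrix(sub).abs()
        np.fill_diagonal(corr.values, 0.0)
        violators = set(v.index[v > vif_max])
        for a in corr.index:
            for b in corr.columns:
                if corr.loc[a, b] > r_max:
                    violators.update([a, b])
        if not violators:
            break
        drop = min(violators, key=lambda name: (contributions.get(name, 0.0), name))
        kept.remove(drop)
    if len(kept) > 1:
        final_vif = vif(table[kept])
        if (final_vif > vif_max).any():  # pragma: no cover - defensive
            warnings.warn("collinearity pruning left a VIF above threshold")
    return kept
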