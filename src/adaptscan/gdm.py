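"""Generalized dissimilarity modelling of genetic turnover.

GDM regresses pairwise genetic dissimilarities d in [0, 1] on differences
of monotone I-spline transforms of site predictors through a negative
exponential link, d_hat = 1 - exp(-eta) with

    eta = a0 + sum_p sum_k beta_pk |I_pk(x_pi) - I_pk(x_pj)|,

all coefficients constrained non-negative so every fitted partial turnover
function f_p(x) = sum_k beta_pk I_pk(x) is monotone non-decreasing.
Coefficients minimize the binomial-form deviance
-2 sum [d log d_hat + (1 - d) log(1 - d_hat)] via iteratively reweighted
non-negative least squares. Predictor importance is the coefficient sum
per predictor (the maximum of its fitted I-spline), rescaled to sum 100.

The fitted turnover functions transform raster layers into "genetic
importance" space; PCA of the transformed stack gives RGB turnover maps,
and Procrustes superimposition of the cell scores of two models (e.g.
neutral vs adaptive) maps their local disagreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import nnls
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from adaptscan.envgrid import Raster

_EPS = 1e-9


# --------------------------------------------------------------------------
# Response and site-pair construction
# --------------------------------------------------------------------------

def genetic_dissimilarity(dosages: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance over dosage rows, scaled so the maximum
    pair maps to 1. All-identical samples yield an all-zero matrix (warn)."""
    X = np.asarray(dosages, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    D = squareform(pdist(X))
    mx = D.max()
    if mx == 0:
        warnings.warn("all samples identical: null response matrix")
        return D
    return D / mx


def build_site_pairs(
    predictors: pd.DataFrame,
    coords: pd.DataFrame,
    d: np.ndarray,
) -> pd.DataFrame:
    """Site-pair table: response dissimilarity, both sites' predictor
    values, and planar geographic distance (km).

    ``predictors`` is samples x predictors; ``coords`` needs x_km, y_km
    aligned with it; ``d`` is the square dissimilarity matrix.
    """
    n = len(predictors)
    if d.shape != (n, n):
        raise ValueError("dissimilarity matrix does not match predictor rows")
    xy = coords[["x_km", "y_km"]].to_numpy(dtype=float)
    rows = []
    P = predictors.to_numpy(dtype=float)
    names = list(predictors.columns)
    for i in range(n):
        for j in range(i + 1, n):
            rec = {"d": float(d[i, j])}
            for k, name in enumerate(names):
                rec[f"{name}_i"] = P[i, k]
                rec[f"{name}_j"] = P[j, k]
            rec["geo_km"] = float(np.hypot(*(xy[i] - xy[j])))
            rows.append(rec)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# I-spline basis
# --------------------------------------------------------------------------

def ispline_basis(
    x: np.ndarray, knots: tuple[float, float, float], K: int = 3
) -> np.ndarray:
    """Order-2 (piecewise-quadratic) monotone I-spline basis values.

    ``knots`` are the (min, median, max) of the predictor. Each of the K=3
    basis functions runs from 0 at the low end of its support to 1 at the
    high end; x outside [min, max] is clamped. I-splines are computed as
    upper partial sums of degree-2 B-splines on the open knot vector.
    Degenerate knots (all equal) give an all-zero basis with a warning.
    """
    if K != 3:
        raise NotImplementedError("K=3 I-splines (min/median/max knots) only")
    q0, q50, q100 = knots
    if not (q0 <= q50 <= q100):
        raise ValueError("knots must be non-decreasing")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if q0 == q100:
        warnings.warn("degenerate knots: zero basis")
        return np.zeros((len(x), K))
    if q50 <= q0:
        q50 = q0 + (q100 - q0) * 1e-6
    if q50 >= q100:
        q50 = q100 - (q100 - q0) * 1e-6
    t = np.array([q0, q0, q0, q50, q100, q100, q100])
    xc = np.clip(x, q0, q100)
    nb = len(t) - 2 - 1  # 4 degree-2 B-splines
    B = np.empty((len(xc), nb))
    for m in range(nb):
        c = np.zeros(nb)
        c[m] = 1.0
        B[:, m] = BSpline(t, c, 2, extrapolate=False)(xc)
    B = np.nan_to_num(B)
    # right edge: B-splines at x == q100 sum to 1 via the last basis
    B[xc == q100, -1] = 1.0
    out = np.empty((len(xc), K))
    for j in range(1, K + 1):
        out[:, j - 1] = B[:, j:].sum(axis=1)
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------------------
# GDM estimator
# --------------------------------------------------------------------------

@dataclass
class ProcrustesResult:
    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    residuals: np.ndarray
    sum_squared_residuals: float


class GDM(BaseEstimator):
    """Generalized dissimilarity model (scikit-learn style estimator).

    Parameters
    ----------
    n_splines : int
        I-splines per predictor (3, with knots at min/median/max).
    max_iter, tol : IRLS stopping rule (deviance change below ``tol``).
    importance_rescale : "sum" rescales importances to sum 100 (default);
        "max" rescales the largest to 100.

    Fitted attributes: ``intercept_``, ``coefs_`` (predictor -> (K,)
    non-negative array), ``knots_``, ``deviance_``, ``null_deviance_``,
    ``deviance_explained_`` (percent), ``importance_`` (Series),
    ``converged_``.
    """

    def __init__(
        self,
        n_splines: int = 3,
        max_iter: int = 500,
        tol: float = 1e-8,
        importance_rescale: str = "sum",
    ):
        self.n_splines = n_splines
        self.max_iter = max_iter
        self.tol = tol
        self.importance_rescale = importance_rescale

    # -- design matrix ------------------------------------------------
    def _design(
        self, pairs: pd.DataFrame, predictors: list[str]
    ) -> np.ndarray:
        cols = []
        for name in predictors:
            xi = pairs[f"{name}_i"].to_numpy(dtype=float)
            xj = pairs[f"{name}_j"].to_numpy(dtype=float)
            knots = self.knots_[name]
            cols.append(
                np.abs(
                    ispline_basis(xi, knots, self.n_splines)
                    - ispline_basis(xj, knots, self.n_splines)
                )
            )
        return np.hstack(cols)

    @staticmethod
    def _pair_predictors(pairs: pd.DataFrame) -> list[str]:
        names = []
        for col in pairs.columns:
            if col.endswith("_i") and f"{col[:-2]}_j" in pairs.columns:
                names.append(col[:-2])
        if "geo_km" in pairs.columns and "geo_km" not in names:
            names.append("geo_km")
        return names

    def fit(self, pairs: pd.DataFrame, y=None) -> "GDM":
        pairs = pairs.copy()
        if "geo_km" in pairs.columns and "geo_km_i" not in pairs.columns:
            # geographic distance enters as a one-sided I-spline set
            pairs["geo_km_i"] = 0.0
            pairs["geo_km_j"] = pairs["geo_km"]
        predictors = self._pair_predictors(pairs)
        d = np.clip(pairs["d"].to_numpy(dtype=float), 0.0, 1.0 - _EPS)
        n_pairs = len(d)
        n_coef = 1 + len(predictors) * self.n_splines
        if n_pairs < n_coef + 1:
            raise ValueError(
                f"need at least {n_coef + 1} pairs, got {n_pairs}"
            )
        self.knots_ = {}
        for name in predictors:
            vals = np.concatenate(
                [pairs[f"{name}_i"], pairs[f"{name}_j"]]
            ).astype(float)
            self.knots_[name] = (
                float(vals.min()), float(np.median(vals)), float(vals.max())
            )
        X = np.column_stack([np.ones(n_pairs), self._design(pairs, predictors)])

        beta = self._irls(X, d)
        self.predictors_ = predictors
        self.intercept_ = float(beta[0])
        self.coefs_ = {
            name: beta[1 + i * self.n_splines: 1 + (i + 1) * self.n_splines]
            for i, name in enumerate(predictors)
        }
        self.deviance_ = self._deviance(d, self._eta(X, beta))

        beta0 = self._irls(np.ones((n_pairs, 1)), d)
        self.null_deviance_ = self._deviance(
            d, np.full(n_pairs, float(beta0[0]))
        )
        self.deviance_explained_ = 100.0 * (
            1.0 - self.deviance_ / self.null_deviance_
        ) if self.null_deviance_ > 0 else 0.0

        raw = pd.Series(
            {name: float(self.coefs_[name].sum()) for name in predictors}
        )
        total = raw.sum()
        if self.importance_rescale == "max" and raw.max() > 0:
            self.importance_ = 100.0 * raw / raw.max()
        else:
            self.importance_ = (
                100.0 * raw / total if total > 0 else raw * 0.0
            )
        return self

    @staticmethod
    def _eta(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
        return X @ beta

    @staticmethod
    def _deviance(d: np.ndarray, eta: np.ndarray) -> float:
        """Binomial-form deviance 2 sum[d log(d/mu) + (1-d) log((1-d)/(1-mu))]
        with 0 log 0 := 0; zero for a saturated fit."""
        mu = np.clip(1.0 - np.exp(-np.clip(eta, 0.0, None)), _EPS, 1.0 - _EPS)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(d > 0, d * np.log(d / mu), 0.0)
            t2 = np.where(d < 1, (1.0 - d) * np.log((1.0 - d) / (1.0 - mu)), 0.0)
        return float(2.0 * (t1 + t2).sum())

    def _irls(self, X: np.ndarray, d: np.ndarray) -> np.ndarray:
        n = len(d)
        beta = np.zeros(X.shape[1])
        beta[0] = max(-np.log(1.0 - np.clip(d.mean(), _EPS, 1 - _EPS)), _EPS)
        dev = self._deviance(d, self._eta(X, beta))
        self.converged_ = False
        for _ in range(self.max_iter):
            eta = np.clip(self._eta(X, beta), _EPS, 50.0)
            mu = np.clip(1.0 - np.exp(-eta), _EPS, 1.0 - _EPS)
            dmu = 1.0 - mu                       # d mu / d eta = exp(-eta)
            var = mu * (1.0 - mu)
            w = dmu**2 / np.maximum(var, _EPS)
            zwork = eta + (d - mu) / np.maximum(dmu, _EPS)
            sw = np.sqrt(w)
            beta_new, _ = nnls(X * sw[:, None], zwork * sw)
            dev_new = self._deviance(d, self._eta(X, beta_new))
            if dev_new > dev + 1e-12:
                # step-halve toward the previous iterate
                for _ in range(20):
                    beta_new = 0.5 * (beta_new + beta)
                    dev_new = self._deviance(d, self._eta(X, beta_new))
                    if dev_new <= dev:
                        break
            change = dev - dev_new
            beta = beta_new
            if abs(change) < self.tol:
                dev = dev_new
                self.converged_ = True
                break
            dev = dev_new
        if not self.converged_:
            warnings.warn("GDM IRLS did not converge; best iterate returned")
        return beta

    # -- prediction / transformation ----------------------------------
    def predict(self, pairs: pd.DataFrame) -> np.ndarray:
        pairs = pairs.copy()
        if "geo_km" in pairs.columns and "geo_km_i" not in pairs.columns:
            pairs["geo_km_i"] = 0.0
            pairs["geo_km_j"] = pairs["geo_km"]
        X = np.column_stack(
            [np.ones(len(pairs)), self._design(pairs, self.predictors_)]
        )
        beta = np.concatenate(
            [[self.intercept_]] + [self.coefs_[n] for n in self.predictors_]
        )
        return 1.0 - np.exp(-np.clip(X @ beta, 0.0, None))

    def partial_function(self, name: str, x: np.ndarray) -> np.ndarray:
        """Fitted monotone turnover function f(x) = sum_k beta_k I_k(x)."""
        basis = ispline_basis(
            np.asarray(x, dtype=float).ravel(), self.knots_[name], self.n_splines
        )
        return basis @ self.coefs_[name]


def fit_gdm(pairs: pd.DataFrame, K: int = 3, **kwargs) -> GDM:
    """Functional wrapper over :class:`GDM`."""
    return GDM(n_splines=K, **kwargs).fit(pairs)


# --------------------------------------------------------------------------
# Raster transformation, RGB composition, Procrustes
# --------------------------------------------------------------------------

def transform_rasters(
    model: GDM, rasters: dict[str, Raster]
) -> dict[str, Raster]:
    """Map each predictor layer through its fitted partial turnover function.

    Geography ('geo_km') is mapped from coordinates: the x and y center
    grids, as distance from the grid origin per axis, each pass through
    the geographic spline and come back as separate layers geo_x / geo_y
    (a documented approximation for mapping a distance-based predictor).
    """
    out: dict[str, Raster] = {}
    env_names = [n for n in model.predictors_ if n != "geo_km"]
    for name in env_names:
        if name not in rasters:
            raise KeyError(f"no raster provided for predictor {name!r}")
        r = rasters[name]
        vals = r.values.copy()
        ok = ~np.isnan(vals)
        new = np.full_like(vals, np.nan)
        new[ok] = model.partial_function(name, vals[ok])
        out[name] = Raster(
            values=new, xll=r.xll, yll=r.yll, cellsize=r.cellsize,
            nodata=r.nodata,
        )
    if "geo_km" in model.predictors_:
        ref = next(iter(rasters.values()))
        cx, cy = ref.cell_centers()
        for label, grid in (("geo_x", cx), ("geo_y", cy)):
            dist = grid - grid.min()
            new = model.partial_function("geo_km", dist.ravel()).reshape(
                dist.shape
            )
            out[label] = Raster(
                values=new, xll=ref.xll, yll=ref.yll,
                cellsize=ref.cellsize, nodata=ref.nodata,
            )
    return out


def pca_rgb(
    stack: dict[str, Raster]
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """First three PCs of the transformed stack as an RGB image.

    Returns (rgb uint8 (H, W, 4) with alpha 0 at nodata, loadings
    DataFrame (layers x PCs), scores (n_valid_cells, 3)). Channels are
    min-max scaled to [0, 255]; with fewer than three informative
    components the trailing channels are zero-padded (warned).
    """
    names = list(stack.keys())
    if len(names) < 3:
        warnings.warn("fewer than 3 layers: trailing RGB channels padded")
    ref = stack[names[0]]
    flat = np.column_stack([stack[n].values.ravel() for n in names])
    valid = ~np.isnan(flat).any(axis=1)
    X = flat[valid]
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_comp = int((s > 1e-12 * max(s[0], 1.0)).sum())
    if n_comp < 3:
        warnings.warn(f"only {n_comp} informative component(s); padding")
    scores = np.zeros((X.shape[0], 3))
    take = min(3, n_comp)
    scores[:, :take] = U[:, :take] * s[:take]
    loadings = pd.DataFrame(
        Vt[:take].T, index=names, columns=[f"PC{i + 1}" for i in range(take)]
    )
    rgb = np.zeros((flat.shape[0], 4), dtype=np.uint8)
    for c in range(3):
        col = scores[:, c]
        rng_ = col.max() - col.min()
        scaled = (col - col.min()) / rng_ * 255.0 if rng_ > 0 else np.zeros_like(col)
        rgb[valid, c] = np.round(scaled).astype(np.uint8)
    rgb[valid, 3] = 255
    return rgb.reshape(ref.nrows, ref.ncols, 4), loadings, scores


def save_rgb_png(rgb: np.ndarray, path) -> None:
    """Write an (H, W, 4) uint8 RGBA turnover map as a PNG."""
    import matplotlib.image

    matplotlib.image.imsave(str(path), rgb)


def procrustes_residuals(
    cells_a: np.ndarray, cells_b: np.ndarray
) -> ProcrustesResult:
    """Optimal translation + rotation + isotropic scaling of B onto A.

    Closed-form orthogonal Procrustes via SVD of the cross-covariance;
    the per-location residual is the Euclidean distance after alignment.
    """
    A = np.asarray(cells_a, dtype=float)
    B = np.asarray(cells_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - mu_a, B - mu_b
    C = B0.T @ A0
    U, s, Vt = np.linalg.svd(C)
    R = U @ Vt
    denom = float((B0**2).sum())
    scale = float(s.sum()) / denom if denom > 0 else 1.0
    aligned = scale * (B0 @ R) + mu_a
    resid = np.linalg.norm(A - aligned, axis=1)
    return ProcrustesResult(
        rotation=R,
        scale=scale,
        translation=mu_a - scale * (mu_b @ R),
        residuals=resid,
        sum_squared_residuals=float((resid**2).sum()),
    )
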