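"""Constrained ordination: RDA, partial RDA, permutation tests, forward
selection, variance partitioning and SNP outlier detection.

Redundancy analysis regresses a multivariate response (here centered SNP
dosages, samples x SNPs) on a predictor matrix, optionally after removing
the effect of conditioning covariates (partial RDA), and eigendecomposes
the fitted values. Axis significance uses an ANOVA-like permutation test
in which rows of the reduced-model residuals are permuted; forward
selection adds predictors by adjusted-R^2 gain with a permutation stopping
rule; variance partitioning contrasts pure-climate / pure-geography /
pure-structure partial models against the full model.

SNP loadings are unit-norm right singular vectors of the fitted values
(response weights); the sign of each axis is fixed so the largest-|loading|
SNP is positive. Outliers are SNPs whose loading lies more than k standard
deviations (default 3) from the axis mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray        # constrained, non-increasing, variance units
    loadings: np.ndarray           # SNPs x axes, unit-norm columns
    sample_scores: np.ndarray      # samples x axes
    r2: float
    adj_r2: float
    total_variance: float          # var of centered response
    conditioned_variance: float
    constrained_variance: float
    residual_variance: float
    rank: int
    n_samples: int
    n_predictors: int


@dataclass
class AxisTest:
    pseudo_f: np.ndarray
    p_values: np.ndarray
    n_perm: int


@dataclass
class VariancePartition:
    full_adj_r2: float
    pure: dict[str, float]                 # adjusted R^2 fractions of total
    confounded: float
    pure_of_explainable: dict[str, float]
    confounded_of_explainable: float
    p_values: dict[str, float] = field(default_factory=dict)
    negative_confounded: bool = False


def _as_2d(M) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    return M


def mean_impute(Y: np.ndarray) -> np.ndarray:
    """Replace missing dosages with the per-SNP (column) mean."""
    Y = np.asarray(Y, dtype=float)
    if not np.isnan(Y).any():
        return Y
    col_mean = np.nanmean(Y, axis=0)
    idx = np.where(np.isnan(Y))
    Y = Y.copy()
    Y[idx] = np.take(col_mean, idx[1])
    return Y


def _residualize(M: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Residuals of M after OLS on [1, C]."""
    n = M.shape[0]
    if C is None or C.shape[1] == 0:
        return M - M.mean(axis=0)
    D = np.column_stack([np.ones(n), C])
    coef, *_ = np.linalg.lstsq(D, M, rcond=None)
    return M - D @ coef


def _orthobasis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank-revealing SVD)."""
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > _RANK_TOL * max(s[0], 1.0)).sum()) if s.size else 0
    return U[:, :rank]


class RDA(BaseEstimator):
    """Redundancy analysis estimator (scikit-learn style).

    Parameters
    ----------
    scale : bool
        Scale response columns to unit variance after centering. Off by
        default so allele-frequency-scale variance is retained.
    n_axes : int or None
        Number of constrained axes kept (default: full rank).

    The response Y (samples x SNPs) is mean-imputed and centered; Y and the
    predictors X are residualized on [1, Z] when conditioning variables Z
    are given; the constrained axes are the singular directions of the
    fitted values of the OLS regression of the residualized Y on the
    residualized X.
    """

    def __init__(self, scale: bool = False, n_axes: int | None = None):
        self.scale = scale
        self.n_axes = n_axes

    def fit(self, X, Y, Z=None) -> "RDA":
        X = _as_2d(X)
        Y = mean_impute(_as_2d(Y))
        Z = None if Z is None else _as_2d(Z)
        n = Y.shape[0]
        n_cond = 0 if Z is None else Z.shape[1]
        if n <= X.shape[1] + n_cond + 1:
            raise ValueError(
                f"too few samples ({n}) for {X.shape[1]} predictors "
                f"+ {n_cond} conditioners"
            )
        Yc = Y - Y.mean(axis=0)
        if self.scale:
            sd = Yc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Yc = Yc / sd
        total_var = float((Yc**2).sum()) / (n - 1)

        Yr = _residualize(Yc, Z)
        Xr = _residualize(X, Z)
        cond_var = total_var - float((Yr**2).sum()) / (n - 1)

        Q = _orthobasis(Xr)
        rank = Q.shape[1]
        if rank < X.shape[1]:
            logger.warning(
                "rank-deficient predictors after conditioning: rank %d < %d",
                rank, X.shape[1],
            )
        Yhat = Q @ (Q.T @ Yr)
        U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
        k = min(rank, (s > _RANK_TOL * max(s[0] if s.size else 1.0, 1.0)).sum())
        if self.n_axes is not None:
            k = min(k, self.n_axes)
        k = max(k, 0)
        U, s, Vt = U[:, :k], s[:k], Vt[:k]

        # deterministic axis orientation: largest-|loading| SNP positive
        for a in range(k):
            imax = np.argmax(np.abs(Vt[a]))
            if Vt[a, imax] < 0:
                Vt[a] = -Vt[a]
                U[:, a] = -U[:, a]

        ss_fit = float((s**2).sum())
        ss_res_total = float((Yr**2).sum())
        self.eigenvalues_ = s**2 / (n - 1)
        self.loadings_ = Vt.T
        self.sample_scores_ = U * s
        self.r2_ = ss_fit / ss_res_total if ss_res_total > 0 else 0.0
        self.rank_ = rank
        self.n_samples_ = n
        self.n_predictors_ = X.shape[1]
        self.total_variance_ = total_var
        self.conditioned_variance_ = cond_var
        self.constrained_variance_ = ss_fit / (n - 1)
        self.residual_variance_ = (
            total_var - cond_var - self.constrained_variance_
        )
        self.adj_r2_ = adjusted_r2(self.r2_, n - n_cond, rank)
        return self

    def transform(self, Y) -> np.ndarray:
        """Project (centered, imputed) new response rows onto the axes."""
        Y = mean_impute(_as_2d(Y))
        return (Y - Y.mean(axis=0)) @ self.loadings_

    def result(self) -> OrdinationResult:
        return OrdinationResult(
            eigenvalues=self.eigenvalues_,
            loadings=self.loadings_,
            sample_scores=self.sample_scores_,
            r2=self.r2_,
            adj_r2=self.adj_r2_,
            total_variance=self.total_variance_,
            conditioned_variance=self.conditioned_variance_,
            constrained_variance=self.constrained_variance_,
            residual_variance=self.residual_variance_,
            rank=self.rank_,
            n_samples=self.n_samples_,
            n_predictors=self.n_predictors_,
        )


def rda_fit(Y, X, Z=None, scale: bool = False) -> OrdinationResult:
    """Functional wrapper over :class:`RDA`."""
    return RDA(scale=scale).fit(X, Y, Z=Z).result()


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel-corrected R^2: 1 - (1 - R^2)(n - 1)/(n - p - 1).

    May be negative; errors when n <= p + 1.
    """
    if n <= p + 1:
        raise ValueError(f"n={n} must exceed p+1={p + 1}")
    if p == 0:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


# --------------------------------------------------------------------------
# Permutation tests
# --------------------------------------------------------------------------

def _first_eig_stats(
    Yr: np.ndarray, Q: np.ndarray
) -> tuple[float, float]:
    """(first eigenvalue*(n-1), residual SS) of the projection of Yr on Q.

    Works in the small p x p Gram space: the nonzero eigenvalues of
    (Q B)(Q B)^T equal those of B B^T for orthonormal Q.
    """
    B = Q.T @ Yr
    G = B @ B.T
    lam1 = float(np.linalg.eigvalsh(G)[-1])
    rss = float((Yr**2).sum()) - float(np.trace(G))
    return lam1, rss


def anova_axes(
    Y,
    X,
    Z=None,
    n_perm: int = 100,
    seed: int | np.random.Generator | None = 0,
    alpha_stop: float | None = None,
    max_axes: int | None = None,
) -> AxisTest:
    """Sequential ANOVA-like permutation test of constrained axes.

    Axis k is tested with previously tested axes added to the conditioning
    set; the pseudo-F compares the axis eigenvalue to the residual variance
    of the model, and the null distribution is built by permuting rows of
    the reduced-model residuals of Y. ``alpha_stop`` stops testing at the
    first non-significant axis (its p-value is still reported).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    X = _as_2d(X)
    Y = mean_impute(_as_2d(Y))
    Y = Y - Y.mean(axis=0)
    Z = None if Z is None else _as_2d(Z)
    n = Y.shape[0]

    fit = RDA().fit(X, Y, Z=Z)
    k_total = len(fit.eigenvalues_)
    if max_axes is not None:
        k_total = min(k_total, max_axes)
    fs, ps = [], []
    for k in range(k_total):
        cond_parts = [] if Z is None else [Z]
        if k > 0:
            cond_parts.append(fit.sample_scores_[:, :k])
        C = np.column_stack(cond_parts) if cond_parts else None
        Yr = _residualize(Y, C)
        Xr = _residualize(X, C)
        Q = _orthobasis(Xr)
        ncond = 0 if C is None else np.linalg.matrix_rank(C)
        df_res = n - 1 - ncond - Q.shape[1]
        if df_res <= 0 or Q.shape[1] == 0:
            fs.append(np.nan)
            ps.append(np.nan)
            continue
        lam_obs, rss_obs = _first_eig_stats(Yr, Q)
        f_obs = lam_obs / (rss_obs / df_res) if rss_obs > 0 else np.inf
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            lam_p, rss_p = _first_eig_stats(Yr[perm], Q)
            f_p = lam_p / (rss_p / df_res) if rss_p > 0 else np.inf
            if f_p >= f_obs:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
        fs.append(f_obs)
        ps.append(p)
        if alpha_stop is not None and p > alpha_stop:
            break
    return AxisTest(
        pseudo_f=np.array(fs), p_values=np.array(ps), n_perm=n_perm
    )


def significant_axes(test: AxisTest, alpha: float = 0.05) -> np.ndarray:
    p = np.nan_to_num(test.p_values, nan=1.0)
    return np.flatnonzero(p <= alpha)


def forward_select(
    Y,
    candidates: pd.DataFrame,
    p_thresh: float = 0.01,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Forward selection of predictors by adjusted-R^2 gain.

    At each step the candidate maximizing model adjusted R^2 is entered;
    selection stops when the best candidate's permutation p-value for the
    added term is >= ``p_thresh``, or once the selected model's adjusted
    R^2 reaches that of the global model containing all candidates (the
    scope ceiling: any further addition would exceed it). Returns the
    selection path with per-step adjusted R^2 and p-values.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate predictor")
    Y = mean_impute(_as_2d(Y))
    Y = Y - Y.mean(axis=0)
    n = Y.shape[0]
    names = list(candidates.columns)
    Xall = candidates.to_numpy(dtype=float)
    global_adj = rda_fit(Y, Xall).adj_r2

    selected: list[str] = []
    path = []
    current_adj = 0.0
    while set(selected) != set(names):
        # scope ceiling: once the model matches the all-candidate adjusted
        # R^2, further additions would only overfit past the global model
        if selected and current_adj >= global_adj - 1e-12:
            break
        remaining = [c for c in names if c not in selected]
        best_name, best_adj = None, -np.inf
        for c in remaining:
            cols = candidates[selected + [c]].to_numpy(dtype=float)
            adj = rda_fit(Y, cols).adj_r2
            if adj > best_adj:
                best_adj, best_name = adj, c
        Xsel = (
            candidates[selected].to_numpy(dtype=float) if selected else None
        )
        Yr = _residualize(Y, Xsel)
        xr = _residualize(
            candidates[[best_name]].to_numpy(dtype=float), Xsel
        )
        q = _orthobasis(xr)
        if q.shape[1] == 0:
            break  # candidate is collinear with the current model
        tot = float((Yr**2).sum())
        num_obs = float(((q.T @ Yr) ** 2).sum())
        perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
        qp = q[:, 0][perm_idx]                       # (n_perm, n)
        num_perm = ((qp @ Yr) ** 2).sum(axis=1)
        df = n - 1 - (0 if Xsel is None else Xsel.shape[1]) - 1
        f_obs = num_obs / ((tot - num_obs) / df)
        f_perm = num_perm / ((tot - num_perm) / df)
        p = (1.0 + (f_perm >= f_obs).sum()) / (1.0 + n_perm)
        if p >= p_thresh:
            break
        selected.append(best_name)
        current_adj = best_adj
        path.append({"predictor": best_name, "adj_r2": best_adj, "p": p})
    return pd.DataFrame(path, columns=["predictor", "adj_r2", "p"])


# --------------------------------------------------------------------------
# Variance partitioning
# --------------------------------------------------------------------------

def _model_adj_r2(Y: np.ndarray, blocks: list[np.ndarray]) -> float:
    X = np.column_stack(blocks)
    return rda_fit(Y, X).adj_r2


def prda_significance(
    Y, X, Z, n_perm: int = 99,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Overall permutation test of a partial model (all axes jointly)."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    Y = mean_impute(_as_2d(Y))
    Y = Y - Y.mean(axis=0)
    X, Z = _as_2d(X), _as_2d(Z)
    n = Y.shape[0]
    Yr = _residualize(Y, Z)
    Xr = _residualize(X, Z)
    Q = _orthobasis(Xr)
    df_res = n - 1 - np.linalg.matrix_rank(Z) - Q.shape[1]
    if Q.shape[1] == 0 or df_res <= 0:
        return 1.0
    tot = float((Yr**2).sum())

    def stat(Ym):
        fit_ss = float(((Q.T @ Ym) ** 2).sum())
        rss = float((Ym**2).sum()) - fit_ss
        return (fit_ss / Q.shape[1]) / (rss / df_res)

    f_obs = stat(Yr)
    exceed = sum(
        stat(Yr[rng.permutation(n)]) >= f_obs for _ in range(n_perm)
    )
    return (1.0 + exceed) / (1.0 + n_perm)


def variance_partition(
    Y,
    env,
    geo,
    struct,
    n_perm: int = 99,
    seed: int | np.random.Generator | None = 0,
) -> VariancePartition:
    """Partition response variance into pure climate / geography /
    structure fractions plus a confounded remainder.

    The pure fraction of a component is the adjusted R^2 of the full model
    minus that of the model omitting the component (equivalently, the
    semipartial contribution of the partial model conditioning on the
    other two); confounded = full - sum(pure) and may be negative with
    collinear components (reported and flagged, not an error).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    Y = mean_impute(_as_2d(Y))
    Y = Y - Y.mean(axis=0)
    blocks = {"env": _as_2d(env), "geo": _as_2d(geo), "struct": _as_2d(struct)}
    for name, B in blocks.items():
        if B.shape[1] == 0:
            raise ValueError(f"component {name!r} is empty")
    full = _model_adj_r2(Y, list(blocks.values()))
    pure, pvals = {}, {}
    for name in blocks:
        others = [blocks[k] for k in blocks if k != name]
        pure[name] = full - _model_adj_r2(Y, others)
        pvals[name] = prda_significance(
            Y, blocks[name], np.column_stack(others), n_perm=n_perm, seed=rng
        )
    confounded = full - sum(pure.values())
    denom = full if full != 0 else np.nan
    return VariancePartition(
        full_adj_r2=full,
        pure=pure,
        confounded=confounded,
        pure_of_explainable={k: v / denom for k, v in pure.items()},
        confounded_of_explainable=confounded / denom,
        p_values=pvals,
        negative_confounded=confounded < 0,
    )


# --------------------------------------------------------------------------
# Outlier SNPs
# --------------------------------------------------------------------------

def outlier_snps(
    result: OrdinationResult,
    axes: np.ndarray | list[int],
    dosages: np.ndarray | None = None,
    predictors: pd.DataFrame | None = None,
    k_sd: float = 3.0,
) -> pd.DataFrame:
    """SNPs whose loading on a significant axis deviates more than
    ``k_sd`` standard deviations from the axis mean.

    Returns one row per (SNP, axis) with the loading, its deviation in SD
    units, and — when dosages and a predictor table are supplied — the
    predictor most correlated with the SNP. A SNP flagged on several axes
    keeps all rows; use :func:`assign_outlier_axis` for a unique
    per-SNP axis.
    """
    rows = []
    for a in np.asarray(axes, dtype=int):
        load = result.loadings[:, a]
        mu, sd = load.mean(), load.std(ddof=0)
        if sd == 0:
            continue
        dev = (load - mu) / sd
        for snp in np.flatnonzero(np.abs(dev) >= k_sd):
            rows.append(
                {
                    "snp_idx": int(snp), "axis": int(a),
                    "loading": float(load[snp]), "sd_units": float(dev[snp]),
                }
            )
    out = pd.DataFrame(rows, columns=["snp_idx", "axis", "loading", "sd_units"])
    if len(out) and dosages is not None and predictors is not None:
        P = predictors.to_numpy(dtype=float)
        Pz = (P - P.mean(axis=0)) / P.std(axis=0, ddof=0)
        names = list(predictors.columns)
        best = []
        for snp in out["snp_idx"]:
            g = dosages[:, snp]
            g = np.where(np.isnan(g), np.nanmean(g), g)
            gz = g - g.mean()
            sd = gz.std(ddof=0)
            if sd == 0:
                best.append(names[0])
                continue
            corr = np.abs(Pz.T @ (gz / sd)) / len(g)
            best.append(names[int(np.argmax(corr))])
        out["predictor"] = best
    return out


def assign_outlier_axis(outliers: pd.DataFrame) -> pd.DataFrame:
    """One row per SNP: the axis with the largest |sd_units|."""
    if not len(outliers):
        return outliers
    idx = (
        outliers.assign(absdev=outliers["sd_units"].abs())
        .sort_values(["absdev"], ascending=False)
        .drop_duplicates("snp_idx")
        .drop(columns="absdev")
    )
    return idx.sort_values("snp_idx").reset_index(drop=True)
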