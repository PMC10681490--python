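"""Adaptive versus neutral population structure.

Genotype PCA (SVD of the centered dosage matrix), broken-stick component
retention, and per-sample-pair differences between Euclidean distances
computed on equally sized adaptive and neutral SNP sets. Negative deltas
mark pairs that are more similar at adaptive loci than their neutral
background would suggest.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from adaptscan.rda import mean_impute


@dataclass
class PcaResult:
    scores: np.ndarray        # samples x components
    eigenvalues: np.ndarray   # non-increasing, >= 0
    percent_variance: np.ndarray


def genotype_pca(
    dosages: np.ndarray, center: bool = True, scale: bool = False
) -> PcaResult:
    """PCA of a samples x SNPs dosage matrix via SVD.

    Scores are left singular vectors scaled by singular values; each axis
    is oriented so its largest-|score| sample is positive.
    """
    X = mean_impute(np.asarray(dosages, dtype=float))
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need at least 2 samples and 1 SNP")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    if not np.any(X):
        raise ValueError("zero-variance matrix")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    eig = s**2 / (n - 1)
    scores = U * s
    for a in range(scores.shape[1]):
        imax = np.argmax(np.abs(scores[:, a]))
        if scores[imax, a] < 0:
            scores[:, a] = -scores[:, a]
    pct = 100.0 * eig / eig.sum()
    return PcaResult(scores=scores, eigenvalues=eig, percent_variance=pct)


def broken_stick(eigenvalues: np.ndarray) -> int:
    """Leading components whose variance proportion exceeds the broken-stick
    expectation b_i = (1/m) sum_{j=i..m} 1/j, stopping at the first failure."""
    eig = np.asarray(eigenvalues, dtype=float)
    if len(eig) < 2:
        raise ValueError("need at least 2 eigenvalues")
    m = len(eig)
    props = eig / eig.sum()
    b = np.array([np.sum(1.0 / np.arange(i, m + 1)) / m for i in range(1, m + 1)])
    keep = 0
    for i in range(m):
        if props[i] > b[i]:
            keep += 1
        else:
            break
    return keep


def distance_deltas(
    dosages: np.ndarray,
    adaptive_idx: np.ndarray,
    neutral_idx: np.ndarray,
    pop_labels: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Per sample pair: Euclidean distance on adaptive and neutral SNP
    subsets (dosage space) and their difference.

    The two subsets must be the same size so the distances are comparable.
    Returns one row per unordered pair with columns sample_i, sample_j,
    pop_i, pop_j, d_adaptive, d_neutral, delta.
    """
    adaptive_idx = np.asarray(adaptive_idx)
    neutral_idx = np.asarray(neutral_idx)
    if len(adaptive_idx) != len(neutral_idx):
        raise ValueError(
            f"set sizes differ: {len(adaptive_idx)} adaptive vs "
            f"{len(neutral_idx)} neutral"
        )
    X = mean_impute(np.asarray(dosages, dtype=float))
    d_a = squareform(pdist(X[:, adaptive_idx]))
    d_n = squareform(pdist(X[:, neutral_idx]))
    pops = np.asarray(pop_labels)
    rows = []
    for i, j in combinations(range(X.shape[0]), 2):
        rows.append(
            {
                "sample_i": i, "sample_j": j,
                "pop_i": pops[i], "pop_j": pops[j],
                "d_adaptive": d_a[i, j], "d_neutral": d_n[i, j],
                "delta": d_a[i, j] - d_n[i, j],
            }
        )
    return pd.DataFrame(rows)


def pair_delta_summary(deltas: pd.DataFrame) -> pd.DataFrame:
    """Median delta per unordered population pair."""
    key = deltas.apply(
        lambda r: tuple(sorted((r["pop_i"], r["pop_j"]))), axis=1
    )
    out = (
        deltas.assign(pair=key)
        .groupby("pair")["delta"]
        .median()
        .reset_index()
        .rename(columns={"delta": "median_delta"})
    )
    return out
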