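"""GO-term over-/under-representation of candidate genes.

Candidate windows (extended by 20 kbp flanks) are crossed with gene spans;
each GO term is tested with hypergeometric tail probabilities against a
universe of annotated genes, reporting the expected count n*K/N, fold
enrichment k/expected, raw p-values for both directions and
Benjamini-Hochberg FDR per direction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def windows_to_genes(
    windows: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 20000
) -> list[str]:
    """Genes whose 1-based closed span intersects any window extended by
    ``flank_bp`` on each side; deduplicated, input order preserved."""
    found: list[str] = []
    seen: set[str] = set()
    for _, g in genes.iterrows():
        sub = windows[windows["chrom"] == g["chrom"]]
        if not len(sub):
            continue
        lo = sub["start"].to_numpy(dtype=float) - flank_bp
        hi = sub["end"].to_numpy(dtype=float) + flank_bp
        if np.any((g["start"] <= hi) & (g["end"] >= lo)):
            if g["gene_id"] not in seen:
                seen.add(g["gene_id"])
                found.append(g["gene_id"])
    return found


def expected_and_fold(
    reference: int, observed: int, sampling_fraction: float
) -> tuple[float, float]:
    """Worked-example arithmetic of an over-representation table row.

    ``expected`` = reference * sampling_fraction (the fraction n/N of the
    universe that the input list represents, obtainable from the root
    row's Expected/Reference ratio); ``fold`` = observed / expected.
    """
    expected = reference * sampling_fraction
    return expected, observed / expected


def enrichment_test(
    sample_genes: list[str] | set[str],
    annotation: pd.DataFrame,
    universe: list[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over- and under-representation per GO term.

    ``annotation`` maps gene_id -> go_id (one row per pair). The universe
    defaults to all annotated genes; sample genes outside the universe are
    dropped with a warning. For each term with K genes in the universe and
    k in the n sample genes drawn from N: expected = n K / N,
    fold = k / expected, p_over = P(X >= k), p_under = P(X <= k) for
    X ~ Hypergeometric(N, K, n); BH FDR is applied separately per
    direction; rows come back sorted by descending fold.
    """
    sample = set(sample_genes)
    if not sample:
        raise ValueError("empty candidate gene set")
    if universe is None:
        universe = set(annotation["gene_id"])
    else:
        universe = set(universe)
    dropped = sample - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} sample gene(s) not in universe were dropped"
        )
    sample &= universe
    if not sample:
        raise ValueError("no sample genes in the annotation universe")
    ann = annotation[annotation["gene_id"].isin(universe)]
    N, n = len(universe), len(sample)
    rows = []
    for term, grp in ann.groupby("go_id"):
        term_genes = set(grp["gene_id"])
        K = len(term_genes)
        k = len(term_genes & sample)
        expected = n * K / N
        rows.append(
            {
                "term": term, "reference": K, "observed": k,
                "expected": expected,
                "fold": k / expected if expected > 0 else np.nan,
                "p_over": float(hypergeom.sf(k - 1, N, K, n)),
                "p_under": float(hypergeom.cdf(k, N, K, n)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_over"] = multipletests(out["p_over"], method="fdr_bh")[1]
        out["fdr_under"] = multipletests(out["p_under"], method="fdr_bh")[1]
        out = out.sort_values("fold", ascending=False).reset_index(drop=True)
    return out
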