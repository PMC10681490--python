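"""Candidate windows: intersection of per-covariate Wstat outlier windows
with multivariate RDA outlier SNPs, representative SNP selection, and
matched neutral control sets.

A window survives only if at least one RDA outlier SNP falls inside its
half-open [start, end) interval; unique windows are deduplicated by exact
(chrom, start, end) — boundaries are covariate-specific, so overlapping
but distinct intervals from different covariates are retained separately —
and each window is represented by its contained outlier SNP of largest
absolute loading (ties broken toward the lower position).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from adaptscan.variants import GenotypeTable, intergenic_subset, site_maf


def intersect(
    outlier_windows: pd.DataFrame,
    rda_outliers: pd.DataFrame,
) -> pd.DataFrame:
    """Windows (rows flagged ``outlier``) containing >= 1 RDA outlier SNP.

    ``rda_outliers`` needs columns chrom, pos (plus any annotation carried
    through). Returns the retained windows with a list-valued
    ``outlier_snps`` column of row indices into ``rda_outliers``.
    """
    flagged = outlier_windows[outlier_windows.get("outlier", False)]
    rows = []
    for _, w in flagged.iterrows():
        sub = rda_outliers[
            (rda_outliers["chrom"] == w["chrom"])
            & (rda_outliers["pos"] >= w["start"])
            & (rda_outliers["pos"] < w["end"])
        ]
        if len(sub):
            rec = w.to_dict()
            rec["outlier_snps"] = list(sub.index)
            rows.append(rec)
    return pd.DataFrame(
        rows, columns=[*outlier_windows.columns, "outlier_snps"]
    )


def merge_unique(per_covariate: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Deduplicate candidate windows across covariates by exact interval.

    Source covariates are unioned; contained outlier-SNP lists are merged.
    """
    merged: dict[tuple, dict] = {}
    for cov, df in per_covariate.items():
        for _, w in df.iterrows():
            key = (w["chrom"], float(w["start"]), float(w["end"]))
            if key not in merged:
                merged[key] = {
                    "chrom": w["chrom"], "start": w["start"], "end": w["end"],
                    "sources": {cov},
                    "outlier_snps": set(w["outlier_snps"]),
                }
            else:
                merged[key]["sources"].add(cov)
                merged[key]["outlier_snps"].update(w["outlier_snps"])
    rows = [
        {
            **rec,
            "sources": sorted(rec["sources"]),
            "outlier_snps": sorted(rec["outlier_snps"]),
        }
        for rec in merged.values()
    ]
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "sources", "outlier_snps"]
    )
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def representative_snps(
    candidates: pd.DataFrame, rda_outliers: pd.DataFrame
) -> pd.DataFrame:
    """One representative SNP per candidate window: the contained outlier
    with the maximum |loading| on the axis where it was flagged."""
    reps = []
    for _, w in candidates.iterrows():
        sub = rda_outliers.loc[w["outlier_snps"]]
        order = sub.assign(absload=sub["loading"].abs()).sort_values(
            ["absload", "pos"], ascending=[False, True]
        )
        top = order.iloc[0]
        reps.append(
            {
                "chrom": w["chrom"], "start": w["start"], "end": w["end"],
                "snp_idx": int(top["snp_idx"]), "pos": int(top["pos"]),
                "loading": float(top["loading"]), "axis": int(top["axis"]),
            }
        )
    return pd.DataFrame(
        reps,
        columns=["chrom", "start", "end", "snp_idx", "pos", "loading", "axis"],
    )


def neutral_controls(
    table: GenotypeTable,
    genes: pd.DataFrame,
    outlier_idx: np.ndarray,
    n_large: int = 1500,
    n_matched: int | None = None,
    maf_min: float = 0.05,
    flank_bp: int = 0,
    seed: int | np.random.Generator | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two neutral SNP-index sets: a large random control set and a
    candidate-count-matched subset of it.

    The pool is intergenic sites with MAF >= maf_min, excluding every
    flagged outlier; sampling is uniform without replacement and seeded.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pool = set(intergenic_subset(table, genes, flank_bp=flank_bp).tolist())
    maf = site_maf(table)
    pool &= set(np.flatnonzero(np.nan_to_num(maf, nan=-1.0) >= maf_min).tolist())
    pool -= set(np.asarray(outlier_idx, dtype=int).tolist())
    pool_arr = np.array(sorted(pool))
    if len(pool_arr) < n_large:
        raise ValueError(
            f"neutral pool ({len(pool_arr)}) smaller than requested ({n_large})"
        )
    large = np.sort(rng.choice(pool_arr, size=n_large, replace=False))
    if n_matched is None:
        return large, large
    if n_matched > n_large:
        raise ValueError(
            f"matched size ({n_matched}) exceeds large set ({n_large})"
        )
    matched = np.sort(rng.choice(large, size=n_matched, replace=False))
    return large, matched
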