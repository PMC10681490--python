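"""Genotype matrix container, VCF IO, and site filtering.

Implements the variant-level filters of a population-genomic GEA study:
GATK-style site-quality thresholds, per-population representation and
depth requirements, a collapsed-paralog depth cap, minor-allele-frequency
filtering, physical-window LD pruning, interleaved thinning into k
independent subsets, and extraction of intergenic sites from a gene
annotation.

Quality filters are written as retention conditions (QUAL > 30 kept, etc.),
the strict complements of the usual removal thresholds. The MAF boundary is
inclusive: MAF >= maf_min is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel in integer outputs; internally np.nan


@dataclass
class SiteFilterSpec:
    """Thresholds for site-level filtering (defaults follow common GATK
    hard-filter recommendations plus cohort representation rules)."""

    qual_min: float = 30.0
    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    min_samples_per_pop: int = 4
    min_depth_per_sample: int = 3
    depth_cap_sd: float = 1.5
    maf_min: float = 0.05


@dataclass
class GenotypeTable:
    """Sites x samples diploid dosage matrix with site and sample metadata.

    ``dosage`` holds alternate-allele copy counts in {0, 1, 2} as float,
    with np.nan for missing genotypes. ``sites`` has columns chrom, pos,
    ref, alt and optional per-site INFO scalars (qual, qd, fs, mq);
    ``samples`` has sample_id, population and optionally x_km, y_km.
    """

    sites: pd.DataFrame
    dosage: np.ndarray
    samples: pd.DataFrame
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def snp_ids(self) -> pd.Series:
        return self.sites["chrom"].astype(str) + ":" + self.sites["pos"].astype(str)

    def take_sites(self, idx: np.ndarray) -> "GenotypeTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[idx],
            samples=self.samples,
            depth=None if self.depth is None else self.depth[idx],
        )

    def pop_indices(self) -> dict[str, np.ndarray]:
        return {
            pop: np.flatnonzero((self.samples["population"] == pop).to_numpy())
            for pop in self.samples["population"].unique()
        }


# --------------------------------------------------------------------------
# VCF IO
# --------------------------------------------------------------------------

def read_vcf(path: str | Path, metadata: pd.DataFrame | str | Path) -> GenotypeTable:
    """Load biallelic SNP dosages from a VCF plus a sample-metadata TSV.

    Metadata needs columns sample_id and population (x_km/y_km carried
    through when present); samples are ordered as in the VCF.
    """
    from cyvcf2 import VCF

    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t")
    vcf = VCF(str(path))
    meta = metadata.set_index("sample_id").loc[vcf.samples].reset_index()

    chroms, positions, refs, alts = [], [], [], []
    quals, qds, fss, mqs = [], [], [], []
    dosages, depths = [], []
    has_depth = False
    for var in vcf:
        if len(var.ALT) != 1 or var.is_indel:
            continue
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        quals.append(var.QUAL if var.QUAL is not None else np.nan)
        qds.append(_info_float(var, "QD"))
        fss.append(_info_float(var, "FS"))
        mqs.append(_info_float(var, "MQ"))
        gts = var.genotype.array()[:, :2]
        dose = np.where((gts < 0).any(axis=1), np.nan, gts.clip(0).sum(axis=1))
        dosages.append(dose.astype(float))
        try:
            dp = var.format("DP")
        except Exception:
            dp = None
        if dp is not None:
            has_depth = True
            depths.append(dp[:, 0].astype(float))
        else:
            depths.append(np.full(len(meta), np.nan))
    sites = pd.DataFrame(
        {
            "chrom": chroms, "pos": positions, "ref": refs, "alt": alts,
            "qual": quals, "qd": qds, "fs": fss, "mq": mqs,
        }
    )
    dosage = (
        np.asarray(dosages, dtype=float)
        if dosages else np.empty((0, len(meta)))
    )
    depth = np.asarray(depths, dtype=float) if has_depth else None
    return GenotypeTable(sites=sites, dosage=dosage, samples=meta, depth=depth)


def _info_float(var, key: str) -> float:
    val = var.INFO.get(key)
    return float(val) if val is not None else np.nan


def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a GT-only VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=adaptscan\n")
        for chrom, grp in table.sites.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 10000}>\n")
        for key, desc in [("QD", "Qual by depth"), ("FS", "Fisher strand"),
                          ("MQ", "Mapping quality")]:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{desc}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = "\t".join(table.samples["sample_id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i in range(table.n_sites):
            row = table.sites.iloc[i]
            qual = "." if pd.isna(row.get("qual", np.nan)) else f"{row['qual']:g}"
            info_parts = [
                f"{k.upper()}={row[k]:g}"
                for k in ("qd", "fs", "mq")
                if k in row.index and not pd.isna(row[k])
            ]
            info = ";".join(info_parts) if info_parts else "."
            gts = "\t".join(
                gt_codes.get(d, "./.") for d in table.dosage[i]
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['chrom']}:{row['pos']}\t"
                f"{row['ref']}\t{row['alt']}\t{qual}\t.\t{info}\tGT\t{gts}\n"
            )


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene records (chrom, start, end, gene_id) from a GFF3 file.

    GFF3 coordinates are 1-based closed; they are kept that way here.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("gene_id", parts[8]))
            rows.append((parts[0], int(parts[3]), int(parts[4]), gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED intervals (0-based half-open) as chrom/start/end."""
    return pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2],
    )


# --------------------------------------------------------------------------
# Filters
# --------------------------------------------------------------------------

def filter_sites(
    table: GenotypeTable,
    spec: SiteFilterSpec | None = None,
    mask_bed: pd.DataFrame | None = None,
) -> GenotypeTable:
    """Apply site-quality, representation, depth-cap and mask filters.

    Retains sites with QUAL > qual_min, QD > qd_min, FS < fs_max,
    MQ > mq_min (a filter whose INFO field is absent is skipped with a
    warning); with >= min_samples_per_pop samples at depth >=
    min_depth_per_sample in EVERY population (depth rule skipped when no
    per-sample depth is available); with site mean depth <= cohort mean +
    depth_cap_sd * sd; and not overlapping any mask interval.
    """
    spec = spec or SiteFilterSpec()
    keep = np.ones(table.n_sites, dtype=bool)

    for col, op, thr in [
        ("qual", "gt", spec.qual_min), ("qd", "gt", spec.qd_min),
        ("fs", "lt", spec.fs_max), ("mq", "gt", spec.mq_min),
    ]:
        if col not in table.sites.columns or table.sites[col].isna().all():
            logger.warning("INFO field %s absent; %s filter skipped", col.upper(), col)
            continue
        vals = table.sites[col].to_numpy(dtype=float)
        ok = vals > thr if op == "gt" else vals < thr
        ok |= np.isnan(vals)  # sites missing just this field pass it
        keep &= ok

    pop_idx = table.pop_indices()
    if table.depth is not None:
        deep = table.depth >= spec.min_depth_per_sample
        genotyped = ~np.isnan(table.dosage)
        counted = deep & genotyped
        for pop, idx in pop_idx.items():
            keep &= counted[:, idx].sum(axis=1) >= spec.min_samples_per_pop
        site_mean_depth = np.nanmean(table.depth, axis=1)
        cap = site_mean_depth.mean() + spec.depth_cap_sd * site_mean_depth.std(ddof=1)
        keep &= site_mean_depth <= cap
    else:
        logger.warning("no per-sample depth; representation counts genotyped samples")
        genotyped = ~np.isnan(table.dosage)
        for pop, idx in pop_idx.items():
            keep &= genotyped[:, idx].sum(axis=1) >= spec.min_samples_per_pop

    if mask_bed is not None and len(mask_bed):
        for chrom, grp in table.sites.groupby("chrom", sort=False):
            sub = mask_bed[mask_bed["chrom"] == chrom]
            if not len(sub):
                continue
            pos = grp["pos"].to_numpy()
            hit = np.zeros(len(pos), dtype=bool)
            for _, iv in sub.iterrows():
                # BED is 0-based half-open; VCF pos is 1-based
                hit |= (pos > iv["start"]) & (pos <= iv["end"])
            keep[grp.index.to_numpy()] &= ~hit

    return table.take_sites(keep)


def site_maf(table: GenotypeTable) -> np.ndarray:
    """Minor-allele frequency per site over non-missing genotypes."""
    dose = table.dosage
    n_called = (~np.isnan(dose)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p_alt = np.nansum(dose, axis=1) / (2.0 * n_called)
    p_alt = np.where(n_called == 0, np.nan, p_alt)
    return np.minimum(p_alt, 1.0 - p_alt)


def maf_filter(table: GenotypeTable, maf_min: float = 0.05) -> GenotypeTable:
    """Keep sites with MAF >= maf_min (inclusive boundary)."""
    maf = site_maf(table)
    keep = np.nan_to_num(maf, nan=-1.0) >= maf_min
    return table.take_sites(keep)


def ld_prune(
    table: GenotypeTable,
    window_bp: int = 5000,
    step: int = 1,
    r2_max: float = 0.7,
) -> np.ndarray:
    """Greedy physical-window LD pruning; returns kept site indices.

    A sliding window of ``window_bp`` is advanced one site at a time; while
    any pair of retained sites within the window has squared Pearson
    correlation of dosages > ``r2_max``, the pair member with the lower MAF
    is dropped (tie: the later position). Missing genotypes are excluded
    pairwise. Deterministic.
    """
    maf = site_maf(table)
    kept = np.ones(table.n_sites, dtype=bool)
    chrom = table.sites["chrom"].to_numpy()
    pos = table.sites["pos"].to_numpy()
    dose = table.dosage

    for i in range(0, table.n_sites, step):
        if not kept[i]:
            continue
        j = i + 1
        while j < table.n_sites and chrom[j] == chrom[i] and pos[j] - pos[i] <= window_bp:
            if kept[j] and kept[i]:
                r2 = _pairwise_r2(dose[i], dose[j])
                if r2 > r2_max:
                    drop = _lower_maf_member(i, j, maf)
                    kept[drop] = False
            if not kept[i]:
                break
            j += 1
    return np.flatnonzero(kept)


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        return 0.0
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return r * r


def _lower_maf_member(i: int, j: int, maf: np.ndarray) -> int:
    if maf[i] < maf[j]:
        return i
    if maf[j] < maf[i]:
        return j
    return max(i, j)  # tie: drop the later position


def thin_interleave(table: GenotypeTable, k: int = 50) -> list[np.ndarray]:
    """Split sites (genome order) into k interleaved subsets.

    Subset i holds ordinal ranks i, i+k, i+2k, ...; the subsets partition
    the table's sites.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > table.n_sites:
        raise ValueError(f"k={k} exceeds number of sites ({table.n_sites})")
    return [np.arange(i, table.n_sites, k) for i in range(k)]


def intergenic_subset(
    table: GenotypeTable, genes: pd.DataFrame, flank_bp: int = 0
) -> np.ndarray:
    """Indices of sites outside all gene intervals extended by ``flank_bp``.

    Gene intervals are 1-based closed (GFF3); a site at end + flank + 1 is
    intergenic.
    """
    if not len(genes):
        return np.arange(table.n_sites)
    table_chroms = set(table.sites["chrom"].unique())
    gene_chroms = set(genes["chrom"].unique())
    missing = table_chroms - gene_chroms
    if missing:
        raise ValueError(
            f"annotation lacks chromosomes present in genotypes: {sorted(missing)}"
        )
    keep = np.ones(table.n_sites, dtype=bool)
    for chrom, grp in table.sites.groupby("chrom", sort=False):
        sub = genes[genes["chrom"] == chrom]
        pos = grp["pos"].to_numpy()
        hit = np.zeros(len(pos), dtype=bool)
        for _, g in sub.iterrows():
            hit |= (pos >= g["start"] - flank_bp) & (pos <= g["end"] + flank_bp)
        keep[grp.index.to_numpy()] = ~hit
    return np.flatnonzero(keep)
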