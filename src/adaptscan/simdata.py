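"""Synthetic genotype / environment / annotation generator with ground truth.

The generative model mirrors the hierarchical covariance model assumed by
covariance-corrected association tests (Balding-Nichols-like standardized
deviations): each SNP has an ancestral frequency pi drawn uniformly, the
per-population frequencies deviate from pi with covariance
drift_scale^2 * Omega on the standardized scale
alpha = (p - pi) / sqrt(pi (1 - pi)), and diploid genotypes are binomial
draws from the population frequency. Adaptive loci additionally receive a
linear shift beta * z_j on the standardized scale, where z is a
standardized environmental covariate sampled from a smooth raster field at
the population coordinates.

Adaptive loci are planted in contiguous blocks of consecutive SNPs
(default 10 SNPs ~ 20 kbp at the default spacing), emulating the footprint
of local selective sweeps: the window-based stages of the pipeline are
designed around spatially clustered signal, and isolated single-SNP
signals are not what selection scans target.

All randomness flows from a single integer seed through one named
generator; fixed seed implies byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from adaptscan.envgrid import Raster, buffer_mean, write_asc
from adaptscan.variants import GenotypeTable, write_vcf


def _default_pop_coords() -> list[tuple[float, float]]:
    # 8 populations on a 4 x 2 grid spanning the default 4000 km extent
    return [
        (x, y)
        for y in (1000.0, 3000.0)
        for x in (500.0, 1500.0, 2500.0, 3500.0)
    ]


@dataclass
class SimConfig:
    """Study-scale defaults: 8 populations x 9 diploids, 5,000 neutral and
    50 adaptive SNPs (effect 0.4 SD of standardized frequency), drift scale
    0.15, two smooth environmental layers of which the first is causal."""

    n_pops: int = 8
    n_per_pop: int = 9
    L_neutral: int = 5000
    L_adaptive: int = 50
    beta: float = 0.4
    drift_scale: float = 0.15
    decay_km: float = 1500.0
    pop_coords: list[tuple[float, float]] = field(default_factory=_default_pop_coords)
    raster_extent: tuple[float, float, float, float] = (0.0, 0.0, 4000.0, 4000.0)
    raster_cell: float = 50.0
    n_rasters: int = 2
    smooth_len: float = 800.0
    n_chroms: int = 2
    snp_spacing_bp: int = 2000
    adaptive_block: int = 10
    coord_jitter_km: float = 20.0
    maf_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValueError("need at least 2 populations")
        if self.L_adaptive < 0:
            raise ValueError("L_adaptive must be >= 0")
        if self.drift_scale <= 0:
            raise ValueError("drift_scale must be > 0")
        if self.raster_cell <= 0:
            raise ValueError("raster_cell must be > 0")
        if len(self.pop_coords) != self.n_pops:
            raise ValueError("pop_coords length must equal n_pops")


@dataclass
class SimTruth:
    """Ground truth of one simulation: the SPD covariance used for drift,
    the planted loci as (snp_id, covariate, beta) triples, and the raster
    fields."""

    omega_true: np.ndarray
    adaptive_loci: list[tuple[str, str, float]]
    raster_fields: dict[str, Raster]
    pi: np.ndarray
    z: np.ndarray
    seed: int


@dataclass
class SimDataset:
    genotypes: GenotypeTable
    rasters: dict[str, Raster]
    genes: pd.DataFrame
    gene2go: pd.DataFrame
    truth: SimTruth
    config: SimConfig


# --------------------------------------------------------------------------
# Core generative operations
# --------------------------------------------------------------------------

def make_covariance(
    pop_coords: np.ndarray | list[tuple[float, float]],
    decay: float,
    scale: float = 1.0,
) -> np.ndarray:
    """Exponentially decaying spatial covariance between populations.

    Omega[i, j] = scale * exp(-dist(i, j) / decay), jittered by 1e-9 on the
    diagonal to guarantee positive definiteness when coordinates coincide.
    """
    if decay <= 0:
        raise ValueError("decay must be > 0")
    coords = np.asarray(pop_coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 populations")
    dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    omega = scale * np.exp(-dist / decay)
    omega[np.diag_indices_from(omega)] = scale
    omega = omega + 1e-9 * np.eye(len(coords))
    return omega


def simulate_frequencies(
    omega_true: np.ndarray,
    L: int,
    drift_scale: float,
    rng: np.random.Generator,
    maf_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[np.ndarray, np.ndarray]:
    """Population allele frequencies under pure drift.

    Returns (freqs (J, L), pi (L,)): pi_l ~ Uniform(maf_range); deviations
    e_l ~ MVN(0, drift_scale^2 * Omega); p_jl = clamp(pi_l +
    sqrt(pi_l (1 - pi_l)) e_jl, 0.001, 0.999).
    """
    J = omega_true.shape[0]
    chol = np.linalg.cholesky(omega_true)
    pi = rng.uniform(maf_range[0], maf_range[1], size=L)
    e = drift_scale * (chol @ rng.standard_normal((J, L)))
    p = pi[None, :] + np.sqrt(pi * (1.0 - pi))[None, :] * e
    return np.clip(p, 0.001, 0.999), pi


def plant_adaptive(
    freqs: np.ndarray,
    pi: np.ndarray,
    z: np.ndarray,
    loci: np.ndarray,
    beta: float,
) -> np.ndarray:
    """Shift frequencies of ``loci`` along the standardized covariate z.

    p_jl <- clamp(p_jl + sqrt(pi_l (1 - pi_l)) * beta * z_j, 0.001, 0.999);
    other loci untouched. ``z`` must be standardized over populations.
    """
    loci = np.asarray(loci)
    if loci.size and (loci.min() < 0 or loci.max() >= freqs.shape[1]):
        bad = loci[(loci < 0) | (loci >= freqs.shape[1])]
        raise ValueError(f"unknown locus id(s): {bad.tolist()}")
    out = freqs.copy()
    shift = np.sqrt(pi[loci] * (1.0 - pi[loci]))[None, :] * beta * z[:, None]
    out[:, loci] = np.clip(out[:, loci] + shift, 0.001, 0.999)
    return out


def sample_genotypes(
    freqs: np.ndarray,
    n_per_pop: int,
    rng: np.random.Generator,
    n_chroms: int = 2,
    snp_spacing_bp: int = 2000,
    pop_coords: np.ndarray | None = None,
    coord_jitter_km: float = 0.0,
) -> GenotypeTable:
    """Binomial(2, p) diploid genotypes on synthetic chromosomes.

    SNPs are split evenly over ``n_chroms`` chromosomes at fixed spacing.
    Individual coordinates are the population coordinate plus a small
    uniform jitter when ``pop_coords`` is given.
    """
    J, L = freqs.shape
    dose = np.empty((L, J * n_per_pop), dtype=float)
    for j in range(J):
        draws = rng.binomial(2, freqs[j][:, None], size=(L, n_per_pop))
        dose[:, j * n_per_pop:(j + 1) * n_per_pop] = draws

    per_chrom = int(np.ceil(L / n_chroms))
    chroms, positions = [], []
    for l in range(L):
        c, within = divmod(l, per_chrom)
        chroms.append(f"chr{c + 1}")
        positions.append((within + 1) * snp_spacing_bp)
    ref = np.full(L, "A")
    alt = np.full(L, "G")
    sites = pd.DataFrame(
        {
            "chrom": chroms, "pos": positions, "ref": ref, "alt": alt,
            "qual": 100.0, "qd": 25.0, "fs": 1.0, "mq": 60.0,
        }
    )
    rows = []
    for j in range(J):
        for i in range(n_per_pop):
            row = {"sample_id": f"P{j + 1}_{i + 1}", "population": f"P{j + 1}"}
            if pop_coords is not None:
                jitter = rng.uniform(-coord_jitter_km, coord_jitter_km, size=2)
                row["x_km"] = pop_coords[j][0] + jitter[0]
                row["y_km"] = pop_coords[j][1] + jitter[1]
            rows.append(row)
    samples = pd.DataFrame(rows)
    return GenotypeTable(sites=sites, dosage=dose, samples=samples)


def simulate_rasters(
    extent: tuple[float, float, float, float],
    cell: float,
    n_rasters: int,
    smooth_len: float,
    rng: np.random.Generator,
) -> dict[str, Raster]:
    """Standardized smoothed-white-noise layers with correlation length
    ``smooth_len`` (km), named env_1..env_n."""
    x0, y0, x1, y1 = extent
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate raster extent")
    if cell > min(x1 - x0, y1 - y0):
        raise ValueError("cell size exceeds extent span")
    ncols = int(round((x1 - x0) / cell))
    nrows = int(round((y1 - y0) / cell))
    sigma = smooth_len / cell
    out = {}
    for k in range(n_rasters):
        smooth = smoothed_noise(nrows, ncols, sigma, rng)
        sd = smooth.std()
        if sd > 1e-12:
            smooth = (smooth - smooth.mean()) / sd
        else:  # smoothing flattened the field entirely
            smooth = smooth - smooth.mean()
        out[f"env_{k + 1}"] = Raster(
            values=smooth, xll=x0, yll=y0, cellsize=cell
        )
    return out


def smoothed_noise(
    nrows: int, ncols: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-smoothed standard white noise, NOT standardized: its cell
    standard deviation shrinks toward 0 as sigma grows past the grid size."""
    noise = rng.standard_normal((nrows, ncols))
    return ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")


# --------------------------------------------------------------------------
# Annotation and dataset assembly
# --------------------------------------------------------------------------

def simulate_annotation(
    genotypes: GenotypeTable,
    rng: np.random.Generator,
    gene_every_bp: int = 50000,
    gene_len_bp: int = 20000,
    n_terms: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniformly spaced synthetic genes plus a gene -> GO-term mapping."""
    genes = []
    gid = 0
    for chrom, grp in genotypes.sites.groupby("chrom", sort=False):
        span = int(grp["pos"].max())
        for start in range(gene_every_bp, span, gene_every_bp):
            gid += 1
            genes.append((chrom, start, start + gene_len_bp - 1, f"gene{gid:05d}"))
    genes_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "gene_id"])
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    rows = []
    for gene in genes_df["gene_id"]:
        for term in rng.choice(terms, size=rng.integers(1, 4), replace=False):
            rows.append((gene, term))
    gene2go = pd.DataFrame(rows, columns=["gene_id", "go_id"])
    return genes_df, gene2go


def _covariate_z(
    raster: Raster, pop_coords: list[tuple[float, float]], radius_km: float = 50.0
) -> np.ndarray:
    vals = np.array(
        [buffer_mean(raster, x, y, radius_km)[0] for x, y in pop_coords]
    )
    return (vals - vals.mean()) / vals.std(ddof=0)


def adaptive_block_indices(cfg: SimConfig) -> np.ndarray:
    """Planted locus indices: contiguous blocks evenly spread along the genome."""
    L = cfg.L_neutral + cfg.L_adaptive
    if cfg.L_adaptive == 0:
        return np.array([], dtype=int)
    block = min(cfg.adaptive_block, cfg.L_adaptive)
    n_blocks = int(np.ceil(cfg.L_adaptive / block))
    starts = np.linspace(0, L - block, n_blocks + 2)[1:-1].astype(int)
    idx = np.concatenate([np.arange(s, s + block) for s in starts])[: cfg.L_adaptive]
    return np.unique(idx)


def simulate_dataset(cfg: SimConfig | None = None, **overrides) -> SimDataset:
    """Generate one complete synthetic study (genotypes + rasters +
    annotation + truth) from a single seed."""
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a SimConfig or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)

    rasters = simulate_rasters(
        cfg.raster_extent, cfg.raster_cell, cfg.n_rasters, cfg.smooth_len, rng
    )
    causal_name = "env_1"
    z = _covariate_z(rasters[causal_name], cfg.pop_coords)

    omega = make_covariance(cfg.pop_coords, cfg.decay_km, scale=1.0)
    L = cfg.L_neutral + cfg.L_adaptive
    freqs, pi = simulate_frequencies(
        omega, L, cfg.drift_scale, rng, maf_range=cfg.maf_range
    )
    loci = adaptive_block_indices(cfg)
    freqs = plant_adaptive(freqs, pi, z, loci, cfg.beta)

    genotypes = sample_genotypes(
        freqs, cfg.n_per_pop, rng,
        n_chroms=cfg.n_chroms, snp_spacing_bp=cfg.snp_spacing_bp,
        pop_coords=np.asarray(cfg.pop_coords), coord_jitter_km=cfg.coord_jitter_km,
    )
    genes, gene2go = simulate_annotation(genotypes, rng)

    snp_ids = genotypes.snp_ids.to_numpy()
    truth = SimTruth(
        omega_true=omega,
        adaptive_loci=[(snp_ids[l], causal_name, cfg.beta) for l in loci],
        raster_fields=rasters,
        pi=pi,
        z=z,
        seed=cfg.seed,
    )
    return SimDataset(
        genotypes=genotypes, rasters=rasters, genes=genes,
        gene2go=gene2go, truth=truth, config=cfg,
    )


def write_dataset(ds: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset as plain-text files: VCF, metadata TSV, .asc rasters,
    GFF3, gene->GO TSV and a truth JSON. Returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["vcf"] = outdir / "genotypes.vcf"
    write_vcf(ds.genotypes, paths["vcf"])

    paths["metadata"] = outdir / "samples.tsv"
    ds.genotypes.samples.to_csv(paths["metadata"], sep="\t", index=False)

    raster_dir = outdir / "rasters"
    raster_dir.mkdir(exist_ok=True)
    for name, raster in ds.rasters.items():
        write_asc(raster, raster_dir / f"{name}.asc")
    paths["rasters"] = raster_dir

    paths["gff"] = outdir / "genes.gff3"
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in ds.genes.iterrows():
            fh.write(
                f"{g['chrom']}\tadaptscan\tgene\t{g['start']}\t{g['end']}\t.\t+\t.\t"
                f"ID={g['gene_id']}\n"
            )

    paths["gene2go"] = outdir / "gene2go.tsv"
    ds.gene2go.to_csv(paths["gene2go"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": ds.truth.seed,
                "omega_true": ds.truth.omega_true.tolist(),
                "adaptive_loci": [
                    {"snp_id": s, "covariate": c, "beta": b}
                    for s, c, b in ds.truth.adaptive_loci
                ],
                "z": ds.truth.z.tolist(),
            },
            fh, indent=1,
        )
    return paths
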