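# adaptscan

Genome–environment association (GEA) scanning for landscape genomics:
from a filtered SNP matrix and gridded environmental predictors to
candidate adaptive windows, adaptive-versus-neutral population structure,
and generalized-dissimilarity turnover maps.

`adaptscan` is aimed at population geneticists studying local adaptation
in structured, range-wide samples (the motivating system is a large
carnivore sampled across a continent, with a handful of populations of
~10 diploid individuals each). It combines two complementary scans and
keeps only their consensus:

1. **Multivariate scan — redundancy analysis (RDA).** SNP dosages
   `Y (n × L)` are regressed on standardized environmental predictors
   `X`, optionally conditioning on neutral-structure principal components
   `Z` (partial RDA). Constrained axes are tested with an ANOVA-like
   permutation test; SNPs whose loadings on significant axes fall more
   than 3 SD from the axis mean are outliers.

2. **Univariate scan — covariance-corrected Bayes factors.** Population
   allele frequencies are standardized, `α̃_jl = (p̂_jl − π_l)/√(π_l(1−π_l))`,
   and the scaled population covariance `Ω = (1/L) Σ_l α̃_l α̃_lᵀ` corrects
   each SNP–covariate test for shared drift history. Under
   `α̃ = βz + e, e ~ N(0, Ω)` with prior `β ~ N(0, τ²)`, the Bayes factor
   has the closed form
   `log BF = −½ log(1 + τ²s) + τ²u²/(2(1 + τ²s))` with `s = zᵀΩ⁻¹z`,
   `u = zᵀΩ⁻¹α̃`, reported in decibans (10·log₁₀BF).

Per-covariate BF tracks are smoothed with a GCV cubic spline along each
chromosome; inflection points delimit windows, each scored with
`Wstat = √n·(mean BF − μ)/σ`. Windows above the 99th Wstat percentile
that also contain at least one RDA outlier SNP are the candidate windows,
each represented by its largest-|loading| SNP. Downstream modules compute
GO-term over-representation of candidate genes (hypergeometric + BH FDR),
adaptive-minus-neutral Euclidean distance contrasts, and generalized
dissimilarity models (GDM: monotone I-spline regression of pairwise
genetic dissimilarity through a `1 − exp(−η)` link) whose fitted turnover
functions transform rasters into RGB maps comparable by Procrustes
superimposition.

A first-class synthetic-data module generates the whole input bundle
(VCF, sample metadata, ESRI ASCII rasters, GFF3, gene→GO map) from a
Balding–Nichols-like model with planted environmental effects and known
ground truth, so every stage is testable without external data.

## Worked example

```bash
adaptscan demo --out demo_run --seed 1
```

simulates the default study (8 populations × 9 diploids, 5,050 SNPs of
which 50 are planted with effect β = 0.4 on a smooth environmental field)
and runs every stage, writing plain-text outputs plus `manifest.json`
under `demo_run/run/`. The same analysis through the library:

```python
from adaptscan.simdata import simulate_dataset
from adaptscan.pipeline import PipelineParams, run_synthetic, planted_recovery

ds = simulate_dataset(seed=1)
res = run_synthetic(ds, PipelineParams(seed=1))
print(planted_recovery(res, [s for s, _, _ in ds.truth.adaptive_loci]))
```

prints (seed 1):

```
{'n_planted_scanned': 49, 'recall': 0.857…, 'fisher_p': 3.4e-71,
 'n_candidate_windows': 13}
```

Of the 50 planted SNPs, 49 survive the MAF filter and 85.7 % land inside
the 13 candidate windows; the Fisher test confirms the candidates are
massively enriched for planted loci rather than scattered noise. Mean
spline-window size is ≈ 14 kbp, two RDA axes are significant, and the
estimated Ω correlates ~0.86 with the generating covariance (off-diagonal
entries).

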