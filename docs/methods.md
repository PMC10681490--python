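# Methods

This note documents the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should
know about. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic data model

The generator (`adaptscan.simdata`) draws, per SNP, an ancestral
frequency `π ~ U(0.05, 0.95)` and per-population deviations on the
standardized scale, `e ~ MVN(0, σ_d² Ω)`, giving
`p_j = clip(π + √(π(1−π)) e_j, 0.001, 0.999)`. `Ω` is an exponentially
decaying spatial covariance `Ω_ij = exp(−d_ij / λ)` over population
coordinates (default decay λ = 1500 km over a 4000 km extent). This
Balding–Nichols-like construction is exactly the hierarchical model the
covariance-corrected association test assumes, which makes parameter
recovery a fair, interpretable benchmark. Diploid genotypes are
`Binomial(2, p_j)`; the clamp at 0.001/0.999 avoids fixation (fixed
sites would be MAF-filtered anyway).

Adaptive loci receive an additional standardized shift `β z_j`, where
`z` is the standardized value of the first environmental layer at the
population coordinates. **Planted loci sit in contiguous blocks of 10
consecutive SNPs (~20 kbp at the default 2 kbp spacing).** Local
selection leaves a regional footprint — linked variation around a swept
site moves together — and the window stage of any scan of this family is
designed around spatially clustered signal; isolated single-SNP plants
would test a different (and unrealistic) alternative hypothesis.

Environmental layers are Gaussian-smoothed white noise (correlation
length 800 km by default), standardized over cells and written as ESRI
ASCII grids. Defaults: 8 populations × 9 diploids, 5,000 neutral + 50
adaptive SNPs, β = 0.4, σ_d = 0.15, two layers with the first causal —
a deliberately desk-scale rendition of a range-wide carnivore study
(dozens of individuals, weak continental structure, a few coherent
selected regions).

What the generator does **not** emulate: linkage disequilibrium from
recombination (SNPs are conditionally independent given frequencies),
sequencing/calling error and missingness, unequal sample sizes, isolation
by distance within populations, and real geodesy (planar km only).
Passing recovery tests therefore demonstrates the statistical machinery
under its own assumptions, not robustness to the full messiness of real
resequencing data.

## Variant filtering

Site filters retain the strict complements of the usual GATK hard-removal
thresholds (QUAL > 30, QD > 2, FS < 60, MQ > 40), require at least 4
samples at depth ≥ 3 in *every* population, and cap per-site mean depth
at the cohort mean + 1.5 SD (collapsed-paralog guard). Absent INFO/FORMAT
fields skip the corresponding filter with a logged warning. The MAF
boundary is inclusive (≥ 0.05 kept). LD pruning slides a 5 kbp physical
window one site at a time and, for any retained pair with r² > 0.7,
drops the lower-MAF member (tie: later position) — deterministic by
construction. Interleaved thinning assigns ordinal ranks modulo k
(default 50), partitioning the genome into k subsets.

## Ordination (RDA / pRDA)

Dosages are mean-imputed per SNP, centered, and not variance-scaled by
default (allele-frequency-scale variance retained; `scale=True`
available). Response and predictors are residualized on `[1, Z]` by OLS;
the constrained axes are singular directions of the fitted values, with
a rank-revealing SVD guarding collinear predictors. Axis sign is fixed
so the largest-|loading| SNP is positive.

The ANOVA-like axis test is sequential: axis k is tested with axes
1..k−1 moved into the conditioning set, and the permutation null is
formed by permuting rows of the reduced-model residuals (so conditioning
is respected). p-values have resolution 1/(n_perm + 1). Its type-I rate
is checked by simulation in the test suite.

Forward selection enters the candidate maximizing the model's Ezekiel
adjusted R², stops when the added term's permutation p ≥ 0.01 (1000
permutations by default) or once the selected model's adjusted R² reaches
the global model's (the scope ceiling). The ceiling is evaluated on the
*selected* model, not on the candidate being tried: adjusted R² is
approximately unbiased under noise additions, so comparing the candidate
itself to the global value would stop the procedure at the first step
about half the time even with a strong true predictor.

Variance partitioning reports, for components env/geo/structure, the
semipartial adjusted R² (full model minus the model omitting the
component), the confounded remainder (full − Σ pure, may legitimately be
negative with collinear components — flagged, not an error), fractions of
explainable variance, and a permutation p-value per partial model.

### Conditioning PCs: broken-stick selection

The number of neutral-structure PCs conditioned out of the scan defaults
to the broken-stick rule applied to the (intergenic-subset) genotype PCA
eigenvalues, rather than a fixed 2. On weakly structured data the
broken-stick retains 0 components and the scan runs unconditioned; on
strongly structured data it retains the leading structure axes. The
fixed-2 alternative has a concrete failure mode at simulation scale:
with thousands of weak-drift SNPs and a few dozen coherent adaptive
SNPs, the first genotype PC *is* the environmental direction being
tested (the "neutral structure" estimate is contaminated by the signal),
and conditioning on it removes the planted effect. Requiring a PC to
beat the broken-stick null spectrum before treating it as structure is
the principled version of the same correction. `n_struct_pcs` forces a
fixed count when the user knows better.

## Covariance-corrected Bayes factors

`π_l` is the haploid-size-weighted mean frequency; `Ω̂` is the mean outer
product of standardized deviations over the (LD-pruned) SNP set plus a
ridge `εI` (ε = 1e−3, escalated ×10 up to three times if a Cholesky
fails). Because `Ω̂` is estimated from sample frequencies it absorbs
binomial sampling noise as well as drift — which is what calibrates the
per-SNP test at finite sample sizes.

The Bayes factor uses the rank-one identities
`det(Ω + τ²zzᵀ) = det(Ω)(1 + τ²s)` and Sherman–Morrison, giving the
closed form quoted in the README; τ defaults to 0.1 on the standardized
frequency scale (a weakly informative prior: effects of ~0.1 SD of
standardized frequency per covariate SD). A grid alternative averages
the likelihood ratio `exp(βu − β²s/2)` over a β grid, either uniformly
(flat prior on the support, default (−0.3, 0.3), mirroring a common
support choice) or weighted by the N(0, τ²) density, in which case a
fine grid converges to the analytic BF. Per-SNP scores are computed per
interleaved subset and re-concatenated; with a closed-form statistic the
subsets exist for workflow parity and their union is verified to equal
the direct computation.

## Spline windows and Wstat

The per-covariate BF track is fitted with a cubic smoothing spline whose
penalty is selected by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`), evaluated on a 10 kbp grid.
Window boundaries are sign changes of the discrete second difference of
the fitted values (midpoint of the flanking grid cells) plus the
chromosome span ends; windows are half-open `[start, end)` and tile the
span exactly. Chromosomes with < 10 SNPs become one window. Wstat uses
the genome-wide mean and SD of the track; empty windows carry NaN and
are excluded from the quantile. Outliers exceed the type-7
(linear-interpolation) 99th percentile strictly, per covariate. A
constant track has σ = 0 and undefined Wstat (warned, all NaN).

## Candidates

A Wstat-outlier window is a candidate iff ≥ 1 RDA outlier SNP lies in
`[start, end)`. Uniqueness across covariates is exact-interval
deduplication: boundaries are covariate-specific, so overlapping but
distinct intervals are genuinely different delimitations and are kept.
The representative SNP is the contained outlier with max |loading| on
the axis where it was flagged (a SNP flagged on two axes uses the larger
|SD deviation|; exact ties go to the lower position). Neutral control
sets are drawn uniformly without replacement from intergenic,
MAF-passing, non-outlier sites.

## Structure contrast and GDM

Genotype PCA is an SVD of the centered (optionally scaled) dosage
matrix with the same sign convention as the RDA. Distance deltas compare
Euclidean distances over equally sized adaptive and neutral SNP sets in
raw dosage space, per individual pair, summarized as the median delta
per population pair.

GDM uses K = 3 order-2 I-splines per predictor with knots at the
min/median/max of the predictor's pairwise-pooled values, built as upper
partial sums of degree-2 B-splines on the open knot vector. Geographic
distance enters as one I-spline set on the pairwise planar distance.
Coefficients (all ≥ 0, intercept included) minimize the binomial-form
deviance `2Σ[d log(d/d̂) + (1−d) log((1−d)/(1−d̂))]` (0·log 0 := 0)
through iteratively reweighted non-negative least squares with step
halving; convergence is declared at deviance change < 1e−8 (≤ 500
iterations; non-convergence returns the best iterate with
`converged_ = False` and a warning). Predictor importance is the
coefficient sum per predictor (the maximum of its fitted partial
function) rescaled to sum to 100; rescaling the maximum to 100 is
available via `importance_rescale="max"`.

Raster transformation maps each layer through its fitted partial
function; geography is mapped per axis as distance from the grid origin
(an explicit approximation for visualizing a distance-based predictor).
The RGB composition min-max scales the first three cell-space PCs to
0–255 with nodata transparent. Procrustes superimposition solves
translation + rotation + isotropic scale in closed form via the SVD of
the cross-covariance; residuals are per-cell Euclidean distances after
alignment.

## Known limitations and observed behaviour

- **The two scans are positively dependent.** The RDA loading of a SNP
  and its Bayes factor are both functionals of the same
  population-frequency deviations (drift *and* binomial noise travel the
  same channel). Under a no-effect simulation the windows flagged by
  Wstat therefore contain ±3 SD RDA SNPs far more often than the product
  of the marginal rates predicts — intersecting the scans sharpens
  localization of true signal but does **not** multiply false-positive
  rates as if independent. The suite measures this joint excess
  explicitly; a user should read the candidate count as controlled by
  the window quantile (1 % by construction), not by a product of rates.
- With spatially autocorrelated environment *and* spatially
  autocorrelated drift, a no-effect simulation still contains genuine
  sample-level environment–genome correlation (isolation by
  environment), so significant RDA axes under β = 0 are expected, not a
  calibration failure of the axis test (whose type-I rate is verified on
  exchangeable nulls).
- Problem sizes in tests and the acceptance script (5,050 SNPs, 72
  individuals, 10 replicate seeds) are the package's reference
  simulation scale; all thresholds are the analysis defaults, not tuned
  per run.
- The GDM deviance explained on small SNP sets (tens of loci) is noisy;
  the recovery benchmark uses noiseless generated dissimilarities to
  test the optimizer separately from sampling noise.
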