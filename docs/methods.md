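# Methods

## Model

Expression for `n` samples and `g` genes is modeled as a mixture of
statistically independent sources: `Y = A S`, with `A` (n × k) the mixing
matrix of per-sample coefficients and `S` (k × g) the per-gene source
weights. The working assumption is that a broad impact eQTL — one genotype
perturbing many genes — produces a non-Gaussian imprint on the multivariate
expression profile that is largely independent of other factors, so ICA can
isolate it into its own component. Components whose coefficient vectors
associate with any genotype are treated as genetic; the rest are treated as
confounding structure. The sample covariance of the gene-standardized
non-genetic reconstruction `Y* = A* S*` becomes the random-effect covariance
`K` of a per-gene linear mixed model

    y_p = X β_p + c_p + ε_p,   c_p ~ N(0, τ²_p K),   ε_p ~ N(0, σ²_p I).

The genotype effect is tested with a Wald statistic against the standard
normal (squared: 1-df chi-square), the convention assumed by the genomic
inflation factor λ_p = qchisq(1 − m_p) / qchisq(0.5) computed from each
gene's median p-value m_p.

## Numerical choices

**ICA orientation and conventions.** FastICA (log-cosh contrast, symmetric
fixed-point updates) runs with genes as the observations: the centered
matrix is projected onto its top-k principal directions and scaled to
identity covariance across genes, and ICA estimates an orthogonal rotation
of that basis. Consequences that the test suite relies on: `A S` equals the
k-PC truncation of the centered matrix exactly; the column space of `A` is
the retained PCA subspace; and the decomposition is a pure re-rotation, so
no variance is invented or lost. Rows of `S` are rescaled to unit variance
with the largest-magnitude entry positive (the complementary scale and sign
absorbed into `A`), and components are ordered by decreasing variance of
their `A` column. Genes are mean-centered only before decomposition; a
`standardize` flag adds per-gene scaling for users who want it. Defaults
tol = 1e-4, max_iter = 1000, with up to 3 restarts at incremented seeds on
non-convergence; with a fixed seed the result is bitwise reproducible.

**Component count.** k is the smallest number of principal components
explaining 95% of the variance (configurable), which keeps the retained
subspace comparable across correction methods that take a component count as
input.

**Component screen.** Each component coefficient vector is regressed on
each genotype (intercept + slope, two-sided t with n − 2 df, computed
via the correlation identity for speed). A component is flagged when its
minimum p-value is below α / (k × s_tested) — a global Bonferroni over the
whole screening family. Monomorphic SNPs are excluded from both testing and
the correction count. The screen regression uses genotype only; genotype
PCs can be added via the scan covariates instead. An optional split plan
halves the SNPs at random so that filtering and scanning never use the same
genotype; full-data filtering is the default.

**Covariance.** Genes of `Y*` are standardized to mean 0 and unit variance
(n − 1 denominator; zero-variance genes dropped with a warning) and
`K = Z* Z*ᵀ / (g' − 1)`. The scale of K is immaterial because τ² absorbs
it. Eigenvalues in (−1e−8, 0) arising from round-off are clipped to zero;
anything more negative raises, signalling a numerical failure. With no
flagged components and centering-only preprocessing, CONFETI-I equals the
ICE baseline (covariance of the standardized observed matrix) to numerical
precision — a reduction the acceptance suite checks.

**Mixed model.** With `K = U D Uᵀ`, rotating `y` and `X` by `Uᵀ` makes the
marginal covariance `s²(h² D + (1 − h²) I)` diagonal, where
h² = τ²/(τ² + σ²). The profiled ML over h² is maximized on
[0, 1 − 1e−6] with a 64-point bracketing grid (linear plus log-spaced
points toward both edges) followed by bounded scalar refinement
(xatol 1e−8); β then follows by generalized least squares and the scale by
its ML estimate. Scan mode `null_fixed` (default) estimates (τ², σ²) once
per gene under the covariates-only model and reuses them for every SNP —
the standard approximation for genome-wide scans — while `exact`
re-optimizes per SNP; tests verify `exact` against a brute-force dense
multivariate-normal likelihood grid, and both modes agree closely on null
data. OLS-based baselines (LINEAR, expression-PC fixed effects) use the
same ML-scale normal-reference Wald convention, so the mixed model with
K = I reduces to them exactly. The expression-PC count follows a
sample-size rule (30 PCs for 150–250 samples, 35 above, configurable below
150, capped at n − v − 3). Permutation calibration is deliberately not
implemented; λ is the calibration diagnostic. BH adjustment is applied
globally across all (gene, SNP) pairs of a scan.

**Post-processing conventions.** Coordinates are 1-based inclusive bp;
UCSC-style 0-based half-open inputs (cytoBand, BED) are converted on load.
cis means same chromosome and |SNP position − gene start| ≤ window,
boundary inclusive — 1 Mb for real-data labeling, 100 kb in the simulation.
Distance to a related gene uses that gene's start. Collapsing keeps the
smallest-p record per (gene, cytoband, label) among significant records,
ties broken by SNP position; without a cytoband table SNPs fall back to
fixed 1-Mb bins so synthetic genomes remain analyzable. A broad-impact
locus must show replicating trans associations with ≥ 2 genes on ≥ 2
chromosomes distinct from its own; grouping is per cytoband by default
(per SNP optionally). Pipeline order: label → screen → collapse →
replicate → detect, so every reported locus has already survived the
pseudo-trans screen.

**QC filters.** SNPs: MAF < 0.05 removed (strict inequality, so a MAF of
exactly 0.05 survives), monomorphic always removed, then greedy
left-to-right LD pruning within 10 kb at r² > 0.99. Missing genotype calls
are mean-imputed (rounded) only when a SNP's missingness is within a
configured maximum, default 0 — i.e. only complete SNPs pass by default.
Genes: removed when zeros exceed 80% of samples or when more than 85% of
values fall in the gene's top or bottom 20%. The 20% band is read as a
fraction of the gene's value range by default (a rank-quantile reading is
available via `tail_mode="quantile"`) — the choice is recorded in the
function signature because the two readings differ for heavy-tailed genes.

## Synthetic data

The generator emulates a yeast-style eQTL panel: 16 chromosomes of 750 kb,
SNP and gene positions uniform, haploid genotypes with per-SNP minor allele
frequency drawn U(0.05, 0.5) (diploid optional), default 2956 SNPs and 3000
genes for 112 samples. The planted architecture is 2500 single-gene pairs
(80% cis by the 100 kb rule, 20% trans) plus 10 broad-impact loci each
affecting a random 10% of genes; broad loci are drawn disjoint from
single-pair SNPs to keep truth categories unambiguous. Effects are N(0.8, 1)
for cis and N(0.48, 1) for trans and broad-impact, one independent draw per
(SNP, gene) pair; noise is N(0, 1). Confounders are sparse (30% of genes,
weights N(1, 0.5)) or dense (all genes, weights N(0, 1)); the scenarios are
30 sparse, 15 + 15 mixed, or none — the last defining the
theoretical-maximum-recovery ceiling when scanned without correction.
Per-sample confounder scores are i.i.d. N(0, 1); the gene-wise weight
distributions above are the specified quantities, the score distribution is
a modeling choice made here. The synthetic genome dimensions (750 kb
chromosomes) are scaffolding chosen so the 100 kb cis rule yields a
realistic cis-eligible fraction.

What the generator does not emulate: linkage disequilibrium between SNPs
(genotypes are independent draws), realistic allele-frequency spectra,
gene-density structure, expression count noise and library-size effects, or
correlated confounders. Passing benchmarks on this data therefore
demonstrates the statistical machinery — separation of genetic from
non-genetic components and the power consequences — not robustness to every
property of real sequencing data.

## Problem sizes used in tests

The full published-scale benchmark (2956 SNPs × 3000 genes × 100 datasets
× 7 methods) is out of scope for a test suite; the suite runs a scaled
configuration chosen to preserve the phenomenon: n = 150 samples, 600
genes, 600 SNPs, 400 planted pairs, 2 broad loci, 10 sparse confounders,
10 replicates. At this scale CONFETI-I's broad-impact recovery advantage
over ICE is large and stable (sign test across replicates), while cis
recovery differs only within noise — the qualitative ordering the method
claims. Mixed-model correctness is verified on n ≤ 30 instances against a
dense-likelihood grid oracle; the component screen's family-wise error on
500 null replicates.

## Known limitations

- The PANAMA-style likelihood-optimized covariance (CONFETI-P) is not
  implemented; an externally estimated K can be supplied through the same
  HDF5 interface.
- `null_fixed` scan mode slightly misestimates the variance components for
  SNPs with strong effects (they are estimated under the null); `exact`
  mode is available when per-SNP precision matters more than speed.
- The λ diagnostic assumes most (gene, SNP) pairs are null for a gene; for
  genes with pervasive true signal λ conflates inflation with signal.
- FastICA local optima: with k close to the matrix rank on featureless
  data, different seeds can converge to different rotations; the
  `component_stability` diagnostic quantifies this, and non-replicating
  components should be interpreted with caution.
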