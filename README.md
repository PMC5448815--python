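# confeti

Confounder correction for eQTL mapping that does not throw the genetics out
with the bathwater.

## The problem

Genome-wide eQTL scans regress every gene's expression on every genotype.
Hidden confounders — batch, environment, cell composition — create shared
expression variation across samples that inflates false positives, so modern
pipelines either regress out latent factors or absorb the sample structure
into the random effect of a linear mixed model. Both strategies have a blind
spot: a **broad impact eQTL** (a trans hotspot / master regulator whose
genotype shifts hundreds of genes at once) looks exactly like a confounder.
Standard corrections model it away, and the hotspot disappears from the
scan.

`confeti` separates genetic from non-genetic structure before correcting:

1. **Decompose** the expression matrix with independent component analysis,
   `Y = A S`, where the rows of `S` (per-gene weights) are maximally
   non-Gaussian sources and the columns of `A` are per-sample coefficients.
   The component count `k` is the number of principal components needed to
   explain 95% of the variance.
2. **Screen** every column of `A` against every genotype by simple
   regression. A component with any association passing the global
   Bonferroni level `α / (k·s)` is a candidate genetic component.
3. **Reconstruct** the non-genetic expression signal from the `k − r`
   unflagged components, `Y* = A* S*`, standardize each gene, and form the
   sample covariance `K = cov(Z*)` (CONFETI-I). The classic ICE baseline
   uses the full observed matrix instead; with `r = 0` the two coincide.
4. **Scan** with the linear mixed model, per gene `p`:

   `y_p = X β_p + c_p + ε_p`, `c_p ~ N(0, τ²_p K)`, `ε_p ~ N(0, σ²_p I)`

   where `X` holds the genotype (minor-allele counts), intercept and
   covariates (e.g. genotype PCs for population structure). Variance
   components are profiled over the heritability ratio after rotating by
   the eigenvectors of `K`; significance is a 1-df Wald test, adjusted by
   Benjamini–Hochberg; calibration is monitored with the per-gene genomic
   inflation factor `λ_p = qchisq(1 − median p) / qchisq(0.5)`.

Because the genotype-associated components are excluded from `K`, the
hotspot's variance stays testable and broad impact eQTL remain detectable —
while the remaining confounder structure is still corrected.

The package also ships the simulation benchmark used to validate the method
(planted cis / trans / broad-impact effects with sparse and dense
confounders), and real-data post-processing: cis/trans labeling, per-cytoband
collapsing of linked SNPs, pseudo-trans artifact screening, replication
counting across dataset pairs, and broad-impact locus detection.

## Worked example

```python
from confeti import (SimulationConfig, simulate_dataset, select_component_count,
                     decompose, flag_genetic_components, reconstruct_nongenetic,
                     build_confeti_k, scan, evaluate, run_confeti)

config = SimulationConfig(n_samples=150, n_genes=600, n_snps=600,
                          n_pairs=400, n_broad=2, n_sparse=10, n_dense=0)
expr, geno, truth = simulate_dataset(config, seed=42)

k = select_component_count(expr, variance_target=0.95)
decomp = decompose(expr, k=k, seed=0)
flags = flag_genetic_components(decomp, geno, alpha=0.05)
print(f"k = {k}, flagged components: {sorted(flags.flagged)}")

ystar = reconstruct_nongenetic(decomp, flags)
K = build_confeti_k(ystar)
table = scan(expr, geno, K=K, method="confeti_i")
metrics = evaluate(table, truth, fdr_grid=(0.05,))
print(f"CONFETI-I: AUC = {metrics['auc']:.3f}, "
      f"broad-impact recovery at FDR 0.05 = {metrics['recovery']['broad'][0.05]:.3f}")

ice_table = run_confeti(expr, geno, method="ice")
ice_metrics = evaluate(ice_table, truth, fdr_grid=(0.05,))
print(f"ICE:       AUC = {ice_metrics['auc']:.3f}, "
      f"broad-impact recovery at FDR 0.05 = {ice_metrics['recovery']['broad'][0.05]:.3f}")
```

Output:

```
k = 92, flagged components: [45, 47, 61, 64, 68, 76, 77, 78, 81, 84, 85, 89, 91]
CONFETI-I: AUC = 0.869, broad-impact recovery at FDR 0.05 = 0.442
ICE:       AUC = 0.841, broad-impact recovery at FDR 0.05 = 0.117
```

On this dataset 92 components capture 95% of the expression variance and 13
of them carry genotype signal (the two planted hotspots plus components
picking up strong cis effects). Excluding them from the covariance raises
broad-impact recovery from 12% to 44% at FDR 0.05 without hurting overall
ranking quality — the behavior the method was designed for.

The same pipeline is available from the shell:

```bash
confeti simulate --scenario sparse_only --n-samples 150 --out sim/
confeti decompose --expression sim/dataset0.expression.h5 --seed 0 --out decomp.h5
confeti filter --decomp decomp.h5 --genotypes sim/dataset0.genotypes.tsv \
    --genotype-annotation sim/dataset0.snp_annotation.tsv --out flags.json
confeti covariance --decomp decomp.h5 --flags flags.json --method confeti-i --out K.h5
confeti scan --expression sim/dataset0.expression.h5 --genotypes sim/dataset0.genotypes.tsv \
    --genotype-annotation sim/dataset0.snp_annotation.tsv --covariance K.h5 \
    --method confeti-i --out results.tsv
confeti evaluate --results results.tsv --truth sim/dataset0.truth.json --out metrics.json
```

`confeti preprocess` applies the QC filters for real data (MAF ≥ 0.05,
greedy LD pruning at r² > 0.99 within 10 kb, zero-inflation and skew filters
on genes, genotype PCs), reading PLINK bed/bim/fam or TSV genotypes and
TSV/HDF5 expression. `confeti replicate` compares two collapsed eQTL tables.

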