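"""Screen independent components for genotype association.

A component whose per-sample coefficient vector (a column of A) is
significantly associated with any genotype is a candidate broad-impact eQTL
carrier: it is flagged and later excluded from the non-genetic
reconstruction. Each (component, SNP) pair is tested by ordinary least
squares of the coefficient on the genotype (intercept + slope), two-sided
t-test with n - 2 df, and a component is flagged when its minimum p-value
clears the global Bonferroni level alpha / (k x s_tested).

An optional split plan divides the SNPs into random halves so filtering and
the downstream eQTL scan never touch the same genotype.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import ComponentFlagResult, GenotypeMatrix, IcaDecomposition, SplitPlan

__all__ = ["flag_genetic_components", "make_split_plan", "association_pvalues"]


def association_pvalues(A: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Two-sided slope p-values of each A column on each G column.

    Vectorized via the identity t = r sqrt(n-2) / sqrt(1 - r^2) for the OLS
    slope t-statistic with an intercept. Returns a (k, s) array.
    """
    n = A.shape[0]
    if G.shape[0] != n:
        raise ValueError("sample dimension mismatch between components and genotypes")
    Ac = A - A.mean(axis=0)
    Gc = G - G.mean(axis=0)
    a_ss = (Ac**2).sum(axis=0)
    g_ss = (Gc**2).sum(axis=0)
    denom = np.sqrt(np.outer(a_ss, g_ss))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac.T @ Gc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t2 = r**2 * (n - 2) / (1.0 - r**2)
    # exact collinearity -> infinite t -> p = 0
    t2 = np.where(r**2 >= 1.0, np.inf, t2)
    p = stats.f.sf(t2, 1, n - 2)  # t^2 with n-2 df is F(1, n-2); two-sided
    return p


def flag_genetic_components(
    D: IcaDecomposition,
    G: GenotypeMatrix,
    alpha: float = 0.05,
    genotype_subset: set | None = None,
) -> ComponentFlagResult:
    """Flag components with at least one Bonferroni-significant genotype hit."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if list(D.sample_ids) != list(G.sample_ids):
        raise ValueError("component and genotype samples are not aligned")
    snp_ids = list(G.snp_ids)
    if genotype_subset is not None:
        subset = set(genotype_subset)
        snp_ids = [s for s in snp_ids if s in subset]
    geno = G.values[snp_ids].to_numpy(dtype=float)
    polymorphic = geno.std(axis=0) > 0
    if not polymorphic.any():
        raise ValueError("no polymorphic SNP available for component screening")
    geno = geno[:, polymorphic]
    snp_ids = [s for s, keep in zip(snp_ids, polymorphic) if keep]

    p = association_pvalues(D.A, geno)
    min_idx = p.argmin(axis=1)
    min_p = p[np.arange(D.k), min_idx]
    best_snp = [snp_ids[i] for i in min_idx]
    n_tests = D.k * len(snp_ids)
    flagged = {int(j) for j in range(D.k) if min_p[j] < alpha / n_tests}
    return ComponentFlagResult(
        min_p=min_p,
        best_snp=best_snp,
        flagged=flagged,
        alpha=alpha,
        n_tests=n_tests,
        genotype_subset=set(snp_ids) if genotype_subset is not None else None,
    )


def make_split_plan(G: GenotypeMatrix, seed: int = 0) -> SplitPlan:
    """Uniformly random half-split of the SNP set, reproducible from seed."""
    snps = list(G.snp_ids)
    if len(snps) < 2:
        raise ValueError("need at least 2 SNPs to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(snps))
    half = len(snps) // 2
    subset_1 = {snps[i] for i in perm[:half]}
    subset_2 = {snps[i] for i in perm[half:]}
    return SplitPlan(subset_1=subset_1, subset_2=subset_2, seed=seed)
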