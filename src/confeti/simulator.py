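"""Benchmark data generator with planted cis/trans/broad-impact eQTL.

The generator mirrors a yeast-scale design: a 16-chromosome synthetic
genome, haploid genotypes with uniform minor-allele frequencies, 3000 genes,
and 2500 planted single-gene eQTL (80% cis by a 100 kb same-chromosome rule,
20% trans) plus 10 broad-impact loci each affecting 10% of genes. Effect
sizes are drawn N(0.8, 1) for cis and N(0.48, 1) for trans and broad-impact
pairs, unit-variance Gaussian noise is added, and confounders come in two
flavors: sparse (30% of genes affected, weights N(1, 0.5)) and dense
(weights N(0, 1) on every gene). Scenarios: ``sparse_only`` (30 sparse),
``mixed`` (15 sparse + 15 dense) and ``none`` (the confounder-free ceiling
used for the theoretical-maximum-recovery reference).

Per-sample confounder scores are i.i.d. standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_gene_annotation",
    "sample_architecture",
    "simulate_expression",
    "simulate_dataset",
    "evaluate",
]

N_CHROMOSOMES = 16
CHROM_LENGTH = 750_000


@dataclass
class SimulationConfig:
    """Benchmark generating parameters; defaults are the study conditions."""

    n_samples: int = 112
    n_snps: int = 2956
    n_genes: int = 3000
    n_pairs: int = 2500
    cis_fraction: float = 0.8
    n_broad: int = 10
    broad_gene_fraction: float = 0.10
    cis_window_sim: int = 100_000
    cis_effect_mean: float = 0.8
    cis_effect_sd: float = 1.0
    trans_effect_mean: float = 0.48
    trans_effect_sd: float = 1.0
    noise_sd: float = 1.0
    sparse_gene_fraction: float = 0.30
    sparse_effect_mean: float = 1.0
    sparse_effect_sd: float = 0.5
    scenario: str = "sparse_only"
    n_datasets: int = 50
    n_sparse: int | None = None
    n_dense: int | None = None
    ploidy: int = 1
    maf_low: float = 0.05
    maf_high: float = 0.5

    def confounder_counts(self) -> tuple[int, int]:
        if self.n_sparse is not None or self.n_dense is not None:
            return self.n_sparse or 0, self.n_dense or 0
        if self.scenario == "sparse_only":
            return 30, 0
        if self.scenario == "mixed":
            return 15, 15
        if self.scenario == "none":
            return 0, 0
        raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class SimulationTruth:
    """Planted effects: one row per (snp, gene) pair, plus confounders."""

    pairs: pd.DataFrame  # snp_id, gene_id, category, effect
    confounders: list = field(default_factory=list)
    gene_annotation: pd.DataFrame | None = None

    def pair_set(self, category: str | None = None) -> set:
        df = self.pairs
        if category is not None:
            df = df[df["category"] == category]
        return set(zip(df["snp_id"], df["gene_id"]))


def _uniform_positions(rng: np.random.Generator, count: int) -> pd.DataFrame:
    chrom = rng.integers(0, N_CHROMOSOMES, size=count)
    pos = rng.integers(1, CHROM_LENGTH + 1, size=count)
    order = np.lexsort((pos, chrom))
    return pd.DataFrame(
        {"chromosome": [f"chr{c + 1}" for c in chrom[order]],
         "position": pos[order].astype(np.int64)}
    )


def simulate_genotypes(config: SimulationConfig, seed: int = 0) -> GenotypeMatrix:
    """Binomial genotypes at uniformly placed loci with MAF ~ U(0.05, 0.5)."""
    rng = np.random.default_rng(seed)
    ann = _uniform_positions(rng, config.n_snps)
    ann.index = [f"snp{i}" for i in range(config.n_snps)]
    ann = ann.rename_axis("snp_id")
    maf = rng.uniform(config.maf_low, config.maf_high, size=config.n_snps)
    geno = rng.binomial(config.ploidy, maf, size=(config.n_samples, config.n_snps))
    values = pd.DataFrame(
        geno.astype(float),
        index=[f"sample{i}" for i in range(config.n_samples)],
        columns=ann.index,
    )
    return GenotypeMatrix(values=values, snp_annotation=ann, ploidy=config.ploidy)


def simulate_gene_annotation(config: SimulationConfig, seed: int = 0) -> pd.DataFrame:
    """Uniform gene starts on the synthetic genome (chromosome, start)."""
    rng = np.random.default_rng(seed)
    ann = _uniform_positions(rng, config.n_genes)
    ann.columns = ["chromosome", "start"]
    ann.index = [f"gene{i}" for i in range(config.n_genes)]
    return ann.rename_axis("gene_id")


def sample_architecture(
    G: GenotypeMatrix,
    gene_positions: pd.DataFrame,
    config: SimulationConfig,
    seed: int = 0,
) -> SimulationTruth:
    """Plant the eQTL architecture onto the genotype/gene scaffold."""
    rng = np.random.default_rng(seed)
    snp_ids = np.asarray(G.snp_ids)
    gene_ids = np.asarray(gene_positions.index)
    snp_chrom = G.snp_annotation["chromosome"].to_numpy()
    snp_pos = G.snp_annotation["position"].to_numpy()
    gene_chrom = gene_positions["chromosome"].to_numpy()
    gene_start = gene_positions["start"].to_numpy()

    # enumerate cis-eligible (snp, gene) index pairs per chromosome
    cis_pairs = []
    for chrom in np.unique(snp_chrom):
        si = np.where(snp_chrom == chrom)[0]
        gi = np.where(gene_chrom == chrom)[0]
        if not len(si) or not len(gi):
            continue
        dist = np.abs(snp_pos[si][:, None] - gene_start[gi][None, :])
        ii, jj = np.where(dist <= config.cis_window_sim)
        cis_pairs.append(np.column_stack([si[ii], gi[jj]]))
    cis_pairs = np.vstack(cis_pairs) if cis_pairs else np.empty((0, 2), dtype=int)

    n_cis = int(round(config.cis_fraction * config.n_pairs))
    n_trans = config.n_pairs - n_cis
    if len(cis_pairs) < n_cis:
        raise ValueError(
            f"only {len(cis_pairs)} cis-eligible pairs for {n_cis} requested; "
            "enlarge the cis window or use denser SNPs"
        )
    chosen_cis = cis_pairs[rng.choice(len(cis_pairs), size=n_cis, replace=False)]

    cis_set = {(int(a), int(b)) for a, b in cis_pairs}
    used = {(int(a), int(b)) for a, b in chosen_cis}
    trans_list: list[tuple[int, int]] = []
    while len(trans_list) < n_trans:
        a = int(rng.integers(0, len(snp_ids)))
        b = int(rng.integers(0, len(gene_ids)))
        if (a, b) in cis_set or (a, b) in used:
            continue
        used.add((a, b))
        trans_list.append((a, b))
    chosen_trans = np.array(trans_list, dtype=int).reshape(-1, 2)

    single_snps = set(chosen_cis[:, 0]) | set(chosen_trans[:, 0])
    free_snps = np.array([i for i in range(len(snp_ids)) if i not in single_snps])
    if len(free_snps) < config.n_broad:
        raise ValueError("not enough SNPs free of single-gene eQTL for broad loci")
    broad_snps = rng.choice(free_snps, size=config.n_broad, replace=False)
    n_broad_genes = int(round(config.broad_gene_fraction * config.n_genes))

    records = []
    eff_cis = rng.normal(config.cis_effect_mean, config.cis_effect_sd, size=n_cis)
    for (a, b), e in zip(chosen_cis, eff_cis):
        records.append((snp_ids[a], gene_ids[b], "cis", float(e)))
    eff_trans = rng.normal(config.trans_effect_mean, config.trans_effect_sd, size=n_trans)
    for (a, b), e in zip(chosen_trans, eff_trans):
        records.append((snp_ids[a], gene_ids[b], "trans", float(e)))
    for a in broad_snps:
        genes = rng.choice(len(gene_ids), size=n_broad_genes, replace=False)
        effs = rng.normal(config.trans_effect_mean, config.trans_effect_sd, size=n_broad_genes)
        for b, e in zip(genes, effs):
            records.append((snp_ids[int(a)], gene_ids[int(b)], "broad", float(e)))

    pairs = pd.DataFrame(records, columns=["snp_id", "gene_id", "category", "effect"])
    if pairs.duplicated(subset=["snp_id", "gene_id"]).any():
        # a broad gene set may touch a gene already carrying a single eQTL on
        # another SNP; duplicates within the same (snp, gene) key are dropped
        pairs = pairs.drop_duplicates(subset=["snp_id", "gene_id"], keep="first")
    return SimulationTruth(pairs=pairs, gene_annotation=gene_positions)


def simulate_expression(
    G: GenotypeMatrix,
    truth: SimulationTruth,
    config: SimulationConfig,
    seed: int = 0,
) -> ExpressionMatrix:
    """Planted genetic effects + confounders + unit-variance Gaussian noise."""
    rng = np.random.default_rng(seed)
    n, s = G.values.shape
    g = config.n_genes
    gene_ids = list(truth.gene_annotation.index)
    gene_index = {gid: i for i, gid in enumerate(gene_ids)}
    snp_index = {sid: i for i, sid in enumerate(G.snp_ids)}
    geno = G.values.to_numpy(dtype=float)

    Y = rng.normal(0.0, config.noise_sd, size=(n, g))
    for snp_id, gene_id, _, effect in truth.pairs.itertuples(index=False):
        Y[:, gene_index[gene_id]] += effect * geno[:, snp_index[snp_id]]

    n_sparse, n_dense = config.confounder_counts()
    confounders = []
    for _ in range(n_sparse):
        scores = rng.normal(0.0, 1.0, size=n)
        n_affected = int(round(config.sparse_gene_fraction * g))
        affected = rng.choice(g, size=n_affected, replace=False)
        weights = rng.normal(
            config.sparse_effect_mean, config.sparse_effect_sd, size=n_affected
        )
        Y[:, affected] += np.outer(scores, weights)
        confounders.append(
            {"type": "sparse", "genes": [gene_ids[i] for i in affected],
             "weights": weights, "scores": scores}
        )
    for _ in range(n_dense):
        scores = rng.normal(0.0, 1.0, size=n)
        weights = rng.normal(0.0, 1.0, size=g)
        Y += np.outer(scores, weights)
        confounders.append(
            {"type": "dense", "genes": gene_ids, "weights": weights, "scores": scores}
        )
    truth.confounders = confounders

    values = pd.DataFrame(Y, index=G.sample_ids, columns=gene_ids)
    return ExpressionMatrix(
        values=values, gene_annotation=truth.gene_annotation, tag="simulated"
    )


def simulate_dataset(
    config: SimulationConfig, seed: int = 0
) -> tuple[ExpressionMatrix, GenotypeMatrix, SimulationTruth]:
    """One benchmark dataset: genotypes, architecture, expression."""
    ss = np.random.SeedSequence(seed)
    s_geno, s_gene, s_arch, s_expr = [int(c.generate_state(1)[0] % 2**31)
                                      for c in ss.spawn(4)]
    G = simulate_genotypes(config, seed=s_geno)
    gene_pos = simulate_gene_annotation(config, seed=s_gene)
    truth = sample_architecture(G, gene_pos, config, seed=s_arch)
    E = simulate_expression(G, truth, config, seed=s_expr)
    return E, G, truth


def evaluate(
    T: pd.DataFrame,
    truth: SimulationTruth,
    fdr_grid: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2),
) -> dict:
    """ROC/AUC over the p-value ranking and per-category recovery rates.

    Positives are all planted (snp, gene) pairs (broad loci counted per
    pair). AUC is the Mann-Whitney probability that a random positive ranks
    ahead of a random negative; recovery at an FDR threshold is the fraction
    of planted pairs in each category with adjusted p below it.
    """
    truth_set = truth.pair_set()
    keys = list(zip(T["snp"], T["gene"]))
    if not truth_set.issubset(set(keys)):
        raise ValueError("eQTL table does not cover all planted pairs")
    is_pos = np.array([k in truth_set for k in keys])
    p = T["p"].to_numpy(dtype=float)
    p = np.where(np.isnan(p), 1.0, p)

    # AUC via rank-sum on -p (smaller p ranks higher)
    ranks = stats.rankdata(-p)
    n_pos = int(is_pos.sum())
    n_neg = len(p) - n_pos
    auc = (ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(p, kind="stable")
    tp = np.cumsum(is_pos[order])
    fp = np.cumsum(~is_pos[order])
    tpr = tp / n_pos
    fpr = fp / n_neg

    padj = T["p_adj"].to_numpy(dtype=float)
    padj = np.where(np.isnan(padj), 1.0, padj)
    pair_padj = dict(zip(keys, padj))
    recovery: dict[str, dict[float, float]] = {}
    for category in ("cis", "trans", "broad"):
        cat_pairs = truth.pair_set(category)
        if not cat_pairs:
            continue
        recovery[category] = {}
        for thr in fdr_grid:
            hit = sum(1 for k in cat_pairs if pair_padj.get(k, 1.0) < thr)
            recovery[category][thr] = hit / len(cat_pairs)
    return {"auc": float(auc), "roc": {"fpr": fpr, "tpr": tpr}, "recovery": recovery}
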