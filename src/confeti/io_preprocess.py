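"""Loading, QC filtering and covariate construction.

Expression and genotype tables arrive as TSV (header = gene/SNP ids, first
column = sample id), HDF5 (datasets /expression, /sample_ids, /gene_ids) or
PLINK bed/bim/fam. QC mirrors common eQTL practice: drop low-MAF and
LD-redundant SNPs, drop zero-inflated and heavily skewed genes, and derive
genotype principal components for population-structure covariates.
"""

from __future__ import annotations

import logging

import h5py
import numpy as np
import pandas as pd

from . import plink
from .datatypes import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    compute_maf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_expression",
    "save_expression",
    "load_genotypes",
    "load_covariates",
    "filter_genotypes",
    "filter_expression",
    "genotype_pcs",
    "align_samples",
]


def _read_matrix_tsv(path: str, kind: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for col in header:  # read_csv mangles duplicate column names; check raw header
        if col in seen:
            raise ValueError(f"duplicate {kind} id {col!r} in {path}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric cell at row {row!r}, column {col!r} in {path}")
    return df


def load_expression(
    path: str,
    format: str = "tsv",
    annotation_path: str | None = None,
) -> ExpressionMatrix:
    """Load a samples x genes expression matrix with optional gene annotation.

    The annotation file is a TSV with columns gene_id, chromosome, start
    (1-based bp). Genes missing from the annotation are kept but logged;
    they cannot be cis/trans labeled downstream.
    """
    if format == "tsv":
        values = _read_matrix_tsv(path, "gene")
    elif format == "hdf5":
        with h5py.File(path, "r") as fh:
            values = pd.DataFrame(
                fh["/expression"][()],
                index=[s.decode() for s in fh["/sample_ids"][()]],
                columns=[g.decode() for g in fh["/gene_ids"][()]],
            )
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in {path}")
    else:
        raise ValueError(f"unknown expression format {format!r}")

    annotation = pd.DataFrame(columns=["chromosome", "start"])
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", dtype={"chromosome": str})
        ann = ann.set_index("gene_id")[["chromosome", "start"]]
        missing = values.columns.difference(ann.index)
        if len(missing):
            logger.warning(
                "%d genes missing from annotation (excluded from cis/trans labeling)",
                len(missing),
            )
        annotation = ann.reindex(values.columns.intersection(ann.index))
    return ExpressionMatrix(values=values, gene_annotation=annotation)


def save_expression(E: ExpressionMatrix, path: str, format: str = "tsv") -> None:
    if format == "tsv":
        # %.17g round-trips IEEE doubles exactly
        E.values.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("/expression", data=E.values.to_numpy(dtype=float))
            fh.create_dataset(
                "/sample_ids", data=[str(s).encode() for s in E.sample_ids]
            )
            fh.create_dataset("/gene_ids", data=[str(g).encode() for g in E.gene_ids])
    else:
        raise ValueError(f"unknown expression format {format!r}")


def load_genotypes(
    path: str,
    format: str = "plink",
    ploidy: int = 2,
    max_missing_frac: float = 0.0,
    annotation_path: str | None = None,
) -> GenotypeMatrix:
    """Load genotypes as minor-allele counts.

    Missing calls are mean-imputed (rounded to the nearest integer count)
    when a SNP's missingness is at most ``max_missing_frac``; otherwise the
    SNP is dropped. The default of 0 keeps only complete SNPs.
    """
    if format == "plink":
        fam, bim, geno = plink.read_bed(path)
        values = pd.DataFrame(geno, index=fam["iid"].tolist(), columns=bim["snp_id"].tolist())
        annotation = bim.set_index("snp_id")[["chromosome", "position"]]
    elif format == "tsv":
        values = _read_matrix_tsv(path, "snp").astype(float)
        if annotation_path is None:
            raise ValueError("tsv genotypes require an annotation_path")
        ann = pd.read_csv(annotation_path, sep="\t", dtype={"chromosome": str})
        annotation = ann.set_index("snp_id")[["chromosome", "position"]]
        annotation = annotation.reindex(values.columns)
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    arr = values.to_numpy(dtype=float)
    miss_frac = np.isnan(arr).mean(axis=0)
    drop = miss_frac > max_missing_frac
    if drop.any():
        logger.warning("dropping %d SNPs exceeding missingness %.2f", drop.sum(), max_missing_frac)
        values = values.loc[:, ~drop]
        arr = arr[:, ~drop]
        annotation = annotation.loc[values.columns]
    if np.isnan(arr).any():
        col_means = np.nanmean(arr, axis=0)
        idx = np.where(np.isnan(arr))
        arr[idx] = np.rint(col_means[idx[1]])
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    annotation = annotation.astype({"position": np.int64})
    return GenotypeMatrix(values=values, snp_annotation=annotation, ploidy=ploidy)


def load_covariates(path: str) -> CovariateTable:
    return CovariateTable(values=_read_matrix_tsv(path, "covariate").astype(float))


def filter_genotypes(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    ld_r2_max: float = 0.99,
    ld_window: int = 10_000,
) -> GenotypeMatrix:
    """Drop low-MAF SNPs and greedily LD-prune within a bp window.

    SNPs with maf < maf_min (strict) or zero variance are removed, then a
    greedy left-to-right sweep within each chromosome removes any SNP whose
    squared Pearson correlation with an already-retained SNP no more than
    ``ld_window`` bp away exceeds ``ld_r2_max``.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if ld_window <= 0:
        raise ValueError("ld_window must be positive")

    maf = compute_maf(G.values, G.ploidy)
    arr = G.values.to_numpy(dtype=float)
    polymorphic = arr.std(axis=0) > 0
    keep_mask = (maf.to_numpy() >= maf_min) & polymorphic
    snp_ids = G.snp_ids[keep_mask]

    ann = G.snp_annotation.loc[snp_ids]
    kept: list[str] = []
    for chrom, group in ann.groupby("chromosome", sort=False):
        order = group.sort_values("position", kind="stable")
        cols = G.values[order.index].to_numpy(dtype=float)
        pos = order["position"].to_numpy()
        std = (cols - cols.mean(axis=0)) / cols.std(axis=0)
        retained: list[int] = []
        for j in range(cols.shape[1]):
            ok = True
            for i in reversed(retained):
                if pos[j] - pos[i] > ld_window:
                    break
                r = float(std[:, i] @ std[:, j]) / cols.shape[0]
                if r * r > ld_r2_max:
                    ok = False
                    break
            if ok:
                retained.append(j)
        kept.extend(order.index[retained])

    kept_in_order = [s for s in G.snp_ids if s in set(kept)]
    if not kept_in_order:
        logger.warning("all SNPs removed by filtering")
    values = G.values[kept_in_order]
    return GenotypeMatrix(
        values=values,
        snp_annotation=G.snp_annotation.loc[kept_in_order],
        ploidy=G.ploidy,
    )


def filter_expression(
    E: ExpressionMatrix,
    zero_frac_max: float = 0.8,
    tail_frac: float = 0.85,
    tail_quantile: float = 0.2,
    tail_mode: str = "range",
) -> ExpressionMatrix:
    """Remove zero-inflated and heavily skewed genes.

    A gene is dropped when more than ``zero_frac_max`` of its values are
    exactly zero, or when more than ``tail_frac`` of its values fall inside
    its own top or bottom ``tail_quantile`` band. With ``tail_mode="range"``
    (default) the band is a fraction of the gene's value range; ``"quantile"``
    uses rank quantiles instead.
    """
    for name, x in (("zero_frac_max", zero_frac_max), ("tail_frac", tail_frac),
                    ("tail_quantile", tail_quantile)):
        if not 0 < x < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    arr = E.values.to_numpy(dtype=float)
    n = arr.shape[0]
    zero_frac = (arr == 0).mean(axis=0)
    keep = zero_frac <= zero_frac_max

    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    if tail_mode == "range":
        lo_cut = lo + tail_quantile * (hi - lo)
        hi_cut = hi - tail_quantile * (hi - lo)
    elif tail_mode == "quantile":
        lo_cut = np.quantile(arr, tail_quantile, axis=0)
        hi_cut = np.quantile(arr, 1 - tail_quantile, axis=0)
    else:
        raise ValueError(f"unknown tail_mode {tail_mode!r}")
    in_bottom = (arr <= lo_cut).sum(axis=0) / n
    in_top = (arr >= hi_cut).sum(axis=0) / n
    constant = hi == lo
    skewed = ((in_bottom > tail_frac) | (in_top > tail_frac)) & ~constant
    keep &= ~skewed

    if not keep.any():
        raise ValueError("all genes removed by expression filters")
    values = E.values.loc[:, keep]
    ann = E.gene_annotation.reindex(values.columns.intersection(E.gene_annotation.index))
    return ExpressionMatrix(values=values, gene_annotation=ann, tag=E.tag)


def genotype_pcs(G: GenotypeMatrix, n_pcs: int) -> CovariateTable:
    """Top left singular directions of the column-standardized genotypes.

    Columns are unit-norm, mutually orthogonal, with the sign of each fixed
    so its largest-magnitude entry is positive — the usual population
    structure covariates.
    """
    if n_pcs >= G.n_samples:
        raise ValueError("n_pcs must be smaller than the number of samples")
    arr = G.values.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    poly = sd > 0
    Z = (arr[:, poly] - arr[:, poly].mean(axis=0)) / sd[poly]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds genotype matrix rank {rank}")
    pcs = U[:, :n_pcs]
    flip = np.sign(pcs[np.abs(pcs).argmax(axis=0), np.arange(n_pcs)])
    pcs = pcs * flip
    cols = [f"genoPC{i + 1}" for i in range(n_pcs)]
    return CovariateTable(values=pd.DataFrame(pcs, index=G.sample_ids, columns=cols))


def align_samples(
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    C: CovariateTable | None = None,
) -> tuple[ExpressionMatrix, GenotypeMatrix, CovariateTable | None]:
    """Restrict all inputs to their common samples, in expression-file order."""
    common = [s for s in E.sample_ids if s in set(G.sample_ids)]
    if C is not None:
        cset = set(C.sample_ids)
        common = [s for s in common if s in cset]
    if not common:
        raise ValueError("expression and genotype sample sets are disjoint")
    dropped = len(E.sample_ids) - len(common)
    if dropped:
        logger.info("dropping %d samples absent from some input", dropped)
    E2 = ExpressionMatrix(E.values.loc[common], E.gene_annotation, E.tag)
    G2 = GenotypeMatrix(G.values.loc[common], G.snp_annotation, G.ploidy)
    C2 = CovariateTable(C.values.loc[common]) if C is not None else None
    return E2, G2, C2
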