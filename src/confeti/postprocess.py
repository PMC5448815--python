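"""Post-scan eQTL curation: cis/trans labels, cytoband collapsing,
pseudo-trans screening, replication counting and broad-impact detection.

The pipeline order is label -> screen -> collapse -> replicate -> detect:
an association is cis when SNP and gene share a chromosome within a distance
window (1 Mb for real data), apparent trans hits near a relative or
homologous region of their gene are discarded as cross-mapping artifacts,
linked SNPs are collapsed to one record per (gene, cytoband, label), and a
broad-impact locus is a genotype whose replicating trans associations span
at least two genes on at least two chromosomes other than its own.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationBundle,
    ExpressionMatrix,
    GenotypeMatrix,
    ReplicationReport,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_cytobands",
    "load_gene_relations",
    "load_homology_regions",
    "label_cis_trans",
    "collapse_per_cytoband",
    "pseudo_trans_screen",
    "count_replication",
    "detect_broad_impact",
]

FALLBACK_BIN = 1_000_000


def load_cytobands(path: str) -> pd.DataFrame:
    """UCSC cytoBand format: chrom, start, end, band, stain (0-based
    half-open on disk, converted to 1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] < df["start"]).any():
        raise ValueError("degenerate cytoband interval")
    return df[["chrom", "start", "end", "band"]]


def load_gene_relations(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "related_gene_id"],
                     dtype=str)
    return df


def load_homology_regions(path: str) -> pd.DataFrame:
    """BED (0-based half-open) with the name column carrying the gene id."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    return df[["gene_id", "chrom", "start", "end"]]


def _gene_positions(E: ExpressionMatrix) -> pd.DataFrame:
    ann = E.gene_annotation
    return ann[["chromosome", "start"]]


def label_cis_trans(
    T: pd.DataFrame,
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """cis iff same chromosome and |SNP position - gene start| <= window
    (boundary inclusive); genes without annotation stay unlabeled."""
    gene_ann = _gene_positions(E)
    snp_ann = G.snp_annotation
    out = T.copy()
    gc = out["gene"].map(gene_ann["chromosome"])
    gs = out["gene"].map(gene_ann["start"])
    sc = out["snp"].map(snp_ann["chromosome"])
    sp = out["snp"].map(snp_ann["position"])
    known = gc.notna() & sc.notna()
    same = (gc == sc) & known
    dist = (sp - gs).abs()
    out["label"] = np.where(
        ~known, "unlabeled", np.where(same & (dist <= window), "cis", "trans")
    )
    return out


def _assign_cytoband(
    snp_ann: pd.DataFrame, cytobands: pd.DataFrame | None, fallback: bool = True
) -> pd.Series:
    """Map each SNP to a cytoband name, or to a fixed 1-Mb bin without a table."""
    out = pd.Series(index=snp_ann.index, dtype=object)
    if cytobands is not None and len(cytobands):
        for chrom, grp in snp_ann.groupby("chromosome", sort=False):
            bands = cytobands[cytobands["chrom"] == str(chrom)]
            pos = grp["position"].to_numpy()
            assigned = np.full(len(grp), None, dtype=object)
            for _, band in bands.iterrows():
                inside = (pos >= band["start"]) & (pos <= band["end"])
                assigned[inside & (assigned == None)] = f"{chrom}:{band['band']}"  # noqa: E711
            out.loc[grp.index] = assigned
    unmapped = out.isna()
    if unmapped.any():
        if cytobands is not None and len(cytobands):
            logger.warning(
                "%d SNPs outside any cytoband; using %d-bp bins", unmapped.sum(), FALLBACK_BIN
            )
        if not fallback:
            raise ValueError("SNPs outside cytobands and bin fallback disabled")
        sub = snp_ann.loc[unmapped[unmapped].index]
        out.loc[sub.index] = (
            sub["chromosome"].astype(str)
            + ":bin"
            + ((sub["position"] - 1) // FALLBACK_BIN).astype(str)
        )
    return out


def collapse_per_cytoband(
    T: pd.DataFrame,
    G: GenotypeMatrix,
    A: AnnotationBundle | None = None,
    fdr_threshold: float = 0.01,
    fallback: bool = True,
) -> pd.DataFrame:
    """Keep, per (gene, cytoband, label), the significant record with the
    smallest p (ties broken by smallest SNP position)."""
    cyto = A.cytobands if A is not None else None
    if cyto is None and not fallback:
        raise ValueError("no cytoband table and bin fallback disabled")
    sig = T[T["p_adj"] < fdr_threshold].copy()
    if not len(sig):
        sig["cytoband"] = pd.Series(dtype=object)
        return sig
    band = _assign_cytoband(G.snp_annotation, cyto, fallback=fallback)
    sig["cytoband"] = sig["snp"].map(band)
    sig["_pos"] = sig["snp"].map(G.snp_annotation["position"])
    sig = sig.sort_values(["p", "_pos"], kind="stable")
    out = sig.drop_duplicates(subset=["gene", "cytoband", "label"], keep="first")
    return out.drop(columns="_pos").reset_index(drop=True)


def pseudo_trans_screen(
    T: pd.DataFrame,
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    A: AnnotationBundle,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Drop trans records plausibly caused by cross-mapping.

    A trans record is removed when its SNP lies within ``window`` bp of the
    start of any gene related to the eQTL gene (pseudogene/parent pairs), or
    within ``window`` bp of any homology region of the eQTL gene. Cis and
    unlabeled records pass through untouched.
    """
    rel = A.gene_relations
    hom = A.homology_regions
    if (rel is None or not len(rel)) and (hom is None or not len(hom)):
        logger.warning("no relation or homology annotation; pseudo-trans screen is a no-op")
        return T.copy()

    gene_ann = _gene_positions(E)
    snp_ann = G.snp_annotation
    trans = T["label"] == "trans"
    drop = np.zeros(len(T), dtype=bool)
    sc = T["snp"].map(snp_ann["chromosome"])
    sp = T["snp"].map(snp_ann["position"])

    if rel is not None and len(rel):
        related = rel.groupby("gene_id")["related_gene_id"].agg(list)
        for i in np.where(trans.to_numpy())[0]:
            row = T.iloc[i]
            for rg in related.get(row["gene"], []):
                if rg not in gene_ann.index:
                    continue
                if (
                    str(gene_ann.loc[rg, "chromosome"]) == str(sc.iloc[i])
                    and abs(int(gene_ann.loc[rg, "start"]) - int(sp.iloc[i])) <= window
                ):
                    drop[i] = True
                    logger.info(
                        "pseudo-trans: %s ~ %s near related gene %s",
                        row["gene"], row["snp"], rg,
                    )
                    break

    if hom is not None and len(hom):
        by_gene = hom.groupby("gene_id")
        for i in np.where(trans.to_numpy() & ~drop)[0]:
            row = T.iloc[i]
            if row["gene"] not in by_gene.groups:
                continue
            regions = by_gene.get_group(row["gene"])
            for _, reg in regions.iterrows():
                if str(reg["chrom"]) != str(sc.iloc[i]):
                    continue
                pos = int(sp.iloc[i])
                if reg["start"] - window <= pos <= reg["end"] + window:
                    drop[i] = True
                    logger.info(
                        "pseudo-trans: %s ~ %s near homology region %s:%d-%d",
                        row["gene"], row["snp"], reg["chrom"], reg["start"], reg["end"],
                    )
                    break

    return T.loc[~drop].reset_index(drop=True)


def count_replication(
    T1: pd.DataFrame, T2: pd.DataFrame, fdr_threshold: float = 0.01
) -> ReplicationReport:
    """Overlap / union of significant (gene, cytoband, label) keys per label."""
    def keys(t):
        sig = t[t["p_adj"] < fdr_threshold]
        return set(zip(sig["gene"], sig["cytoband"], sig["label"]))

    k1, k2 = keys(T1), keys(T2)
    overlap = k1 & k2
    union = k1 | k2
    labels = sorted({k[2] for k in union})
    n_overlap = {lab: sum(1 for k in overlap if k[2] == lab) for lab in labels}
    n_union = {lab: sum(1 for k in union if k[2] == lab) for lab in labels}
    ratio = {
        lab: (n_overlap[lab] / n_union[lab]) if n_union[lab] else 0.0 for lab in labels
    }
    n_overlap["all"] = len(overlap)
    n_union["all"] = len(union)
    ratio["all"] = len(overlap) / len(union) if union else 0.0
    rep = pd.DataFrame(sorted(overlap), columns=["gene", "cytoband", "label"])
    return ReplicationReport(
        n_overlap=n_overlap,
        n_union=n_union,
        replication_ratio=ratio,
        replicating=rep,
        table_1=T1,
        table_2=T2,
    )


def detect_broad_impact(
    R: ReplicationReport,
    G: GenotypeMatrix,
    E: ExpressionMatrix,
    key: str = "cytoband",
) -> list[dict]:
    """Loci whose replicating trans associations span >= 2 genes on >= 2
    chromosomes, each distinct from the locus's own chromosome.

    ``key`` groups replicating trans hits by cytoband (default) or by snp.
    """
    rep = R.replicating
    trans = rep[rep["label"] == "trans"]
    if not len(trans):
        return []
    gene_ann = _gene_positions(E)

    # locus chromosome: parse from the cytoband/bin name prefix
    out = []
    for locus, grp in trans.groupby(key, sort=False):
        locus_chrom = str(locus).split(":")[0]
        genes = sorted(set(grp["gene"]))
        chroms = {
            str(gene_ann.loc[g, "chromosome"])
            for g in genes
            if g in gene_ann.index
        }
        other = chroms - {locus_chrom}
        if len(genes) >= 2 and len(other) >= 2:
            out.append(
                {"locus": locus, "trans_genes": genes, "chromosomes": sorted(other)}
            )
    return out
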