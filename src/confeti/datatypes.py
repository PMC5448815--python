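"""Core in-memory containers shared across the pipeline.

All matrices are pandas DataFrames with sample identifiers on the row index,
so that alignment between expression, genotype and covariate data is always
explicit. Gene/SNP genomic annotations use 1-based inclusive base-pair
coordinates throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GenotypeMatrix",
    "CovariateTable",
    "IcaDecomposition",
    "SampleCovariance",
    "ComponentFlagResult",
    "SplitPlan",
    "AnnotationBundle",
    "ReplicationReport",
]


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with per-gene genomic annotation.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are gene ids. All entries
        must be finite.
    gene_annotation
        DataFrame indexed by gene id with columns ``chromosome`` (str) and
        ``start`` (1-based bp). Genes absent from the annotation are retained
        in ``values`` but cannot be cis/trans labeled.
    tag
        Free-text provenance: ``raw``, ``reconstructed-nongenetic`` or
        ``simulated``.
    """

    values: pd.DataFrame
    gene_annotation: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chromosome", "start"])
    )
    tag: str = "raw"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr.astype(float))):
            raise ValueError("expression values must be finite")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele counts with SNP positions.

    ``values`` entries are in {0, 1, 2} (diploid) or {0, 1} (haploid); no
    missing values are allowed after loading. ``maf`` is the per-SNP minor
    allele frequency in [0, 0.5].
    """

    values: pd.DataFrame
    snp_annotation: pd.DataFrame
    ploidy: int = 2
    maf: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate snp id: {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and np.isnan(arr.astype(float)).any():
            raise ValueError("genotype matrix contains missing values")
        if self.maf is None:
            self.maf = compute_maf(self.values, self.ploidy)

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


def compute_maf(values: pd.DataFrame, ploidy: int = 2) -> pd.Series:
    """Minor allele frequency: min(f, 1 - f) of the counted allele."""
    freq = values.to_numpy(dtype=float).sum(axis=0) / (ploidy * values.shape[0])
    return pd.Series(np.minimum(freq, 1.0 - freq), index=values.columns, name="maf")


@dataclass
class CovariateTable:
    """Samples x covariates design columns (genotype PCs, batch, ...)."""

    values: pd.DataFrame

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]


@dataclass
class IcaDecomposition:
    """Result of the independent component decomposition Y_c = A S.

    ``A`` (n x k) holds per-sample mixing coefficients, ``S`` (k x g) the
    per-gene source weights. Rows of S have unit variance and the entry of
    largest magnitude in each row is positive; A absorbs the complementary
    scale and sign. ``center`` is the per-gene mean removed before the
    decomposition.
    """

    A: np.ndarray
    S: np.ndarray
    k: int
    center: np.ndarray
    seed: int
    converged: bool
    n_iter: int
    sample_ids: pd.Index
    gene_ids: pd.Index

    @property
    def n_samples(self) -> int:
        return self.A.shape[0]

    @property
    def n_genes(self) -> int:
        return self.S.shape[1]


@dataclass
class SampleCovariance:
    """n x n symmetric PSD sample covariance used as the random effect.

    The eigendecomposition is computed eagerly and cached; small negative
    eigenvalues (> -1e-8) from round-off are clipped to zero, anything more
    negative raises, signalling a numerical failure upstream.
    """

    K: np.ndarray
    method: str
    sample_ids: pd.Index
    provenance: dict = field(default_factory=dict)
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("K must be symmetric to 1e-10")
        self.K = (K + K.T) / 2.0
        w, v = np.linalg.eigh(self.K)
        if w.min(initial=0.0) < -1e-8:
            raise ValueError(
                f"K has eigenvalue {w.min():.3e} < -1e-8; not PSD"
            )
        self.eigenvalues = np.clip(w, 0.0, None)
        self.eigenvectors = v

    @property
    def n_samples(self) -> int:
        return self.K.shape[0]


@dataclass
class ComponentFlagResult:
    """Per-component genotype-association screen outcome.

    ``flagged`` holds the indices of components whose minimum association
    p-value clears the global Bonferroni threshold alpha / n_tests.
    """

    min_p: np.ndarray
    best_snp: list
    flagged: set
    alpha: float
    n_tests: int
    genotype_subset: set | None = None


@dataclass
class SplitPlan:
    """Random half-split of the SNP set for the leave-out filtering strategy."""

    subset_1: set
    subset_2: set
    seed: int

    def __post_init__(self) -> None:
        if self.subset_1 & self.subset_2:
            raise ValueError("split subsets must be disjoint")
        if abs(len(self.subset_1) - len(self.subset_2)) > 1:
            raise ValueError("split subset sizes must differ by at most 1")


@dataclass
class AnnotationBundle:
    """Cytobands, gene relations and homology regions for postprocessing.

    ``cytobands``: DataFrame(chrom, start, end, band); 1-based inclusive.
    ``gene_relations``: DataFrame(gene_id, related_gene_id); symmetric after
    loading. ``homology_regions``: DataFrame(gene_id, chrom, start, end)
    covering genomic regions matching >= 50% of the gene's transcript.
    """

    cytobands: pd.DataFrame | None = None
    gene_relations: pd.DataFrame | None = None
    homology_regions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.gene_relations is not None and len(self.gene_relations):
            rel = self.gene_relations[["gene_id", "related_gene_id"]]
            flipped = rel.rename(
                columns={"gene_id": "related_gene_id", "related_gene_id": "gene_id"}
            )
            self.gene_relations = (
                pd.concat([rel, flipped[["gene_id", "related_gene_id"]]])
                .drop_duplicates()
                .reset_index(drop=True)
            )


@dataclass
class ReplicationReport:
    """Replication of collapsed eQTL between two datasets.

    Keys are (gene, cytoband, label); ``replication_ratio`` is overlap/union
    per label.
    """

    n_overlap: dict
    n_union: dict
    replication_ratio: dict
    replicating: pd.DataFrame
    table_1: pd.DataFrame | None = None
    table_2: pd.DataFrame | None = None
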