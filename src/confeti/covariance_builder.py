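"""Build the random-effect sample covariance from expression data.

CONFETI-I: reconstruct the expression signal attributable to non-genetic
components (Y* = A* S* over the unflagged components), location-scale
normalize each gene, and take the n x n sample covariance across genes.
ICE: the same covariance computed from the full observed expression matrix,
the classic intersample-correlation baseline. With nothing flagged and
centering-only ICA preprocessing the two coincide.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    ComponentFlagResult,
    ExpressionMatrix,
    IcaDecomposition,
    SampleCovariance,
)

logger = logging.getLogger(__name__)

__all__ = ["reconstruct_nongenetic", "build_confeti_k", "build_ice_k"]


def reconstruct_nongenetic(
    D: IcaDecomposition, flags: ComponentFlagResult
) -> ExpressionMatrix:
    """Y* = A[:, unflagged] @ S[unflagged, :], tagged reconstructed-nongenetic."""
    bad = {j for j in flags.flagged if not 0 <= j < D.k}
    if bad:
        raise ValueError(f"flagged indices {sorted(bad)} out of range for k={D.k}")
    keep = [j for j in range(D.k) if j not in flags.flagged]
    if not keep:
        logger.warning("all %d components flagged; reconstruction is identically zero", D.k)
        ystar = np.zeros((D.n_samples, D.n_genes))
    else:
        ystar = D.A[:, keep] @ D.S[keep, :]
    values = pd.DataFrame(ystar, index=D.sample_ids, columns=D.gene_ids)
    return ExpressionMatrix(values=values, tag="reconstructed-nongenetic")


def _standardized_covariance(values: pd.DataFrame, method: str, provenance: dict) -> SampleCovariance:
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    usable = sd > 0
    if usable.sum() < 2:
        raise ValueError("need at least 2 genes with nonzero variance to build K")
    if not usable.all():
        logger.warning("dropping %d zero-variance genes from covariance", (~usable).sum())
    Z = (arr[:, usable] - mu[usable]) / sd[usable]
    g = Z.shape[1]
    K = Z @ Z.T / (g - 1)
    return SampleCovariance(
        K=K,
        method=method,
        sample_ids=values.index,
        provenance={**provenance, "n_genes_used": int(g)},
    )


def build_confeti_k(Ystar: ExpressionMatrix, provenance: dict | None = None) -> SampleCovariance:
    """Sample covariance of the gene-standardized non-genetic reconstruction."""
    return _standardized_covariance(Ystar.values, "confeti_i", provenance or {})


def build_ice_k(E: ExpressionMatrix) -> SampleCovariance:
    """Sample covariance of the gene-standardized observed expression."""
    return _standardized_covariance(E.values, "ice", {})
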