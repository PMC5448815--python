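"""End-to-end orchestration: decompose, filter, build K, scan.

``run_confeti`` wires the stages together for the common case; each stage
remains available individually for custom workflows. The optional split
strategy uses one random half of the SNPs to flag genetic components and
scans the other half, then flips the roles and concatenates, so no genotype
is both filtered on and tested.
"""

from __future__ import annotations

import pandas as pd

from .covariance_builder import build_confeti_k, build_ice_k, reconstruct_nongenetic
from .datatypes import CovariateTable, ExpressionMatrix, GenotypeMatrix
from .genetic_filter import flag_genetic_components, make_split_plan
from .ica_engine import decompose, select_component_count
from .lmm_scan import bh_adjust, scan

__all__ = ["run_confeti", "build_covariance"]


def build_covariance(
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    method: str = "confeti_i",
    variance_target: float = 0.95,
    k: int | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    genotype_subset: set | None = None,
):
    """Build the requested sample covariance; returns (K, decomposition, flags)."""
    if method == "ice":
        return build_ice_k(E), None, None
    if method != "confeti_i":
        raise ValueError(f"unknown covariance method {method!r}")
    if k is None:
        k = select_component_count(E, variance_target)
    D = decompose(E, k, seed=seed)
    flags = flag_genetic_components(D, G, alpha=alpha, genotype_subset=genotype_subset)
    ystar = reconstruct_nongenetic(D, flags)
    K = build_confeti_k(
        ystar,
        provenance={"k": D.k, "r": len(flags.flagged), "flagged": sorted(flags.flagged)},
    )
    return K, D, flags


def run_confeti(
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    C: CovariateTable | None = None,
    method: str = "confeti_i",
    variance_target: float = 0.95,
    k: int | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    split: bool = False,
    mode: str = "null_fixed",
) -> pd.DataFrame:
    """Full scan with the chosen confounder correction.

    ``method``: confeti_i | ice | pca_fixed | linear. With ``split=True``
    (confeti_i only) the SNPs are halved: flag on one half, scan the other,
    flip, concatenate, and re-adjust p-values globally.
    """
    if method in ("linear", "pca_fixed"):
        return scan(E, G, K=None, C=C, method=method, mode=mode)
    if method == "ice":
        K, _, _ = build_covariance(E, G, method="ice")
        return scan(E, G, K=K, C=C, method="ice", mode=mode)
    if method != "confeti_i":
        raise ValueError(f"unknown method {method!r}")

    if not split:
        K, _, _ = build_covariance(
            E, G, method="confeti_i", variance_target=variance_target,
            k=k, seed=seed, alpha=alpha,
        )
        return scan(E, G, K=K, C=C, method="confeti_i", mode=mode)

    plan = make_split_plan(G, seed=seed)
    parts = []
    for filter_set, test_set in ((plan.subset_1, plan.subset_2),
                                 (plan.subset_2, plan.subset_1)):
        K, _, _ = build_covariance(
            E, G, method="confeti_i", variance_target=variance_target,
            k=k, seed=seed, alpha=alpha, genotype_subset=filter_set,
        )
        test_ids = [s for s in G.snp_ids if s in test_set]
        G_test = GenotypeMatrix(
            values=G.values[test_ids],
            snp_annotation=G.snp_annotation.loc[test_ids],
            ploidy=G.ploidy,
        )
        parts.append(scan(E, G_test, K=K, C=C, method="confeti_i", mode=mode))
    table = pd.concat(parts, ignore_index=True)
    valid = table["p"].notna()
    table.loc[valid, "p_adj"] = bh_adjust(table.loc[valid, "p"].to_numpy())
    return table
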