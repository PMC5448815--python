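"""Independent component decomposition of the expression matrix.

The centered expression matrix Y_c (samples x genes) is decomposed as
Y_c = A S, where rows of S are maximally non-Gaussian per-gene source
weights and A holds per-sample mixing coefficients. The component count k
is chosen so the retained PCA subspace explains a target fraction of the
variance (default 95%), making mixed-model corrections built from the
decomposition comparable across methods that take k as an input.

Conventions fixed here: genes are mean-centered only before the
decomposition; each row of S is scaled to unit variance with its
largest-magnitude entry positive, A absorbing the complementary scale;
components are ordered by decreasing variance of their A column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .datatypes import ExpressionMatrix, IcaDecomposition

logger = logging.getLogger(__name__)

__all__ = ["select_component_count", "decompose", "component_stability"]


def select_component_count(E: ExpressionMatrix, variance_target: float = 0.95) -> int:
    """Smallest k whose top-k principal components reach the variance target."""
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    Y = E.values.to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=0)
    s = np.linalg.svd(Yc, compute_uv=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("expression matrix is constant; zero total variance")
    frac = np.cumsum(var) / total
    k = int(np.searchsorted(frac, variance_target - 1e-12) + 1)
    return min(k, min(E.n_samples, E.n_genes) - 1) if k >= min(E.n_samples, E.n_genes) else k


def decompose(
    E: ExpressionMatrix,
    k: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 1000,
    standardize: bool = False,
    n_restarts: int = 3,
) -> IcaDecomposition:
    """Symmetric fixed-point FastICA (log-cosh contrast) on centered data.

    Whitening projects onto the top-k principal components, so the column
    space of A equals the retained PCA subspace and A @ S reproduces the
    k-PC truncation of the centered matrix. On non-convergence the run is
    restarted with incremented seeds up to ``n_restarts`` times before
    returning ``converged=False``.
    """
    n, g = E.values.shape
    if k > min(n, g):
        raise ValueError(f"k={k} exceeds min(n_samples, n_genes)={min(n, g)}")
    Y = E.values.to_numpy(dtype=float)
    center = Y.mean(axis=0)
    Yc = Y - center
    sd = Yc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = E.gene_ids[np.where(sd == 0)[0][0]]
        raise ValueError(
            f"gene {bad!r} has zero variance; run filter_expression first"
        )
    if standardize:
        Yc = Yc / sd

    # Whiten in the gene-observation orientation: genes are the i.i.d.
    # observations whose component weights (rows of S) are made maximally
    # non-Gaussian, so FastICA reduces to an orthogonal rotation of the
    # top-k principal subspace and A @ S reproduces the k-PC truncation.
    U, sv, Vt = np.linalg.svd(Yc, full_matrices=False)
    if sv[k - 1] <= sv[0] * 1e-12:
        raise ValueError(f"centered expression matrix has rank < k={k}")
    Xw = np.sqrt(g) * Vt[:k].T  # (g, k), identity covariance across genes

    converged = False
    attempt_seed = seed
    n_iter = 0
    S = None
    for _ in range(n_restarts + 1):
        def _run(seed_):
            # n_components omitted: Xw already has exactly k columns
            ica = FastICA(
                algorithm="parallel",
                fun="logcosh",
                whiten=False,
                tol=tol,
                max_iter=max_iter,
                random_state=seed_,
            )
            src = ica.fit_transform(Xw)  # (g, k) rotated gene weights
            return src, ica.n_iter_

        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                src, n_iter = _run(attempt_seed)
                converged = True
            except ConvergenceWarning:
                warnings.simplefilter("ignore", ConvergenceWarning)
                src, n_iter = _run(attempt_seed)
                converged = False
        S = src.T  # (k, g)
        if converged:
            break
        attempt_seed += 1
        logger.info("FastICA did not converge; restarting with seed %d", attempt_seed)
    # S = R^T sqrt(g) V_k^T with R orthogonal, hence S S^T = g I and the
    # least-squares mixing matrix is exact:
    A = Yc @ S.T / g

    # unit-variance rows of S, sign so largest |entry| is positive; A absorbs
    row_sd = S.std(axis=1, ddof=1)
    row_sd[row_sd == 0] = 1.0
    sign = np.sign(S[np.arange(k), np.abs(S).argmax(axis=1)])
    sign[sign == 0] = 1.0
    scale = sign / row_sd
    S = S * scale[:, None]
    A = A / scale[None, :]

    order = np.argsort(-A.var(axis=0, ddof=1), kind="stable")
    A, S = A[:, order], S[order]

    return IcaDecomposition(
        A=A,
        S=S,
        k=k,
        center=center if not standardize else center / 1.0,
        seed=seed,
        converged=converged,
        n_iter=int(n_iter),
        sample_ids=E.sample_ids,
        gene_ids=E.gene_ids,
    )


@dataclass
class StabilityReport:
    """Fraction of repeated runs in which each component of run 1 recurs."""

    replication_fraction: np.ndarray
    n_runs: int
    match_threshold: float


def component_stability(
    E: ExpressionMatrix,
    k: int,
    n_runs: int = 5,
    match_threshold: float = 0.9,
    seed: int = 0,
    seeds: list[int] | None = None,
    **decompose_kwargs,
) -> StabilityReport:
    """Replication diagnostic across independent FastICA runs.

    Components of the first run are greedily matched to each later run by
    maximal absolute Pearson correlation of their S rows; the report gives,
    per component, the fraction of later runs containing a match with
    |correlation| >= ``match_threshold``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if seeds is None:
        seeds = [seed + i for i in range(n_runs)]
    runs = [decompose(E, k, seed=s, **decompose_kwargs) for s in seeds[:n_runs]]
    ref = runs[0].S
    hits = np.zeros(k)
    for other in runs[1:]:
        corr = np.abs(np.corrcoef(ref, other.S)[:k, k:])
        matched_cols: set[int] = set()
        # greedy: best global match first
        order = np.dstack(np.unravel_index(np.argsort(-corr, axis=None), corr.shape))[0]
        matched_rows: set[int] = set()
        for i, j in order:
            if i in matched_rows or j in matched_cols:
                continue
            matched_rows.add(int(i))
            matched_cols.add(int(j))
            if corr[i, j] >= match_threshold:
                hits[i] += 1
            if len(matched_rows) == k:
                break
    return StabilityReport(
        replication_fraction=hits / (n_runs - 1),
        n_runs=n_runs,
        match_threshold=match_threshold,
    )
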