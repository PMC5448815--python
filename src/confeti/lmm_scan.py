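"""Genome-wide mixed-model eQTL scan with a fixed random-effect covariance.

Per gene p the model is

    y_p = X beta_p + c_p + eps_p,   c_p ~ N(0, tau_p^2 K),   eps_p ~ N(0, sigma_p^2 I)

with X holding the genotype (minor-allele counts), an intercept and optional
covariates. Writing K = U D U^T, rotating y and X by U^T makes the marginal
covariance diagonal, s^2 (h^2 D + (1 - h^2) I) with h^2 = tau^2/(tau^2+sigma^2),
so the profiled ML over h^2 is a cheap one-dimensional search and beta follows
by generalized least squares. Significance is a Wald test of the genotype
coefficient against the standard normal (squared: 1-df chi-square), the
convention the per-gene genomic inflation factor assumes.

Scan modes: ``null_fixed`` (default) estimates the variance components once
per gene under the covariates-only model and reuses them for every SNP
(EMMAX-style); ``exact`` re-optimizes per SNP. Fixed-effect baselines:
``linear`` (no correction) and ``pca_fixed`` (expression PCs as covariates,
count set by a sample-size rule) use ordinary least squares with the same
Wald convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    SampleCovariance,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LmmFit",
    "fit_gene_lmm",
    "scan",
    "genomic_inflation",
    "bh_adjust",
    "pca_factor_count",
]

H2_MAX = 1.0 - 1e-6
_GRID_SIZE = 64


@dataclass
class LmmFit:
    """Single-gene, single-SNP mixed model fit."""

    beta: np.ndarray
    se_beta: np.ndarray
    wald: float
    p: float
    tau2: float
    sigma2: float
    h2: float
    loglik: float


def _neg_profile_loglik(h2: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    w = h2 * d + (1.0 - h2)
    Xw = Xr / w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    resid = yr - Xr @ beta
    n = yr.shape[0]
    rss = float(resid @ (resid / w))
    if rss <= 0:
        rss = np.finfo(float).tiny
    s2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + n + np.log(w).sum())
    return -ll


def _optimize_h2(d: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> tuple[float, float]:
    """Grid-bracketed bounded search for the ML heritability ratio."""
    # log-spaced toward both edges plus a linear fill
    edges = 1.0 - np.logspace(-6, -0.31, _GRID_SIZE // 4)
    grid = np.unique(
        np.concatenate(
            [
                [0.0, H2_MAX],
                np.logspace(-6, -0.31, _GRID_SIZE // 4),
                np.linspace(0.0, H2_MAX, _GRID_SIZE // 2),
                edges,
            ]
        )
    )
    vals = np.array([_neg_profile_loglik(h, d, yr, Xr) for h in grid])
    i = int(vals.argmin())
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi - lo < 1e-12:
        return float(grid[i]), float(-vals[i])
    res = optimize.minimize_scalar(
        _neg_profile_loglik,
        bounds=(lo, hi),
        args=(d, yr, Xr),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if res.fun <= vals[i]:
        return float(res.x), float(-res.fun)
    return float(grid[i]), float(-vals[i])


def _gls_at(h2: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray):
    w = h2 * d + (1.0 - h2)
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    resid = yr - Xr @ beta
    n = yr.shape[0]
    s2 = float(resid @ (resid / w)) / n
    cov = s2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    return beta, se, s2, w


def fit_gene_lmm(
    y: np.ndarray,
    X: np.ndarray,
    K: SampleCovariance,
    mode: str = "exact",
    wald_reference: str = "normal",
) -> LmmFit:
    """Fit the mixed model for one gene and one genotype.

    ``X`` columns are ordered genotype first, then intercept and covariates.
    ``mode="null_fixed"`` profiles the variance components under the
    covariates-only model (genotype column removed) and holds them fixed for
    the genotype test; ``mode="exact"`` profiles them under the full design.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[0]
    if y.std() == 0:
        raise ValueError("zero-variance expression vector")
    U = K.eigenvectors
    d = K.eigenvalues
    yr = U.T @ y
    Xr = U.T @ X

    # collinearity of genotype with the remaining design
    rest = Xr[:, 1:]
    if rest.size:
        proj = rest @ np.linalg.lstsq(rest, Xr[:, 0], rcond=None)[0]
        resid_g = Xr[:, 0] - proj
    else:
        resid_g = Xr[:, 0]
    if float(resid_g @ resid_g) <= 1e-12 * max(float(Xr[:, 0] @ Xr[:, 0]), 1e-300):
        logger.warning("genotype collinear with covariates; returning NaN p")
        nan = np.full(X.shape[1], np.nan)
        return LmmFit(nan, nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)

    if mode == "null_fixed":
        null_X = Xr[:, 1:] if X.shape[1] > 1 else (U.T @ np.ones((n, 1)))
        h2, ll = _optimize_h2(d, yr, null_X)
        _, _, s2_null, w = _gls_at(h2, d, yr, null_X)
        # EMMAX-style: null-model variance components reused for the SNP test
        Xw = Xr / w[:, None]
        XtWX = Xr.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yr)
        cov = s2_null * np.linalg.inv(XtWX)
        se = np.sqrt(np.diag(cov))
        s2 = s2_null
        w_h2 = h2
    elif mode == "exact":
        w_h2, ll = _optimize_h2(d, yr, Xr)
        beta, se, s2, w = _gls_at(w_h2, d, yr, Xr)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    z = beta[0] / se[0]
    wald = float(z * z)
    if wald_reference == "normal":
        p = float(stats.chi2.sf(wald, 1))
    elif wald_reference == "t":
        p = float(2 * stats.t.sf(abs(z), n - X.shape[1]))
    else:
        raise ValueError(f"unknown wald_reference {wald_reference!r}")
    total = s2
    tau2 = w_h2 * total
    sigma2 = (1.0 - w_h2) * total
    return LmmFit(beta, se, wald, p, tau2, sigma2, w_h2, float(ll))


def pca_factor_count(n_samples: int, n_covariates: int, small_n_factors: int = 10) -> int:
    """Expression-PC count by sample size: 30 for 150-250 samples, 35 above,
    a configurable default below 150; capped at n - v - 3."""
    if n_samples > 250:
        k = 35
    elif n_samples >= 150:
        k = 30
    else:
        k = small_n_factors
    return max(1, min(k, n_samples - n_covariates - 3))


def _ols_scan_gene(y, cov_design, Gmat, wald_reference="normal"):
    """Vectorized OLS of one gene on every SNP given shared covariates."""
    n = y.shape[0]
    Q, _ = np.linalg.qr(cov_design)
    My = y - Q @ (Q.T @ y)
    MG = Gmat - Q @ (Q.T @ Gmat)
    gss = (MG**2).sum(axis=0)
    ok = gss > 1e-12 * np.maximum((Gmat**2).sum(axis=0), 1e-300)
    beta = np.where(ok, (MG * My[:, None]).sum(axis=0) / np.where(ok, gss, 1.0), np.nan)
    rss = (My @ My) - beta**2 * gss
    rss = np.maximum(rss, np.finfo(float).tiny)
    s2 = rss / n  # ML scale, matching the mixed-model Wald convention
    se = np.sqrt(s2 / np.where(ok, gss, 1.0))
    z = beta / se
    if wald_reference == "normal":
        p = stats.chi2.sf(z**2, 1)
    else:
        df = n - cov_design.shape[1] - 1
        p = 2 * stats.t.sf(np.abs(z), df)
    p = np.where(ok, p, np.nan)
    beta = np.where(ok, beta, np.nan)
    se = np.where(ok, se, np.nan)
    return beta, se, p


def _lmm_scan_gene(yr, covrot, Grot, d, mode, wald_reference="normal"):
    """Per-gene mixed-model scan over all rotated SNP columns."""
    n = yr.shape[0]
    h2, _ = _optimize_h2(d, yr, covrot)
    w = h2 * d + (1.0 - h2)
    sw = np.sqrt(w)
    yt = yr / sw
    Ct = covrot / sw[:, None]
    Gt = Grot / sw[:, None]
    Q, _ = np.linalg.qr(Ct)
    My = yt - Q @ (Q.T @ yt)
    MG = Gt - Q @ (Q.T @ Gt)
    gss = (MG**2).sum(axis=0)
    ok = gss > 1e-12 * np.maximum((Gt**2).sum(axis=0), 1e-300)
    beta = np.where(ok, (MG * My[:, None]).sum(axis=0) / np.where(ok, gss, 1.0), np.nan)
    if mode == "null_fixed":
        s2 = float(My @ My) / n  # null-model ML variance reused for every SNP
        se = np.sqrt(s2 / np.where(ok, gss, 1.0))
    else:
        rss = (My @ My) - beta**2 * gss
        rss = np.maximum(rss, np.finfo(float).tiny)
        se = np.sqrt(rss / n / np.where(ok, gss, 1.0))
    z = beta / se
    if wald_reference == "normal":
        p = stats.chi2.sf(z**2, 1)
    else:
        p = 2 * stats.t.sf(np.abs(z), n - covrot.shape[1] - 1)
    p = np.where(ok, p, np.nan)
    beta = np.where(ok, beta, np.nan)
    se = np.where(ok, se, np.nan)
    return beta, se, p


def scan(
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    K: SampleCovariance | None = None,
    C: CovariateTable | None = None,
    method: str = "confeti_i",
    mode: str = "null_fixed",
    wald_reference: str = "normal",
    small_n_factors: int = 10,
    exact_per_snp: bool = False,
) -> pd.DataFrame:
    """Test every (gene, SNP) pair; returns the eQTL table.

    Columns: gene, snp, beta, se, p, p_adj (global BH), label (unlabeled),
    lambda_gene, method. Monomorphic or covariate-collinear SNPs yield NaN
    records. ``exact_per_snp`` switches the mixed-model scan from the
    per-gene-null variance components to full per-SNP re-optimization.
    """
    if list(E.sample_ids) != list(G.sample_ids):
        raise ValueError("expression and genotype samples are not aligned")
    n = E.n_samples
    Y = E.values.to_numpy(dtype=float)
    Gmat = G.values.to_numpy(dtype=float)
    design = [np.ones((n, 1))]
    if C is not None:
        if list(C.sample_ids) != list(E.sample_ids):
            raise ValueError("covariate samples are not aligned")
        design.append(C.values.to_numpy(dtype=float))
    cov_design = np.hstack(design)

    mixed = method in ("confeti_i", "ice", "external_k")
    if mixed and K is None:
        raise ValueError(f"method {method!r} requires a sample covariance K")
    if not mixed and K is not None:
        raise ValueError(f"method {method!r} does not take a sample covariance")

    if method == "pca_fixed":
        n_pc = pca_factor_count(n, cov_design.shape[1] - 1, small_n_factors)
        Yc = Y - Y.mean(axis=0)
        U, s, _ = np.linalg.svd(Yc, full_matrices=False)
        cov_design = np.hstack([cov_design, U[:, :n_pc]])
    elif method not in ("linear", "confeti_i", "ice", "external_k"):
        raise ValueError(f"unknown method {method!r}")

    scan_mode = "exact" if exact_per_snp else mode
    records_beta = np.empty((E.n_genes, G.n_snps))
    records_se = np.empty_like(records_beta)
    records_p = np.empty_like(records_beta)
    if mixed:
        U = K.eigenvectors
        d = K.eigenvalues
        Grot = U.T @ Gmat
        covrot = U.T @ cov_design
        for gi in range(E.n_genes):
            yr = U.T @ Y[:, gi]
            if scan_mode == "exact":
                b = np.empty(G.n_snps)
                se = np.empty(G.n_snps)
                p = np.empty(G.n_snps)
                for m in range(G.n_snps):
                    gcol = Gmat[:, m]
                    if gcol.std() == 0:
                        b[m] = se[m] = p[m] = np.nan
                        continue
                    X = np.column_stack([gcol, cov_design])
                    fit = fit_gene_lmm(Y[:, gi], X, K, mode="exact",
                                       wald_reference=wald_reference)
                    b[m], se[m], p[m] = fit.beta[0], fit.se_beta[0], fit.p
            else:
                b, se, p = _lmm_scan_gene(yr, covrot, Grot, d, scan_mode, wald_reference)
                mono = Gmat.std(axis=0) == 0
                b[mono] = se[mono] = p[mono] = np.nan
            records_beta[gi], records_se[gi], records_p[gi] = b, se, p
    else:
        for gi in range(E.n_genes):
            b, se, p = _ols_scan_gene(Y[:, gi], cov_design, Gmat, wald_reference)
            mono = Gmat.std(axis=0) == 0
            b[mono] = se[mono] = p[mono] = np.nan
            records_beta[gi], records_se[gi], records_p[gi] = b, se, p

    genes = np.repeat(E.gene_ids.to_numpy(), G.n_snps)
    snps = np.tile(G.snp_ids.to_numpy(), E.n_genes)
    table = pd.DataFrame(
        {
            "gene": genes,
            "snp": snps,
            "beta": records_beta.ravel(),
            "se": records_se.ravel(),
            "p": records_p.ravel(),
        }
    )
    valid = table["p"].notna()
    p_adj = np.full(len(table), np.nan)
    if valid.any():
        p_adj[valid.to_numpy()] = bh_adjust(table.loc[valid, "p"].to_numpy())
    table["p_adj"] = p_adj
    table["label"] = "unlabeled"

    lam = {}
    tiny = np.finfo(float).tiny
    for gene, sub in table.groupby("gene", sort=False):
        pv = sub["p"].dropna().to_numpy()
        lam[gene] = genomic_inflation(np.clip(pv, tiny, 1.0))[0] if pv.size else np.nan
    table["lambda_gene"] = table["gene"].map(lam)
    table["method"] = method
    return table


def genomic_inflation(p_values: np.ndarray) -> tuple[float, float]:
    """Per-gene genomic inflation factor from the median p-value.

    lambda = qchisq(1 - median p) / qchisq(0.5) with 1 df; lambda_diff is
    1 - lambda, positive under deflation.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = float(np.median(p))
    lam = stats.chi2.ppf(1.0 - m, 1) / stats.chi2.ppf(0.5, 1)
    return float(lam), float(1.0 - lam)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
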