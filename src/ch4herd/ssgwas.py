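"""Single-step GWAS: SNP effects back-solved from genomic breeding values.

Given genotyped-animal EBVs from a single-step evaluation, marker effects are
recovered in one pass as

    u_hat = Z' (Z Z')^-1 a_hat = (1/d) Z' G^-1 a_hat,   d = 2 * sum p_j (1 - p_j)

which reproduces the EBVs exactly (``Z u_hat = a_hat``) whenever G is full
rank.  Per-SNP sampling variances propagate the EBV (co)variance
``Var(a_hat) = sigma_a^2 G - PEV`` through the same linear map, yielding
two-sided normal p-values; genetic-variance shares are computed per SNP and
for moving windows of adjacent SNPs (a fixed SNP count, or a fixed
base-pair span anchored at each SNP).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .legendre_rr import LegendreBasis, SolutionSet
from .simdata import GenotypeMatrix

__all__ = [
    "aggregate_ebv",
    "centered_genotypes",
    "backsolve_snp_effects",
    "ebv_prior_variance",
    "aggregate_pev",
    "snp_pvalues",
    "snp_variance_explained",
    "window_variance",
    "bonferroni_threshold",
    "significant_hits",
    "gwas_table",
    "manhattan",
]


def aggregate_ebv(
    solution_set: SolutionSet,
    basis: LegendreBasis,
    dim_range: tuple[int, int] | None = None,
    coefficient: int | None = None,
) -> np.ndarray:
    """Collapse per-animal regression coefficients to one scalar EBV.

    Default functional: the mean daily genetic effect, ``mean_t phi(t)' a_i``
    over the integer DIM grid.  ``coefficient=i`` instead passes through the
    i-th regression coefficient.
    """
    if coefficient is not None:
        return solution_set.bv[:, coefficient].copy()
    lo, hi = dim_range or (basis.dim_min, basis.dim_max)
    dims = np.arange(lo, hi + 1)
    if dims.size == 0:
        raise ValueError("empty DIM range")
    c = basis.evaluate(dims).mean(axis=0)
    return solution_set.bv @ c


def aggregate_weights(basis: LegendreBasis, dim_range=None) -> np.ndarray:
    """The weight vector c with aggregate EBV_i = c' a_i."""
    lo, hi = dim_range or (basis.dim_min, basis.dim_max)
    dims = np.arange(lo, hi + 1)
    if dims.size == 0:
        raise ValueError("empty DIM range")
    return basis.evaluate(dims).mean(axis=0)


def centered_genotypes(genotypes: GenotypeMatrix, allele_freq=None):
    """(Z, d): frequency-centered counts and the VanRaden denominator."""
    p = genotypes.allele_freq() if allele_freq is None else np.asarray(allele_freq, float)
    Z = genotypes.counts - 2.0 * p
    Z[np.isnan(Z)] = 0.0
    d = 2.0 * float(np.sum(p * (1.0 - p)))
    if d <= 0:
        raise ValueError("zero VanRaden denominator (all SNPs monomorphic)")
    return Z, d


def _solve_G(G_mat: np.ndarray, B: np.ndarray, ridge: float | None):
    G_mat = np.asarray(G_mat, float)
    n = G_mat.shape[0]
    if ridge is None:
        ridge = 1e-8 * np.trace(G_mat) / n
    if ridge == 0.0:
        # exact minimum-norm solve (pseudoinverse behaviour)
        return np.linalg.lstsq(G_mat, B, rcond=None)[0]
    try:
        return np.linalg.solve(G_mat + ridge * np.eye(n), B)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "G is singular; blend with A22 or increase the ridge"
        ) from err


def backsolve_snp_effects(
    G_mat: np.ndarray,
    Z: np.ndarray,
    ebv_genotyped: np.ndarray,
    denominator: float | None = None,
    ridge: float | None = None,
) -> np.ndarray:
    """Back-solve per-SNP effects from genotyped-animal EBVs.

    ``G_mat`` must be the unblended genomic matrix built from the same
    centered ``Z`` (``G = Z Z' / d``); a small ridge (default
    ``1e-8 * trace/n``) keeps the solve stable.
    """
    Z = np.asarray(Z, float)
    a = np.asarray(ebv_genotyped, float)
    if Z.shape[0] != G_mat.shape[0] or a.shape[0] != G_mat.shape[0]:
        raise ValueError("Z / EBV dimensions do not match G")
    d = float(denominator) if denominator is not None else None
    if d is None:
        # recover d from G = ZZ'/d via least squares on the diagonals
        zz = np.einsum("ij,ij->i", Z, Z)
        gd = np.diag(G_mat)
        d = float(zz @ gd / (gd @ gd))
    x = _solve_G(G_mat, a, ridge)
    return (Z.T @ x) / d


def ebv_prior_variance(sigma2_agg: float, G_mat: np.ndarray) -> np.ndarray:
    """Prior (co)variance of aggregate genotyped EBVs: sigma_a^2 * G."""
    return float(sigma2_agg) * np.asarray(G_mat, float)


def aggregate_pev(
    solution_set: SolutionSet, c: np.ndarray, genotyped_index: np.ndarray
) -> np.ndarray:
    """Prediction-error covariance of the aggregated EBVs of genotyped animals."""
    if solution_set.caa is None:
        raise ValueError("solution set lacks prediction-error covariances")
    g = np.asarray(genotyped_index)
    sub = solution_set.caa[g][:, :, g, :]
    return np.einsum("i,aibj,j->ab", c, sub, c)


def snp_pvalues(
    snp_effects: np.ndarray,
    Z: np.ndarray,
    G_mat: np.ndarray,
    var_ebv: np.ndarray,
    denominator: float,
    ridge: float | None = None,
):
    """Two-sided p-values for back-solved SNP effects.

    ``var_ebv`` is Var(a_hat) of the genotyped EBVs, typically
    ``sigma_a^2 G - PEV``; it is propagated through the back-solution map
    ``Lambda = (1/d) Z' G^-1``.  SNPs with (numerically) non-positive
    variance get p = 1 and a flag.
    """
    u = np.asarray(snp_effects, float)
    B = _solve_G(G_mat, np.asarray(var_ebv, float), ridge)  # G^-1 V
    BG = _solve_G(G_mat, B.T, ridge)  # G^-1 V G^-1 (V symmetric)
    var_u = np.einsum("ij,ji->i", Z.T @ BG, Z) / denominator**2
    flagged = var_u <= 0
    se = np.sqrt(np.clip(var_u, 0.0, None))
    z = np.zeros_like(u)
    ok = ~flagged
    z[ok] = np.abs(u[ok]) / se[ok]
    p = np.ones_like(u)
    p[ok] = 2.0 * stats.norm.sf(z[ok])
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return p, se, flagged


def snp_variance_explained(
    Z: np.ndarray, snp_effects: np.ndarray, ebv_genotyped: np.ndarray
) -> np.ndarray:
    """Percent of genetic variance per SNP: 100 var(z_j u_j) / var(a_hat)."""
    a = np.asarray(ebv_genotyped, float)
    denom = float(np.var(a))
    if denom <= 0:
        raise ValueError("zero variance of genotyped EBVs")
    scores = np.asarray(Z, float) * np.asarray(snp_effects, float)
    return 100.0 * np.var(scores, axis=0) / denom


def window_variance(
    Z: np.ndarray,
    snp_effects: np.ndarray,
    ebv_genotyped: np.ndarray,
    snp_map: pd.DataFrame,
    window_snps: int | None = 50,
    window_bp: int | None = None,
) -> pd.DataFrame:
    """Percent of genetic variance explained by moving SNP windows.

    Count mode (``window_snps``): sliding windows of k adjacent SNPs within
    each chromosome, step 1 (n - k + 1 windows; short chromosomes yield one
    truncated, flagged window).  Length mode (``window_bp``): one window per
    anchor SNP spanning ``[pos, pos + bp)``.  The window statistic is the
    variance over genotyped animals of the summed SNP scores, as a percent
    of the EBV variance.
    """
    if (window_snps is None) == (window_bp is None):
        raise ValueError("specify exactly one of window_snps or window_bp")
    a = np.asarray(ebv_genotyped, float)
    denom = float(np.var(a))
    if denom <= 0:
        raise ValueError("zero variance of genotyped EBVs")
    scores = np.asarray(Z, float) * np.asarray(snp_effects, float)
    chroms = snp_map["chrom"].astype(str).to_numpy()
    pos = snp_map["pos"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        cpos = pos[idx]
        if window_snps is not None:
            k = int(window_snps)
            truncated = len(idx) < k
            n_win = max(len(idx) - k + 1, 1)
            width = min(k, len(idx))
            csum = np.cumsum(scores[:, idx], axis=1)
            for w in range(n_win):
                j0, j1 = w, w + width  # [j0, j1)
                s = csum[:, j1 - 1] - (csum[:, j0 - 1] if j0 > 0 else 0.0)
                rows.append(
                    (
                        chrom, int(cpos[j0]), int(cpos[j1 - 1]), j0 + 1,
                        width, 100.0 * float(np.var(s)) / denom, truncated,
                    )
                )
        else:
            bp = int(window_bp)
            for j0 in range(len(idx)):
                lo = cpos[j0]
                j1 = j0 + int(np.searchsorted(cpos[j0:], lo + bp, side="left"))
                s = scores[:, idx[j0:j1]].sum(axis=1)
                rows.append(
                    (
                        chrom, int(lo), int(cpos[j1 - 1]), j0 + 1,
                        j1 - j0, 100.0 * float(np.var(s)) / denom, False,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "first_snp", "n_snps", "pct_var", "truncated"],
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold on the -log10 scale: -log10(alpha / n_tests)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(-np.log10(alpha / n_tests))


def significant_hits(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Rows at or above the -log10(p) threshold, strongest first."""
    out = table.loc[table["neglog10p"] >= threshold].copy()
    return out.sort_values("neglog10p", ascending=False).reset_index(drop=True)


def gwas_table(
    genotypes: GenotypeMatrix,
    snp_effects: np.ndarray,
    pvalues: np.ndarray,
    se: np.ndarray,
    pct_var: np.ndarray,
) -> pd.DataFrame:
    """Assemble the per-SNP results table (Manhattan-ready)."""
    m = genotypes.snp_map
    return pd.DataFrame(
        {
            "chrom": m["chrom"].astype(str),
            "pos": m["pos"],
            "snp_id": m["snp_id"],
            "effect": snp_effects,
            "se": se,
            "p": pvalues,
            "neglog10p": -np.log10(pvalues),
            "pct_var": pct_var,
        }
    )


def manhattan(table: pd.DataFrame, value: str = "pct_var", threshold=None, ax=None):
    """Manhattan plot of a per-SNP or per-window statistic."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    x0 = 0
    xcol = "pos" if "pos" in table.columns else "start"
    for i, (chrom, grp) in enumerate(table.groupby("chrom", sort=False)):
        x = x0 + (grp[xcol] - grp[xcol].min())
        ax.scatter(x, grp[value], s=4, color="C0" if i % 2 else "C1")
        x0 = float(x.max()) + 1e6
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=0.8, ls="--")
    ax.set_xlabel("genome position (concatenated chromosomes)")
    ax.set_ylabel(value)
    return ax
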