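"""Kinship-corrected genotype-phenotype association.

The per-SNP model is the standard univariate linear mixed model

    y = W a + x b + u + e,   u ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

with W the covariates (intercept, body mass, pronotum length), x the SNP
dosage and K the centered-genotype relatedness matrix.  K is eigendecomposed
once; per SNP the variance ratio lambda = sg^2/se^2 is maximized by a coarse
grid on log lambda followed by Brent refinement (maximum likelihood, not
REML), and the SNP effect is tested with a Wald statistic against
chi-square(1).

The multi-trait scan combines per-trait Wald z-scores into an omnibus
sum-of-squares statistic referenced to chi-square(#traits) — an approximation
to a full multivariate mixed model that is exact when traits are
uncorrelated given the covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import MISSING, GenotypeMatrix

__all__ = [
    "compute_grm",
    "lmm_wald_scan",
    "multitrait_scan",
    "phenotype_pca",
    "adjust_pvalues",
]


def compute_grm(gm: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Centered-genotype relatedness matrix K = ZZ'/(2 sum f(1-f)).

    Missing dosages are mean-imputed per site; monomorphic sites are
    excluded.  The diagonal averages ~1 under Hardy-Weinberg.
    """
    dosage = gm.dosage if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    d = dosage.astype(float)
    d[dosage == MISSING] = np.nan
    f = np.nanmean(d, axis=1) / 2.0
    poly = (f > 0) & (f < 1)
    if not poly.any():
        raise ValueError("all sites monomorphic; GRM undefined")
    d = d[poly]
    f = f[poly]
    z = np.where(np.isnan(d), 0.0, d - 2 * f[:, None])
    denom = 2.0 * (f * (1 - f)).sum()
    return (z.T @ z) / denom


def _profile_loglik(log_lam, s, yr, Wr):
    """Profiled ML log-likelihood of the rotated model at one lambda."""
    lam = np.exp(log_lam)
    v = lam * s + 1.0
    w = 1.0 / v
    Ww = Wr * w[:, None]
    A = Wr.T @ Ww
    beta = np.linalg.solve(A, Ww.T @ yr)
    resid = yr - Wr @ beta
    n = len(yr)
    rss = float((resid * resid * w).sum())
    return -0.5 * (n * np.log(2 * np.pi * rss / n) + np.log(v).sum() + n)


LAMBDA_GRID = np.linspace(np.log(1e-5), np.log(1e5), 25)


def _grid_loglik_all(s, yr, Wr, Xall, grid=LAMBDA_GRID):
    """Profiled ML log-likelihood on a log-lambda grid, for every SNP at once.

    ``Xall`` holds the rotated dosages (n x S).  Covariates are projected out
    per grid point with GLS algebra, so the cost is O(G * n * (S + p^2)).
    """
    n = len(yr)
    S = Xall.shape[1]
    out = np.empty((len(grid), S))
    for g, loglam in enumerate(grid):
        w = 1.0 / (np.exp(loglam) * s + 1.0)
        logdet = np.log(np.maximum(1.0 / w, 1e-300)).sum()
        Wd = Wr * w[:, None]
        Ainv = np.linalg.inv(Wr.T @ Wd)
        WdY = Wd.T @ yr
        yMy = float((yr * yr * w).sum() - WdY @ Ainv @ WdY)
        WdX = Wd.T @ Xall
        AWdX = Ainv @ WdX
        xMy = Xall.T @ (w * yr) - WdX.T @ (Ainv @ WdY)
        xMx = (Xall * Xall * w[:, None]).sum(axis=0) - (WdX * AWdX).sum(axis=0)
        rss = yMy - xMy**2 / np.maximum(xMx, 1e-300)
        rss = np.maximum(rss, 1e-300)
        out[g] = -0.5 * (n * np.log(2 * np.pi * rss / n) + logdet + n)
    return out


def _refine_lambda(s, yr, Xr, i_best, grid=LAMBDA_GRID):
    """Brent refinement of log lambda inside the bracketing grid cells."""
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[i_best])
    res = optimize.minimize_scalar(
        lambda g: -_profile_loglik(g, s, yr, Xr),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x)


def _gls_wald(s, yr, Xr, log_lam):
    """GLS effect, SE and Wald chi-square p for the last column of Xr."""
    lam = np.exp(log_lam)
    w = 1.0 / (lam * s + 1.0)
    Xw = Xr * w[:, None]
    A = Xr.T @ Xw
    Ainv = np.linalg.inv(A)
    beta = Ainv @ (Xw.T @ yr)
    resid = yr - Xr @ beta
    n = len(yr)
    sigma2 = float((resid * resid * w).sum()) / n  # ML estimate
    var_b = sigma2 * Ainv[-1, -1]
    b = float(beta[-1])
    wald = b * b / var_b if var_b > 0 else np.nan
    p = float(stats.chi2.sf(wald, df=1)) if np.isfinite(wald) else np.nan
    return b, float(np.sqrt(var_b)), wald, p


def lmm_wald_scan(
    trait: np.ndarray,
    gm: GenotypeMatrix,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Per-SNP mixed-model Wald tests of one trait.

    ``covariates`` (n_samples x c) gets an intercept prepended; samples with
    a missing trait or covariate are dropped from the analysis.  Monomorphic
    SNPs (in the analyzed samples) are skipped.  Returns the site table with
    ``beta, se, wald, p, p_adj, lambda_`` columns.
    """
    y = np.asarray(trait, dtype=float)
    n = gm.n_samples
    if len(y) != n:
        raise ValueError("trait length does not match sample count")
    W = np.ones((n, 1))
    if covariates is not None:
        W = np.column_stack([W, np.asarray(covariates, dtype=float)])
    keep = ~np.isnan(y) & ~np.isnan(W).any(axis=1)
    y, W = y[keep], W[keep]
    if np.nanstd(y) == 0:
        raise ValueError("trait is constant")
    Ksub = K[np.ix_(keep, keep)]
    s, U = np.linalg.eigh(Ksub)
    s = np.maximum(s, 0.0)
    yr = U.T @ y
    Wr = U.T @ W

    dosage = gm.dosage[:, keep].astype(float)
    dosage[gm.dosage[:, keep] == MISSING] = np.nan
    site_mean = np.nanmean(dosage, axis=1)
    dosage = np.where(np.isnan(dosage), site_mean[:, None], dosage)

    poly = np.nanstd(dosage, axis=1) > 0
    Xall = (U.T @ dosage[poly].T)  # n x S_poly rotated dosages
    grid_ll = _grid_loglik_all(s, yr, Wr, Xall)
    best = np.argmax(grid_ll, axis=0)

    rows = np.full((gm.n_sites, 5), np.nan)
    for j, i in enumerate(np.flatnonzero(poly)):
        Xr = np.column_stack([Wr, Xall[:, j]])
        log_lam = _refine_lambda(s, yr, Xr, int(best[j]))
        b, se, wald, p = _gls_wald(s, yr, Xr, log_lam)
        rows[i] = (b, se, wald, p, np.exp(log_lam))
    out = gm.sites.reset_index(drop=True).copy()
    out[["beta", "se", "wald", "p", "lambda_"]] = rows
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = adjust_pvalues(out.loc[ok, "p"], method=adjust)
    return out


def multitrait_scan(
    traits: pd.DataFrame,
    gm: GenotypeMatrix,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Omnibus association of each SNP with a trait set (e.g. CHC PCs 1-4).

    Runs the univariate mixed-model scan per trait, converts each Wald
    statistic to a signed z, and tests sum(z^2) against chi-square(#traits).
    """
    names = list(traits.columns)
    if len(names) < 2:
        raise ValueError("need at least two traits for an omnibus test")
    notna = traits.notna().all(axis=1).to_numpy()
    if not notna.any():
        raise ValueError("no samples observed for all traits")
    z2 = np.zeros(gm.n_sites)
    defined = np.ones(gm.n_sites, dtype=bool)
    per_trait = {}
    for name in names:
        res = lmm_wald_scan(traits[name].to_numpy(), gm, K, covariates, adjust)
        per_trait[name] = res
        z2 += np.nan_to_num(res["wald"].to_numpy())
        defined &= res["wald"].notna().to_numpy()
    out = gm.sites.reset_index(drop=True).copy()
    out["omnibus"] = np.where(defined, z2, np.nan)
    out["p"] = np.where(defined, stats.chi2.sf(z2, df=len(names)), np.nan)
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = adjust_pvalues(out.loc[ok, "p"], method=adjust)
    out.attrs["per_trait"] = per_trait
    return out


def phenotype_pca(peaks: pd.DataFrame, n_pcs: int = 4, scale: bool = False):
    """PCA of a complete peak-abundance matrix (rows with missing values
    dropped and logged).  Returns (scores DataFrame, explained-variance
    fractions, loadings)."""
    complete = peaks.dropna()
    n_dropped = len(peaks) - len(complete)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "phenotype_pca: dropped %d incomplete rows", n_dropped
        )
    if len(complete) < 2:
        raise ValueError("need at least two complete samples")
    X = complete.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    U, svals, Vt = np.linalg.svd(X, full_matrices=False)
    var = svals**2 / (len(complete) - 1)
    frac = var / var.sum()
    n_pcs = min(n_pcs, len(svals))
    scores = pd.DataFrame(
        U[:, :n_pcs] * svals[:n_pcs],
        index=complete.index,
        columns=[f"PC{i + 1}" for i in range(n_pcs)],
    )
    return scores, frac[:n_pcs], Vt[:n_pcs].T


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up ('BH') or
    Bonferroni."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=key)[1]
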