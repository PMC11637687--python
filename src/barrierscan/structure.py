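"""Population-structure summaries: LD pruning, genotype PCA, and
simplex-constrained ancestry estimation.

Ancestry proportions are estimated by least squares: minimize
||P - Q F'||^2 where P is the dosage/2 matrix (samples x sites), rows of Q
live on the K-simplex and F entries in [0, 1].  The blocks are updated by
projected gradient steps with backtracking line search, which keeps the
objective monotonically non-increasing (a plain least-squares solve followed
by projection does not), from several random restarts.
"""

from __future__ import annotations

import numpy as np


from .core_io import MISSING, GenotypeMatrix

__all__ = ["ld_prune", "genotype_pca", "admixture_als"]


def _imputed(gm) -> np.ndarray:
    dosage = gm.dosage if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    d = dosage.astype(float)
    d[dosage == MISSING] = np.nan
    mean = np.nanmean(d, axis=1)
    return np.where(np.isnan(d), mean[:, None], d)  # sites x samples


def ld_prune(
    gm, window: int = 50, step: int = 10, r2_max: float = 0.01
) -> np.ndarray:
    """Greedy LD pruning over sliding SNP-count windows.

    Within each window, for every pair with squared dosage correlation
    > ``r2_max`` one SNP is dropped — the one with more missing data, ties
    broken toward the later position.  Single pass; returns a boolean mask of
    retained sites.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must lie in (0, 1]")
    if step < 1 or window < step:
        raise ValueError("require window >= step >= 1")
    dosage = gm.dosage if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    S = dosage.shape[0]
    d = _imputed(gm)
    n_missing = (dosage == MISSING).sum(axis=1)
    keep = np.ones(S, dtype=bool)
    start = 0
    while start < S:
        idx = np.flatnonzero(keep[start:start + window]) + start
        if len(idx) > 1:
            sub = d[idx]
            sd = sub.std(axis=1)
            ok = sd > 0
            sub = (sub - sub.mean(axis=1, keepdims=True))
            sub[ok] /= sd[ok, None] * np.sqrt(sub.shape[1])
            r2 = (sub @ sub.T) ** 2
            np.fill_diagonal(r2, 0.0)
            for a in range(len(idx)):
                if not keep[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if not keep[idx[b]]:
                        continue
                    if r2[a, b] > r2_max:
                        ia, ib = idx[a], idx[b]
                        if n_missing[ia] > n_missing[ib]:
                            drop = ia
                        elif n_missing[ib] > n_missing[ia]:
                            drop = ib
                        else:
                            drop = max(ia, ib)  # later position
                        keep[drop] = False
                        if drop == ia:
                            break
        if start + window >= S:
            break
        start += step
    return keep


def genotype_pca(gm, n_pcs: int = 4, scale: bool = False):
    """PCA of mean-imputed, centered dosages.

    Returns (scores (samples x n_pcs), explained-variance fractions)."""
    d = _imputed(gm).T  # samples x sites
    if d.shape[0] < 2:
        raise ValueError("need at least two samples")
    X = d - d.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    if not np.any(X):
        raise ValueError("zero-variance genotype data")
    U, svals, _ = np.linalg.svd(X, full_matrices=False)
    var = svals**2
    frac = var / var.sum()
    n_pcs = min(n_pcs, len(svals))
    return U[:, :n_pcs] * svals[:n_pcs], frac[:n_pcs]


def _project_simplex(Q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    K = Q.shape[1]
    srt = np.sort(Q, axis=1)[:, ::-1]
    css = np.cumsum(srt, axis=1) - 1.0
    ind = np.arange(1, K + 1)
    cond = srt - css / ind > 0
    rho = cond.sum(axis=1)
    theta = css[np.arange(len(Q)), rho - 1] / rho
    return np.maximum(Q - theta[:, None], 0.0)


def admixture_als(
    gm, k: int, seed: int = 0, max_iter: int = 500, tol: float = 1e-6,
    n_restarts: int = 3,
):
    """Least-squares ancestry fractions Q (samples x K) and allele
    frequencies F (sites x K).

    Alternating projected-gradient block updates with backtracking; the best
    of ``n_restarts`` random initializations is returned.  Deterministic
    given ``seed``.
    """
    dosage = gm.dosage if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    P = _imputed(gm).T / 2.0  # samples x sites in [0, 1]
    n, S = P.shape
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > n:
        raise ValueError("K cannot exceed the number of samples")
    rng = np.random.default_rng(seed)

    def objective(Q, F):
        R = P - Q @ F.T
        return float((R * R).sum())

    def pg_step(Mat, grad, proj, obj_fun, obj0):
        """One projected-gradient step with backtracking on the block."""
        gnorm2 = float((grad * grad).sum())
        if gnorm2 == 0.0:
            return Mat, obj0
        eta = 1.0
        for _ in range(40):
            cand = proj(Mat - eta * grad)
            obj = obj_fun(cand)
            if obj <= obj0 + 1e-12:
                return cand, obj
            eta *= 0.5
        return Mat, obj0

    best = None
    for _ in range(n_restarts):
        Q = _project_simplex(rng.dirichlet(np.ones(k), size=n))
        F = np.clip(rng.random((S, k)), 0.0, 1.0)
        obj = objective(Q, F)
        for _ in range(max_iter):
            obj_start = obj
            R = P - Q @ F.T
            grad_Q = -2.0 * R @ F / max(float((F * F).sum()), 1.0)
            Q, obj = pg_step(
                Q, grad_Q, _project_simplex, lambda M: objective(M, F), obj
            )
            R = P - Q @ F.T
            grad_F = -2.0 * R.T @ Q / max(float((Q * Q).sum()), 1.0)
            F, obj = pg_step(
                F, grad_F, lambda M: np.clip(M, 0.0, 1.0),
                lambda M: objective(Q, M), obj
            )
            if obj_start - obj <= tol * max(obj_start, 1e-12):
                break
        if best is None or obj < best[0]:
            best = (obj, Q, F)
    obj, Q, F = best
    return Q, F, obj
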