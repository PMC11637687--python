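"""Joint-SFS demographic model comparison for a two-species split.

Four nested divergence scenarios are compared on the joint site-frequency
spectrum by Poisson composite likelihood and AIC:

* ``no_mig``      — split T1 ago, sizes nu1/nu2, no gene flow (3 params)
* ``sym_mig``     — split with continuous symmetric migration m (4 params)
* ``anc_mig``     — migration from the split until it ceased at T2 (5 params)
* ``sec_contact`` — no migration until secondary contact at T2 (5 params)

Times are in units of 2*N_ref generations, sizes relative to N_ref and
migration in units of 2*N_ref * per-generation rate.  Expected spectra come
from a Monte Carlo structured coalescent with common random numbers (the same
seed is reused at every likelihood evaluation, so the Nelder-Mead simplex
moves on a fixed noisy-but-consistent surface).  Theta is profiled
analytically, and the fixed corners [0,0] and [n1,n2] are masked in all
likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._coalescent import expected_sfs_kernel, migration_window
from .core_io import MISSING, GenotypeMatrix

__all__ = [
    "MODEL_PARAMS",
    "JointSFS",
    "FitResult",
    "build_joint_sfs",
    "project_sfs",
    "expected_sfs",
    "poisson_loglik",
    "fit_model",
    "compare_models",
]

MODEL_PARAMS = {
    "no_mig": ("nu1", "nu2", "T1"),
    "sym_mig": ("nu1", "nu2", "T1", "m"),
    "anc_mig": ("nu1", "nu2", "T1", "m", "T2"),
    "sec_contact": ("nu1", "nu2", "T1", "m", "T2"),
}


@dataclass
class JointSFS:
    """(n1+1) x (n2+1) derived-allele count spectrum with masked corners."""

    counts: np.ndarray
    n1: int
    n2: int
    folded: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError("counts shape inconsistent with sample sizes")
        if (self.counts < 0).any():
            raise ValueError("negative SFS entries")

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros_like(self.counts, dtype=bool)
        m[0, 0] = True
        m[self.n1, self.n2] = True
        return m

    def total(self) -> float:
        return float(self.counts[~self.mask].sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# joint SFS n1={self.n1} n2={self.n2} "
                     f"folded={int(self.folded)} mask=corners\n")
            np.savetxt(fh, self.counts, delimiter="\t", fmt="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "JointSFS":
        with open(path) as fh:
            header = fh.readline()
            counts = np.loadtxt(fh, delimiter="\t", ndmin=2)
        kv = dict(tok.split("=") for tok in header.strip("# \n").split() if "=" in tok)
        return cls(counts, int(kv["n1"]), int(kv["n2"]),
                   folded=bool(int(kv.get("folded", 0))))


def _hyp_weights(n: int, n_to: int) -> np.ndarray:
    """(n+1, n_to+1) hypergeometric projection weights W[i, k]."""
    i = np.arange(n + 1)[:, None]
    k = np.arange(n_to + 1)[None, :]
    w = (
        special.comb(i, k)
        * special.comb(n - i, n_to - k)
        / special.comb(n, n_to)
    )
    return np.where(np.isfinite(w), w, 0.0)


def project_sfs(sfs: JointSFS, n1_to: int, n2_to: int) -> JointSFS:
    """Project the spectrum down to smaller sample sizes by independent
    hypergeometric redistribution of each entry; mass is conserved before
    masking."""
    if n1_to > sfs.n1 or n2_to > sfs.n2:
        raise ValueError("cannot project upward")
    w1 = _hyp_weights(sfs.n1, n1_to)
    w2 = _hyp_weights(sfs.n2, n2_to)
    return JointSFS(w1.T @ sfs.counts @ w2, n1_to, n2_to, folded=sfs.folded)


def build_joint_sfs(
    gm: GenotypeMatrix,
    pop1: list[str],
    pop2: list[str],
    outgroup: list[str] | None = None,
    project_to: tuple[int, int] | None = None,
    max_outgroup_freq: float = 0.0,
) -> JointSFS:
    """Build the joint SFS of two sample sets from a genotype matrix.

    With an outgroup, sites are polarized (outgroup-fixed allele = ancestral;
    outgroup-polymorphic sites beyond ``max_outgroup_freq`` are dropped);
    without one the spectrum is folded onto minor-allele counts and flagged.
    ``project_to`` enables per-site hypergeometric projection so sites with
    missing calls still contribute; otherwise sites not fully genotyped in
    either set are skipped (count recorded in ``attrs['n_skipped']``).
    """
    idx1 = gm.sample_indices(pop1)
    idx2 = gm.sample_indices(pop2)
    d1, d2 = gm.dosage[:, idx1], gm.dosage[:, idx2]

    def cnt(d):
        called = d != MISSING
        return (np.where(called, d, 0).sum(axis=1).astype(np.int64),
                (2 * called.sum(axis=1)).astype(np.int64))

    a1, m1 = cnt(d1)
    a2, m2 = cnt(d2)

    folded = outgroup is None
    keep = (m1 > 0) & (m2 > 0)
    if not folded:
        og = gm.dosage[:, gm.sample_indices(outgroup)]
        aog, mog = cnt(og)
        with np.errstate(invalid="ignore", divide="ignore"):
            fog = aog / mog
        anc_ref = fog <= max_outgroup_freq
        anc_alt = fog >= 1.0 - max_outgroup_freq
        keep &= (mog > 0) & (anc_ref | anc_alt)
        flip = anc_alt
    else:
        warnings.warn("no outgroup: building a folded (minor-allele) spectrum")
        flip = np.zeros(gm.n_sites, dtype=bool)

    n1_full, n2_full = 2 * len(pop1), 2 * len(pop2)
    if project_to is None:
        full = (m1 == n1_full) & (m2 == n2_full)
        n_skipped = int((keep & ~full).sum())
        keep &= full
        n1_t, n2_t = n1_full, n2_full
        counts = np.zeros((n1_t + 1, n2_t + 1))
        i = np.where(flip[keep], m1[keep] - a1[keep], a1[keep])
        j = np.where(flip[keep], m2[keep] - a2[keep], a2[keep])
        if folded:
            fold_mask = (i + j) * 2 > (n1_t + n2_t)
            i = np.where(fold_mask, n1_t - i, i)
            j = np.where(fold_mask, n2_t - j, j)
        np.add.at(counts, (i, j), 1.0)
    else:
        n1_t, n2_t = project_to
        ok = keep & (m1 >= n1_t) & (m2 >= n2_t)
        n_skipped = int((keep & ~ok).sum())
        counts = np.zeros((n1_t + 1, n2_t + 1))
        for s in np.flatnonzero(ok):
            i = m1[s] - a1[s] if flip[s] else a1[s]
            j = m2[s] - a2[s] if flip[s] else a2[s]
            w1 = _hyp_weights(int(m1[s]), n1_t)[int(i)]
            w2 = _hyp_weights(int(m2[s]), n2_t)[int(j)]
            counts += np.outer(w1, w2)
        if folded:
            counts = counts + counts[::-1, ::-1]
            half = np.add.outer(np.arange(n1_t + 1), np.arange(n2_t + 1)) * 2
            counts[half > n1_t + n2_t] = 0.0
            counts[half == n1_t + n2_t] /= 2.0
    sfs = JointSFS(counts, n1_t, n2_t, folded=folded)
    sfs.attrs = {"n_skipped": n_skipped}
    return sfs


def _check_params(model: str, params: dict) -> None:
    for name in MODEL_PARAMS[model]:
        if name not in params:
            raise ValueError(f"model {model!r} requires parameter {name!r}")
        if params[name] <= 0:
            raise ValueError(f"parameter {name!r} must be positive")
    if "T2" in MODEL_PARAMS[model] and not params["T2"] < params["T1"]:
        raise ValueError("T2 must be smaller than T1")


def expected_sfs(model: str, params: dict, n1: int, n2: int,
                 n_reps: int = 2000, seed: int = 0) -> np.ndarray:
    """Expected joint spectrum per unit theta (Monte Carlo, CRN by seed)."""
    _check_params(model, params)
    if n_reps < 1000:
        warnings.warn("n_reps < 1000: expected spectrum noisy for inference")
    lo, hi, uses_m = migration_window(model, params["T1"], params.get("T2"))
    m = float(params.get("m", 0.0)) if uses_m else 0.0
    return expected_sfs_kernel(
        int(n1), int(n2), float(params["nu1"]), float(params["nu2"]),
        float(params["T1"]), lo, hi, m, int(n_reps), int(seed) & 0x7FFFFFFF,
    )


def poisson_loglik(observed: JointSFS, model_per_theta: np.ndarray) -> tuple[float, float]:
    """Profiled-theta Poisson composite log-likelihood over unmasked cells.

    Returns (lnL, theta_hat) with theta_hat = sum(obs) / sum(model).
    Model cells are floored at a tiny epsilon so observed mass in a cell the
    Monte Carlo expectation missed is penalized, not fatal.
    """
    mask = observed.mask
    obs = observed.counts[~mask]
    mod = np.maximum(model_per_theta[~mask], 0.0)
    mod_sum = mod.sum()
    if mod_sum <= 0:
        return -np.inf, 0.0
    theta = obs.sum() / mod_sum
    lam = np.maximum(theta * mod, 1e-300)
    lam = np.maximum(lam, 1e-8 * lam.max())
    lnl = float((obs * np.log(lam) - lam - special.gammaln(obs + 1.0)).sum())
    return lnl, float(theta)


@dataclass
class FitResult:
    model: str
    params: dict
    loglik: float
    theta: float
    aic: float
    n_params: int
    trace: list = field(default_factory=list)
    observed: JointSFS | None = None


def _pack(model: str, params: dict) -> np.ndarray:
    """Log-parameterization; T2 encoded as logit of T2/T1 so T2 < T1 always."""
    names = MODEL_PARAMS[model]
    x = []
    for name in names:
        if name == "T2":
            frac = params["T2"] / params["T1"]
            frac = min(max(frac, 1e-6), 1 - 1e-6)
            x.append(np.log(frac / (1 - frac)))
        else:
            x.append(np.log(params[name]))
    return np.array(x)


def _unpack(model: str, x: np.ndarray) -> dict:
    names = MODEL_PARAMS[model]
    params = {}
    for name, v in zip(names, x):
        if name == "T2":
            frac = 1.0 / (1.0 + np.exp(-v))
            params["T2"] = frac * params["T1"]
        else:
            params[name] = float(np.exp(np.clip(v, -12.0, 12.0)))
    return params


def fit_model(
    observed: JointSFS,
    model: str,
    rounds: list[int] = (10, 20, 30, 40),
    n_reps: int = 2000,
    seed: int = 0,
    init: dict | None = None,
    maxiter_per_start: int = 400,
) -> FitResult:
    """Multi-round Nelder-Mead fit of one demographic model.

    Each round launches the stated number of replicate Nelder-Mead starts;
    every start perturbs the incumbent best parameters by log-uniform
    fold-changes whose range shrinks round by round, and the best
    log-likelihood seeds the next round.  The Monte Carlo expected spectrum
    uses the same random-number seed at every evaluation (common random
    numbers), so the composite-likelihood surface is deterministic within a
    fit.
    """
    if observed.total() <= 0:
        raise ValueError("observed spectrum carries no polymorphism")
    names = MODEL_PARAMS[model]
    k = len(names)
    rng = np.random.default_rng(seed)
    crn_seed = int(rng.integers(0, 2**31 - 1))

    def objective_at(x, reps):
        params = _unpack(model, x)
        mod = expected_sfs(model, params, observed.n1, observed.n2,
                           n_reps=reps, seed=crn_seed)
        lnl, _ = poisson_loglik(observed, mod)
        return -lnl

    def objective(x):
        return objective_at(x, n_reps)

    default = {"nu1": 1.0, "nu2": 1.0, "T1": 1.0, "m": 1.0, "T2": 0.5}
    inits = init if isinstance(init, (list, tuple)) else [init or default]
    anchors = []
    best_x, best_f = None, np.inf
    for cand in inits:
        base = {n: dict(cand)[n] for n in names}
        _check_params(model, base)
        x = _pack(model, base)
        anchors.append(x)
        f = objective(x)
        if f < best_f:
            best_x, best_f = x, f
    trace = []
    fold_schedule = [3.0, 2.0, 1.5, 1.2, 1.1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rnd, n_rep_starts in enumerate(rounds):
            fold = fold_schedule[min(rnd, len(fold_schedule) - 1)]
            for rep in range(n_rep_starts):
                # round 0 explores every supplied anchor, later rounds the
                # incumbent best
                center = anchors[rep % len(anchors)] if rnd == 0 else best_x
                x0 = center + rng.uniform(-np.log(fold), np.log(fold), size=k)
                # explicit simplex: scipy's default collapses near x0 = 0
                simplex = np.vstack([x0] + [x0 + 0.4 * np.eye(k)[i]
                                            for i in range(k)])
                res = optimize.minimize(
                    objective, x0, method="Nelder-Mead",
                    options={"maxiter": maxiter_per_start,
                             "xatol": 1e-3, "fatol": 1e-3,
                             "initial_simplex": simplex},
                )
                if res.fun < best_f:
                    best_f = res.fun
                    best_x = res.x
                trace.append((rnd, rep, -res.fun, -best_f))
        # polish on a less noisy surface: the Monte Carlo likelihood at the
        # working replicate count carries a parameter-dependent noise bias
        # that distorts fine comparisons
        simplex = np.vstack([best_x] + [best_x + 0.1 * np.eye(k)[i]
                                        for i in range(k)])
        res = optimize.minimize(
            lambda x: objective_at(x, 4 * n_reps), best_x,
            method="Nelder-Mead",
            options={"maxiter": maxiter_per_start // 2,
                     "xatol": 1e-4, "fatol": 1e-4,
                     "initial_simplex": simplex},
        )
        best_x = res.x
    if not np.isfinite(res.fun):
        raise RuntimeError(f"no finite likelihood found for model {model}")

    # final likelihood at high replication (common seed across models fitted
    # with the same `seed`, so log-likelihoods are comparable)
    params = _unpack(model, best_x)
    mod = expected_sfs(model, params, observed.n1, observed.n2,
                       n_reps=10 * n_reps, seed=crn_seed)
    lnl, theta = poisson_loglik(observed, mod)
    aic = 2 * k - 2 * lnl
    return FitResult(model, params, lnl, theta, aic, k, trace, observed)


def fit_model_sequence(
    observed: JointSFS,
    models: list[str],
    rounds: list[int] = (10, 20, 30, 40),
    n_reps: int = 2000,
    seed: int = 0,
    **kwargs,
) -> list[FitResult]:
    """Fit several models, seeding each from the best simpler fit.

    Models are fitted in order of parameter count; a richer model starts
    from the best-fitting parameters of the best nested model found so far
    (new parameters get neutral defaults: m = 0.5, T2 = T1/2).  This is the
    usual remedy for the richer model's optimizer missing the basin the
    simpler model already found — a nested model's likelihood can then never
    be grossly overtaken by its special case.
    """
    order = sorted(models, key=lambda m: len(MODEL_PARAMS[m]))
    fits = []
    best = None
    for model in order:
        init = None
        if best is not None:
            shared = {k: best.params[k] for k in best.params
                      if k in MODEL_PARAMS[model]}
            candidates = [dict(shared)]
            if "m" in MODEL_PARAMS[model] and "m" not in shared:
                # a nested anchor (vanishing gene flow) and a migration-scale
                # anchor, so the richer model can neither lose its special
                # case nor miss the high-migration basin
                candidates = [dict(shared, m=0.01), dict(shared, m=2.0)]
            for cand in candidates:
                if "T2" in MODEL_PARAMS[model] and "T2" not in cand:
                    cand["T2"] = 0.5 * cand.get("T1", 1.0)
            init = candidates
        fit = fit_model(observed, model, rounds=rounds, n_reps=n_reps,
                        seed=seed, init=init, **kwargs)
        fits.append(fit)
        if best is None or fit.loglik > best.loglik:
            best = fit
    by_name = {f.model: f for f in fits}
    return [by_name[m] for m in models]


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fitted models by AIC (ties broken toward fewer parameters)."""
    if len(fits) > 1:
        ref = fits[0].observed
        for f in fits[1:]:
            if f.observed is not None and ref is not None and (
                f.observed.counts.shape != ref.counts.shape
                or not np.allclose(f.observed.counts, ref.counts)
            ):
                raise ValueError("fits compare different observed spectra")
    rows = [
        {"model": f.model, "n_params": f.n_params, "loglik": f.loglik,
         "aic": f.aic, **{f"par_{k}": v for k, v in f.params.items()}}
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values(
        ["aic", "n_params"], kind="stable"
    ).reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out
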