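"""Monte Carlo structured-coalescent kernels (numba-compiled).

Two demes of sizes ``nu1``, ``nu2`` (relative to a reference size) diverged
``T1`` time units ago (units of 2*N_ref generations); symmetric migration at
rate ``m`` (units of 2*N_ref * per-generation rate) is active only inside the
backward-time window [mig_lo, mig_hi).  At ``T1`` all lineages merge into an
ancestral deme of size 1.  Per-pair coalescence rate within a deme of size nu
is 1/nu; per-lineage migration rate is m/2.

Each surviving lineage subtends (i, j) sampled alleles from demes 1 and 2;
its branch length is accumulated into SFS cell (i, j) when it coalesces
(lifetime bookkeeping — O(1) per event).  The expected spectrum is the
per-genealogy average, in units where the mutation rate per branch per time
unit is 1 (overall scale is irrelevant downstream: theta is profiled).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _simulate_genealogy(n1, n2, nu1, nu2, T1, mig_lo, mig_hi, m, acc):
    """One genealogy; adds branch lengths into acc[(i, j)]. Returns total length."""
    k = n1 + n2
    deme = np.empty(k, np.int64)
    cfg1 = np.zeros(k, np.int64)
    cfg2 = np.zeros(k, np.int64)
    birth = np.zeros(k)
    for i in range(n1):
        deme[i] = 0
        cfg1[i] = 1
    for i in range(n1, k):
        deme[i] = 1
        cfg2[i] = 1
    k0 = n1

    t = 0.0
    total = 0.0
    while k > 1:
        ancestral = t >= T1
        if ancestral:
            rate_c0 = 0.5 * k * (k - 1)  # nu_anc = 1
            rate_c1 = 0.0
            rate_m = 0.0
        else:
            k1 = k - k0
            rate_c0 = 0.5 * k0 * (k0 - 1) / nu1
            rate_c1 = 0.5 * k1 * (k1 - 1) / nu2
            rate_m = 0.5 * m * k if (mig_lo <= t < mig_hi) else 0.0

        boundary = np.inf
        if not ancestral:
            boundary = T1
            if t < mig_lo < boundary:
                boundary = mig_lo
            if t < mig_hi < boundary:
                boundary = mig_hi

        total_rate = rate_c0 + rate_c1 + rate_m
        if total_rate <= 0.0:
            t = boundary
            continue
        dt = np.random.exponential(1.0 / total_rate)
        if t + dt >= boundary:
            t = boundary
            continue
        t += dt

        u = np.random.random() * total_rate
        if u < rate_c0 + rate_c1:
            if ancestral:
                kd = k
            elif u < rate_c0:
                kd = k0
            else:
                kd = k - k0
            d = 0 if (ancestral or u < rate_c0) else 1
            a = int(np.random.random() * kd)
            b = int(np.random.random() * (kd - 1))
            if b >= a:
                b += 1
            ia = -1
            ib = -1
            seen = 0
            for i in range(k):
                if ancestral or deme[i] == d:
                    if seen == a:
                        ia = i
                    if seen == b:
                        ib = i
                    seen += 1
            la = t - birth[ia]
            lb = t - birth[ib]
            acc[cfg1[ia], cfg2[ia]] += la
            acc[cfg1[ib], cfg2[ib]] += lb
            total += la + lb
            cfg1[ia] += cfg1[ib]
            cfg2[ia] += cfg2[ib]
            birth[ia] = t
            if not ancestral and deme[ib] == 0:
                k0 -= 1
            last = k - 1
            if ib != last:
                deme[ib] = deme[last]
                cfg1[ib] = cfg1[last]
                cfg2[ib] = cfg2[last]
                birth[ib] = birth[last]
            k -= 1
        else:
            i = int(np.random.random() * k)
            if deme[i] == 0:
                k0 -= 1
            else:
                k0 += 1
            deme[i] = 1 - deme[i]
    return total


@njit(cache=True)
def expected_sfs_kernel(n1, n2, nu1, nu2, T1, mig_lo, mig_hi, m, n_reps, seed):
    """Mean branch length per SFS cell over n_reps genealogies (CRN via seed)."""
    np.random.seed(seed)
    acc = np.zeros((n1 + 1, n2 + 1))
    for _ in range(n_reps):
        _simulate_genealogy(n1, n2, nu1, nu2, T1, mig_lo, mig_hi, m, acc)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            acc[i, j] /= n_reps
    return acc


@njit(cache=True)
def sample_sfs_kernel(n1, n2, nu1, nu2, T1, mig_lo, mig_hi, m,
                      n_loci, theta_per_locus, seed):
    """Observed joint SFS from n_loci independent non-recombining genealogies.

    theta_per_locus <= 0: place exactly one mutation per locus, on a branch
    chosen proportionally to its length.  Otherwise: Poisson(theta * L_total)
    mutations per locus, each placed proportionally to branch length.
    """
    np.random.seed(seed)
    sfs = np.zeros((n1 + 1, n2 + 1))
    cells = (n1 + 1) * (n2 + 1)
    for _ in range(n_loci):
        acc = np.zeros((n1 + 1, n2 + 1))
        total = _simulate_genealogy(n1, n2, nu1, nu2, T1, mig_lo, mig_hi, m, acc)
        if total <= 0.0:
            continue
        if theta_per_locus <= 0.0:
            n_mut = 1
        else:
            n_mut = np.random.poisson(theta_per_locus * total)
        for _ in range(n_mut):
            u = np.random.random() * total
            c = 0.0
            done = False
            for i in range(n1 + 1):
                if done:
                    break
                for j in range(n2 + 1):
                    c += acc[i, j]
                    if u < c:
                        sfs[i, j] += 1.0
                        done = True
                        break
            if not done:  # float round-off: last non-empty cell
                for idx in range(cells - 1, -1, -1):
                    i = idx // (n2 + 1)
                    j = idx % (n2 + 1)
                    if acc[i, j] > 0.0:
                        sfs[i, j] += 1.0
                        break
    return sfs


def migration_window(model: str, T1: float, T2: float | None) -> tuple[float, float, bool]:
    """Backward-time window in which migration is active for a model name."""
    if model == "no_mig":
        return (0.0, 0.0, False)
    if model == "sym_mig":
        return (0.0, T1, True)
    if model == "anc_mig":
        if T2 is None:
            raise ValueError("anc_mig requires T2")
        return (T2, T1, True)
    if model == "sec_contact":
        if T2 is None:
            raise ValueError("sec_contact requires T2")
        return (0.0, T2, True)
    raise ValueError(f"unknown model {model!r}")
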